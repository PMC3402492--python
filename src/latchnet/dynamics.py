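"""Continuous-time rate dynamics of one recurrent attractor network.

Each neuron carries a local input ``h_i`` integrated with a leaky,
forward-Euler scheme (one numeric step = 0.66 ms) and an activity
``x_i = f(h_i)`` through a logistic transfer with gain ``T``:

    tau_n * dh_i/dt = -h_i + sum_j J_ij x_j - lambda * (<x> - p) - theta
                      + [I_ext_i - theta_ext]_+ + eta_i

The ``lambda`` term regulates the mean activity ``<x>`` toward the coding
sparseness ``p`` and, together with the constant threshold ``theta``, acts
as global inhibition. External inputs are excitatory and take effect only
above the external threshold ``theta_ext`` (rectified shift). ``eta`` is
temporally correlated Gaussian noise, an AR(1) (discretised
Ornstein-Uhlenbeck) process with stationary standard deviation ``eta_amp``
and autocorrelation ``exp(-lag / tau_corr)``.

All functions broadcast over a leading batch axis, so a state of shape
``(B, N)`` advances B independent trials at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

__all__ = [
    "NetworkParams",
    "NetworkState",
    "transfer",
    "gate_external",
    "noise_step",
    "step",
    "pattern_correlation",
]


@dataclass(frozen=True)
class NetworkParams:
    """All scalar parameters of one network (times in ms, rates in spikes/s)."""

    N: int  # number of neurons
    p: float  # sparseness of the stored patterns
    T: float  # neuronal gain of the logistic transfer
    tau_n: float  # neuron time constant [ms]
    theta: float  # constant activation threshold / global inhibition
    lam: float  # regulation strength on mean activity
    x_max: float  # maximal firing rate [spikes/s]; x=1 maps to x_max
    theta_ext: float  # external-input threshold
    eta_amp: float  # stationary noise standard deviation
    tau_corr: float  # noise correlation time [ms]
    U_within: float = 0.0  # recurrent utilization [1/spike]; 0 = no depression
    tau_r_within: float = 1.0  # recurrent recovery time [ms]
    U_between: float = 0.0  # outgoing inter-network utilization [1/spike]
    tau_r_between: float = 1.0  # inter-network recovery time [ms]

    def __post_init__(self) -> None:
        if self.N <= 0 or not (0.0 < self.p < 1.0):
            raise ValueError("need N > 0 and 0 < p < 1")
        if min(self.tau_n, self.tau_corr, self.tau_r_within, self.tau_r_between) <= 0:
            raise ValueError("all time constants must be positive")
        if self.eta_amp < 0 or self.U_within < 0 or self.U_between < 0:
            raise ValueError("eta_amp and U must be non-negative")

    def with_(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass
class NetworkState:
    """Instantaneous state of one network (or a batch of them)."""

    h: np.ndarray  # local inputs, (..., N)
    x: np.ndarray  # activities in [0, 1], x = f(h)
    eta: np.ndarray  # current noise values
    t: float  # current time [ms]


def transfer(h: np.ndarray | float, T: float) -> np.ndarray | float:
    """Logistic transfer ``f(h) = 1 / (1 + exp(-h / T))``."""
    return expit(np.asarray(h, dtype=np.float64) / T)


def gate_external(I_ext: np.ndarray | float, theta_ext: float) -> np.ndarray:
    """Threshold-linear gate: drive passes only above ``theta_ext``."""
    return np.maximum(np.asarray(I_ext, dtype=np.float64) - theta_ext, 0.0)


def noise_step(
    eta_prev: np.ndarray,
    eta_amp: float,
    tau_corr: float,
    dt: float,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> np.ndarray:
    """One AR(1) update of the low-pass-filtered Gaussian noise.

    eta(t + dt) = a * eta(t) + eta_amp * sqrt(1 - a^2) * eps,
    a = exp(-dt / tau_corr), eps ~ N(0, 1). This realises exactly the
    stationary std ``eta_amp`` and autocorrelation ``exp(-lag/tau_corr)``.
    ``eps`` may be supplied directly (batched drivers pre-draw it); otherwise
    it is drawn from ``rng``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.exp(-dt / tau_corr)
    if eps is None:
        if rng is None:
            raise ValueError("provide either rng or eps")
        eps = rng.standard_normal(np.shape(eta_prev))
    return a * eta_prev + eta_amp * np.sqrt(1.0 - a * a) * eps


def init_noise(
    shape: tuple[int, ...], eta_amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw noise from its stationary distribution N(0, eta_amp^2)."""
    return eta_amp * rng.standard_normal(shape)


def step(
    state: NetworkState,
    J_eff: np.ndarray,
    I_ext: np.ndarray | float,
    params: NetworkParams,
    dt: float,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> NetworkState:
    """One forward-Euler step of the local-input dynamics.

    ``J_eff`` must already include any depression scaling (see
    :mod:`latchnet.depression`); ``I_ext`` is the raw excitatory external
    drive, gated here by ``theta_ext``.
    """
    h, x = state.h, state.x
    recurrent = x @ J_eff.T
    regulation = params.lam * (x.mean(axis=-1, keepdims=True) - params.p)
    drive = (
        -h
        + recurrent
        - regulation
        - params.theta
        + gate_external(I_ext, params.theta_ext)
        + state.eta
    )
    h_next = h + (dt / params.tau_n) * drive
    if not np.isfinite(h_next).all():
        raise FloatingPointError(
            "non-finite local input; check parameter configuration"
        )
    eta_next = (
        noise_step(state.eta, params.eta_amp, params.tau_corr, dt, rng, eps)
        if params.eta_amp > 0
        else np.zeros_like(state.eta)
    )
    return NetworkState(
        h=h_next, x=transfer(h_next, params.T), eta=eta_next, t=state.t + dt
    )


def pattern_correlation(x: np.ndarray, xi: np.ndarray) -> float:
    """Pearson correlation between an activity vector and a binary pattern.

    Returns ``nan`` for zero-variance input (reported as not-converged by
    callers).
    """
    x = np.asarray(x, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    xc = x - x.mean()
    kc = xi - xi.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(kc)
    if denom == 0.0:
        return float("nan")
    return float(xc @ kc / denom)


def correlations_with_patterns(x: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    """Pearson correlation of activity row(s) with every stored pattern.

    ``x``: (..., N); ``patterns``: (M, N) binary. Returns (..., M). Rows of
    zero variance yield 0 (never satisfy a convergence criterion).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    kc = patterns.astype(np.float64)
    kc = kc - kc.mean(axis=1, keepdims=True)
    knorm = np.linalg.norm(kc, axis=1)
    xc = x - x.mean(axis=-1, keepdims=True)
    xnorm = np.linalg.norm(xc, axis=-1, keepdims=True)
    num = xc @ kc.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / (xnorm * knorm)
    return np.where(np.isfinite(out), out, 0.0)
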