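"""The coupled two-network model and its trial simulator.

A lexical and a semantic attractor network are joined by excitatory
pattern-to-pattern projections: every active neuron of word pattern mu in
the lexical network projects to every active neuron of concept pattern mu
in the semantic network and vice versa, with per-connection weight
``gain / n_presynaptic_active``. Bottom-up (lexical-to-semantic)
projections are strong but depress with a slow recovery time, giving the
lexical network a fast, short-lived influence on the semantic one;
top-down (semantic-to-lexical) projections are weak and never depress,
providing the slow feedback that produces priming. The baseline patterns
have no inter-network connections at all.

The simulator advances a whole batch of independent trials at once. All
weight matrices here are low-rank (at most one term per stored pattern),
so matrix-vector products are evaluated through their factors; the dense
matrices returned by :func:`build_projections` and
:func:`latchnet.patterns.hopfield_weights` are mathematically identical
and are used to cross-check the factored path in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depression import depression_step
from .dynamics import NetworkParams, gate_external, noise_step, transfer
from .patterns import PatternSet

__all__ = [
    "CoupledModel",
    "CoupledState",
    "SimResult",
    "build_projections",
    "coupled_step",
    "simulate_trials",
]

#: internal noise pre-draw block, in steps (fixed; part of the determinism contract)
_NOISE_CHUNK = 128


class _CovarianceFactor:
    """Factored covariance-rule weights: J = (A^T A)/c - diag, A = xi - p."""

    def __init__(self, patterns: PatternSet):
        xi = patterns.patterns.astype(np.float64)
        p = patterns.p
        self.A = xi - p
        self.c = patterns.n_neurons * p * (1.0 - p)
        self.d = (self.A**2).sum(axis=0) / self.c

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """J @ v for rows of ``v`` (J is symmetric)."""
        return (v @ self.A.T) @ self.A / self.c - v * self.d


class _CrossFactor:
    """Factored inter-network projection, baseline pattern excluded."""

    def __init__(self, pre: PatternSet, post: PatternSet, gain: float):
        if pre.n_patterns != post.n_patterns:
            raise ValueError("pattern sets must have matching indexing")
        keep = [mu for mu in range(pre.n_patterns) if mu != pre.baseline_index]
        self.Xpre = pre.patterns[keep].astype(np.float64)
        self.Xpost = post.patterns[keep].astype(np.float64)
        self.scale = gain / self.Xpre.sum(axis=1)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """W @ v (rows of ``v`` are presynaptic activity vectors)."""
        return ((v @ self.Xpre.T) * self.scale) @ self.Xpost

    def dense(self) -> np.ndarray:
        return (self.Xpost.T * self.scale) @ self.Xpre


class _CorrProbe:
    """Fast Pearson correlation of activity rows with every stored pattern."""

    def __init__(self, patterns: PatternSet):
        k = patterns.patterns.astype(np.float64)
        kc = k - k.mean(axis=1, keepdims=True)
        self.Kc = kc / np.linalg.norm(kc, axis=1, keepdims=True)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=-1, keepdims=True)
        norm = np.linalg.norm(xc, axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (xc @ self.Kc.T) / norm
        return np.where(np.isfinite(out), out, 0.0)


def build_projections(
    lexical: PatternSet,
    semantic: PatternSet,
    g_ls: float = 2.0,
    g_sl: float = 0.21,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense inter-network weight matrices (W_ls, W_sl).

    ``W_ls[i, j]`` connects lexical neuron j to semantic neuron i; each
    stored word/concept pair contributes ``gain / n_active_presynaptic`` to
    every active-to-active connection, summed when a presynaptic neuron
    serves several patterns. Baseline patterns contribute nothing.
    """
    W_ls = _CrossFactor(lexical, semantic, g_ls).dense()
    W_sl = _CrossFactor(semantic, lexical, g_sl).dense()
    return W_ls, W_sl


@dataclass
class CoupledState:
    """Batched state of the coupled system (arrays shaped ``(B, N)``)."""

    h_sem: np.ndarray
    x_sem: np.ndarray
    eta_sem: np.ndarray
    r_sem: np.ndarray  # recurrent-semantic resources, per presynaptic neuron
    h_lex: np.ndarray
    x_lex: np.ndarray
    eta_lex: np.ndarray
    r_ls: np.ndarray  # lexical-to-semantic resources, per lexical neuron
    t: float


@dataclass
class CoupledModel:
    """Parameters, patterns and factored weights of the two-network system."""

    sem_params: NetworkParams
    lex_params: NetworkParams
    sem_patterns: PatternSet
    lex_patterns: PatternSet
    g_ls: float = 2.0  # lexical-to-semantic input gain (raw, per pattern)
    g_sl: float = 0.21  # semantic-to-lexical input gain
    g_ext: float = 0.56  # external (visual) input gain
    condition: str = "control"

    J_sem: _CovarianceFactor = field(init=False, repr=False)
    J_lex: _CovarianceFactor = field(init=False, repr=False)
    W_ls: _CrossFactor = field(init=False, repr=False)
    W_sl: _CrossFactor = field(init=False, repr=False)
    corr_sem: _CorrProbe = field(init=False, repr=False)
    corr_lex: _CorrProbe = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.J_sem = _CovarianceFactor(self.sem_patterns)
        self.J_lex = _CovarianceFactor(self.lex_patterns)
        self.W_ls = _CrossFactor(self.lex_patterns, self.sem_patterns, self.g_ls)
        self.W_sl = _CrossFactor(self.sem_patterns, self.lex_patterns, self.g_sl)
        self.corr_sem = _CorrProbe(self.sem_patterns)
        self.corr_lex = _CorrProbe(self.lex_patterns)

    @property
    def n_patterns(self) -> int:
        return self.sem_patterns.n_patterns

    def baseline_state(self, batch: int, rngs=None, noise: bool = True) -> CoupledState:
        """Fresh state on both baseline patterns, full resources.

        ``h`` is set at the baseline fixed point (recurrent drive of the
        baseline pattern minus the threshold); noise starts from its
        stationary distribution, one stream per trial.
        """
        xi_s = self.sem_patterns.patterns[self.sem_patterns.baseline_index]
        xi_l = self.lex_patterns.patterns[self.lex_patterns.baseline_index]
        h_sem = np.tile(
            self.J_sem.matvec(xi_s[np.newaxis].astype(np.float64))
            - self.sem_params.theta,
            (batch, 1),
        )
        h_lex = np.tile(
            self.J_lex.matvec(xi_l[np.newaxis].astype(np.float64))
            - self.lex_params.theta,
            (batch, 1),
        )
        eta_sem = np.zeros_like(h_sem)
        eta_lex = np.zeros_like(h_lex)
        if noise and rngs is not None:
            for b, rng in enumerate(rngs):
                eta_sem[b] = self.sem_params.eta_amp * rng.standard_normal(
                    self.sem_params.N
                )
                eta_lex[b] = self.lex_params.eta_amp * rng.standard_normal(
                    self.lex_params.N
                )
        return CoupledState(
            h_sem=h_sem,
            x_sem=transfer(h_sem, self.sem_params.T),
            eta_sem=eta_sem,
            r_sem=np.ones_like(h_sem),
            h_lex=h_lex,
            x_lex=transfer(h_lex, self.lex_params.T),
            eta_lex=eta_lex,
            r_ls=np.ones_like(h_lex),
            t=0.0,
        )


def coupled_step(
    model: CoupledModel,
    state: CoupledState,
    visual_input: np.ndarray | None,
    dt: float,
    eps_sem: np.ndarray | None = None,
    eps_lex: np.ndarray | None = None,
    depression: bool = True,
) -> CoupledState:
    """One synchronous forward-Euler step of both networks.

    All drives are computed from the previous step's activities. The
    semantic network receives the gate-thresholded bottom-up drive (scaled
    by the lexical-to-semantic resources), the lexical network the
    gate-thresholded sum of top-down feedback and the external visual
    drive. ``visual_input`` is the raw drive to lexical neurons, ``(B, N)``
    or ``None``; ``eps_*`` are standard-normal innovations for the noise
    (``None`` freezes the noise at its current value scale 0 when unset).
    """
    ps, pl = model.sem_params, model.lex_params
    x_sem, x_lex = state.x_sem, state.x_lex

    I_sem = gate_external(model.W_ls.matvec(state.r_ls * x_lex), ps.theta_ext)
    top_down = model.W_sl.matvec(x_sem)
    if visual_input is not None:
        top_down = top_down + visual_input
    I_lex = gate_external(top_down, pl.theta_ext)

    rec_sem = model.J_sem.matvec(state.r_sem * x_sem)
    rec_lex = model.J_lex.matvec(x_lex)
    reg_sem = ps.lam * (x_sem.mean(axis=-1, keepdims=True) - ps.p)
    reg_lex = pl.lam * (x_lex.mean(axis=-1, keepdims=True) - pl.p)

    h_sem = state.h_sem + (dt / ps.tau_n) * (
        -state.h_sem + rec_sem - reg_sem - ps.theta + I_sem + state.eta_sem
    )
    h_lex = state.h_lex + (dt / pl.tau_n) * (
        -state.h_lex + rec_lex - reg_lex - pl.theta + I_lex + state.eta_lex
    )
    if not (np.isfinite(h_sem).all() and np.isfinite(h_lex).all()):
        raise FloatingPointError("non-finite state; check parameter configuration")

    if depression:
        r_sem = depression_step(
            state.r_sem, x_sem, ps.U_within, ps.tau_r_within, ps.x_max, dt
        )
        r_ls = depression_step(
            state.r_ls, x_lex, pl.U_between, pl.tau_r_between, pl.x_max, dt
        )
    else:
        r_sem, r_ls = state.r_sem, state.r_ls

    eta_sem = (
        noise_step(state.eta_sem, ps.eta_amp, ps.tau_corr, dt, eps=eps_sem)
        if eps_sem is not None
        else state.eta_sem * 0.0
    )
    eta_lex = (
        noise_step(state.eta_lex, pl.eta_amp, pl.tau_corr, dt, eps=eps_lex)
        if eps_lex is not None
        else state.eta_lex * 0.0
    )
    return CoupledState(
        h_sem=h_sem,
        x_sem=transfer(h_sem, ps.T),
        eta_sem=eta_sem,
        r_sem=r_sem,
        h_lex=h_lex,
        x_lex=transfer(h_lex, pl.T),
        eta_lex=eta_lex,
        r_ls=r_ls,
        t=state.t + dt,
    )


@dataclass
class SimResult:
    """Outcome of a batch of simulated trials (times in ms after prime onset)."""

    rt: np.ndarray  # RT from target onset; nan where not converged
    converged: np.ndarray  # bool
    sem_events: list  # per trial: list of (time, pattern index) convergences
    lex_events: list
    wave: np.ndarray | None = None  # (B, n_wave_times, n_patterns) correlations
    wave_times: tuple = ()
    sem_traj: np.ndarray | None = None  # (B, n_steps, n_patterns)
    lex_traj: np.ndarray | None = None
    times: np.ndarray | None = None


def _converged_ids(corr: np.ndarray, accept: float, reject: float) -> np.ndarray:
    """Per row: index of the pattern meeting the convergence criterion, else -1."""
    best = np.argmax(corr, axis=-1)
    bvals = np.take_along_axis(corr, best[:, None], axis=-1)[:, 0]
    second = np.partition(corr, -2, axis=-1)[:, -2]
    ok = (bvals >= accept) & (second < reject)
    return np.where(ok, best, -1)


def simulate_trials(
    model: CoupledModel,
    primes: np.ndarray,
    targets: np.ndarray,
    soa: float,
    rngs=None,
    seeds=None,
    dt: float = 0.66,
    prime_duration: float = 100.0,
    burn_in: float = 50.0,
    timeout: float = 1000.0,
    noise: bool = True,
    depression: bool = True,
    accept: float = 0.95,
    reject: float = 0.5,
    wave_times: tuple = (),
    record_trajectory: bool = False,
) -> SimResult:
    """Simulate a batch of priming trials sharing one SOA.

    Protocol per trial: a 50 ms burn-in with activities clamped to the
    baseline patterns (resources untouched) lets ``h`` and the noise settle
    on the baseline fixed point; at t=0 the prime word drives the lexical
    network for ``prime_duration`` ms; no input until the target appears at
    t=``soa`` and stays on until the end. RT is the time from target onset
    until the lexical network reaches correlation >= ``accept`` with the
    target pattern and < ``reject`` with every other pattern. Semantic (and
    lexical) convergence events are logged with the same criterion.

    Each trial owns one RNG stream (``rngs``, or fresh ``PCG64(seed)``
    streams from ``seeds``); identical seeds give bit-identical trials
    regardless of how trials are batched together.
    """
    primes = np.asarray(primes, dtype=np.intp)
    targets = np.asarray(targets, dtype=np.intp)
    B = len(primes)
    if rngs is None:
        if seeds is None:
            raise ValueError("provide rngs or seeds")
        rngs = [np.random.default_rng(int(s)) for s in seeds]
    rngs = list(rngs)
    ps, pl = model.sem_params, model.lex_params
    N_s, N_l = ps.N, pl.N
    M = model.n_patterns

    state = model.baseline_state(B, rngs=rngs, noise=noise)

    # --- burn-in: activities clamped to baseline, h and noise relax -------
    xi_s = model.sem_patterns.patterns[model.sem_patterns.baseline_index].astype(
        np.float64
    )
    xi_l = model.lex_patterns.patterns[model.lex_patterns.baseline_index].astype(
        np.float64
    )
    n_burn = int(round(burn_in / dt))
    drive_s = model.J_sem.matvec(xi_s[np.newaxis]) - ps.theta  # (1, N_s)
    drive_l = model.J_lex.matvec(xi_l[np.newaxis]) - pl.theta
    for k in range(n_burn):
        if noise:
            eps_s = np.stack([r.standard_normal(N_s) for r in rngs])
            eps_l = np.stack([r.standard_normal(N_l) for r in rngs])
            state.eta_sem = noise_step(state.eta_sem, ps.eta_amp, ps.tau_corr, dt, eps=eps_s)
            state.eta_lex = noise_step(state.eta_lex, pl.eta_amp, pl.tau_corr, dt, eps=eps_l)
        state.h_sem += (dt / ps.tau_n) * (-state.h_sem + drive_s + state.eta_sem)
        state.h_lex += (dt / pl.tau_n) * (-state.h_lex + drive_l + state.eta_lex)
    state.x_sem = transfer(state.h_sem, ps.T)
    state.x_lex = transfer(state.h_lex, pl.T)
    state.t = 0.0

    # --- main loop ---------------------------------------------------------
    V_prime = model.g_ext * model.lex_patterns.patterns[primes].astype(np.float64)
    V_target = model.g_ext * model.lex_patterns.patterns[targets].astype(np.float64)
    n_prime = int(round(prime_duration / dt))
    n_target_on = int(round(soa / dt))
    n_total = n_target_on + int(round(timeout / dt))
    wave_steps = {int(round(tw / dt)): i for i, tw in enumerate(wave_times)}
    last_wave_step = max(wave_steps) if wave_steps else -1

    rt = np.full(B, np.nan)
    sem_events: list[list[tuple[float, int]]] = [[] for _ in range(B)]
    lex_events: list[list[tuple[float, int]]] = [[] for _ in range(B)]
    cur_sem = np.full(B, -1, dtype=np.intp)
    cur_lex = np.full(B, -1, dtype=np.intp)
    wave = np.full((B, len(wave_times), M), np.nan) if wave_times else None
    if record_trajectory:
        sem_traj = np.full((B, n_total, M), np.nan)
        lex_traj = np.full((B, n_total, M), np.nan)
        times = (np.arange(n_total) + 1) * dt
    else:
        sem_traj = lex_traj = times = None

    alive = np.arange(B)  # original trial index of each batch row
    step_idx = 0
    while step_idx < n_total and alive.size:
        n_chunk = min(_NOISE_CHUNK, n_total - step_idx)
        if noise:
            eps_s = np.empty((alive.size, n_chunk, N_s))
            eps_l = np.empty((alive.size, n_chunk, N_l))
            for b, i in enumerate(alive):
                eps_s[b] = rngs[i].standard_normal((n_chunk, N_s))
                eps_l[b] = rngs[i].standard_normal((n_chunk, N_l))
        for k in range(n_chunk):
            if step_idx < n_prime:
                visual = V_prime[alive]
            elif step_idx < n_target_on:
                visual = None
            else:
                visual = V_target[alive]
            state = coupled_step(
                model,
                state,
                visual,
                dt,
                eps_sem=eps_s[:, k] if noise else None,
                eps_lex=eps_l[:, k] if noise else None,
                depression=depression,
            )
            step_idx += 1
            t_now = step_idx * dt

            cs = model.corr_sem(state.x_sem)
            cl = model.corr_lex(state.x_lex)
            sem_id = _converged_ids(cs, accept, reject)
            lex_id = _converged_ids(cl, accept, reject)
            for b in np.nonzero((sem_id >= 0) & (sem_id != cur_sem[alive]))[0]:
                i = alive[b]
                cur_sem[i] = sem_id[b]
                sem_events[i].append((t_now, int(sem_id[b])))
            for b in np.nonzero((lex_id >= 0) & (lex_id != cur_lex[alive]))[0]:
                i = alive[b]
                cur_lex[i] = lex_id[b]
                lex_events[i].append((t_now, int(lex_id[b])))
            if step_idx > n_target_on:
                hit = (lex_id == targets[alive]) & np.isnan(rt[alive])
                if hit.any():
                    rt[alive[hit]] = t_now - soa
            if wave is not None and step_idx in wave_steps:
                wave[alive, wave_steps[step_idx]] = cs
            if record_trajectory:
                sem_traj[alive, step_idx - 1] = cs
                lex_traj[alive, step_idx - 1] = cl
        # compact the batch: drop trials that already converged on the target
        if step_idx > last_wave_step and not record_trajectory:
            keep = np.nonzero(np.isnan(rt[alive]))[0]
            if keep.size < alive.size:
                alive = alive[keep]
                state = CoupledState(
                    h_sem=state.h_sem[keep],
                    x_sem=state.x_sem[keep],
                    eta_sem=state.eta_sem[keep],
                    r_sem=state.r_sem[keep],
                    h_lex=state.h_lex[keep],
                    x_lex=state.x_lex[keep],
                    eta_lex=state.eta_lex[keep],
                    r_ls=state.r_ls[keep],
                    t=state.t,
                )

    return SimResult(
        rt=rt,
        converged=~np.isnan(rt),
        sem_events=sem_events,
        lex_events=lex_events,
        wave=wave,
        wave_times=tuple(wave_times),
        sem_traj=sem_traj,
        lex_traj=lex_traj,
        times=times,
    )
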