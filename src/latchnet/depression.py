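"""Short-term synaptic depression (rate-based Tsodyks-Markram form).

Each presynaptic neuron j owns a fraction ``r_j`` of available synaptic
resources, shared by all its outgoing synapses within one projection class.
Each presynaptic spike consumes a fraction ``U`` (the utilization) of what
is left, and the synapse recovers with time constant ``tau_r``:

    dr_j/dt = (1 - r_j) / tau_r - U * x_max * x_j * r_j

with ``x_j`` the normalized presynaptic rate in [0, 1] and ``x_max`` the
maximal firing rate that maps it back to spikes (so ``U * x_max * x_j`` is
the instantaneous utilization rate in 1/ms). The effective outgoing weight
of neuron j is its static weight scaled by ``r_j`` — excitatory and
inhibitory connections are attenuated alike, which is what destabilises a
converged attractor and produces latching. The elevated-utilization
("schizophrenic") condition differs from control only in ``U``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "depression_step",
    "effective_weights",
    "steady_state_resources",
]


def depression_step(
    r: np.ndarray,
    x_pre: np.ndarray,
    U: float,
    tau_r: float,
    x_max: float,
    dt: float,
) -> np.ndarray:
    """One forward-Euler update of the per-presynaptic-neuron resources.

    Parameters use the model's native units: ``U`` per spike, ``x_max`` in
    spikes/s (converted internally to spikes/ms), ``tau_r`` and ``dt`` in ms.
    With ``U = 0`` the resources stay pinned at 1 (no adaptation, as in the
    lexical recurrent and semantic-to-lexical projections).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if U == 0.0:
        return r
    rate = U * (x_max / 1000.0) * x_pre
    return r + dt * ((1.0 - r) / tau_r - rate * r)


def effective_weights(J_static: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Scale every outgoing (column) weight of neuron j by its resources r_j."""
    J_static = np.asarray(J_static)
    r = np.asarray(r)
    if J_static.shape[-1] != r.shape[-1]:
        raise ValueError(
            f"presynaptic dimension mismatch: {J_static.shape[-1]} != {r.shape[-1]}"
        )
    return J_static * r[..., np.newaxis, :]


def steady_state_resources(U: float, tau_r: float, x_max: float, x: float = 1.0) -> float:
    """Plateau resource level under sustained presynaptic activity ``x``.

    Closed form of the depression ODE at equilibrium:
    ``r* = 1 / (1 + U * x_max * x * tau_r)`` (x_max in spikes/ms). At the
    control semantic parameters (U=0.206, tau_r=93 ms, x_max=100 spikes/s)
    this is ~0.343; the elevated-utilization condition (U=0.2615) plateaus
    lower, ~0.291.
    """
    return 1.0 / (1.0 + U * (x_max / 1000.0) * x * tau_r)
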