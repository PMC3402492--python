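"""Simulated semantic-priming experiments.

A trial presents a prime word to the lexical network for 100 ms, waits
until the stimulus onset asynchrony (SOA) has elapsed, then presents the
target until the lexical network converges on it; the convergence latency
from target onset is the trial's RT. The two experiments differ in SOA
(200 ms vs 950 ms) and in whether indirectly related pairs are included.
Cells of the design cross mental condition (control / schizophrenic),
relatedness (related / indirect / unrelated) and the Type-I prime ratio
in {0, 0.25, 0.5, 0.75, 1}; the full-scale grid runs 300 trials per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .coupled import CoupledModel, simulate_trials
from .patterns import RelationGraph

__all__ = [
    "TrialSpec",
    "TrialRecord",
    "sample_pair",
    "run_trial",
    "run_session",
    "count_transitions",
    "records_to_frame",
    "run_wave_trials",
]

RELATEDNESS = ("related", "indirect", "unrelated")


@dataclass(frozen=True)
class TrialSpec:
    """One trial's design cell and sampled stimuli (0-based pattern indices)."""

    condition: str  # control | schizophrenic
    relatedness: str  # related | indirect | unrelated
    prime_type: str | None  # "I" | "II" | None (unrelated cells)
    soa: float  # ms
    ratio: float | None  # Type-I prime ratio of the trial's cell
    prime: int
    target: int
    seed: int


@dataclass
class TrialRecord:
    """Outcome of one trial."""

    spec: TrialSpec
    rt: float  # ms from target onset; nan when not converged
    converged: bool
    sem_events: list[tuple[float, int]] = field(default_factory=list)
    lex_events: list[tuple[float, int]] = field(default_factory=list)
    n_transitions: int = 0


def sample_pair(
    graph: RelationGraph,
    relatedness: str,
    prime_type: str | None,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw a (prime, target) pair from the canonical lists for a cell."""
    if relatedness == "related":
        pairs = (
            graph.typeI_direct_pairs if prime_type == "I" else graph.typeII_direct_pairs
        )
        prime, target = pairs[rng.integers(len(pairs))]
    elif relatedness == "indirect":
        pairs = (
            graph.typeI_indirect_pairs
            if prime_type == "I"
            else graph.typeII_indirect_pairs
        )
        prime, target, _mediator = pairs[rng.integers(len(pairs))]
    elif relatedness == "unrelated":
        hoods = graph.unrelated_neighborhood_pairs
        a, b = hoods[rng.integers(len(hoods))]
        if rng.integers(2):
            a, b = b, a
        prime = graph.neighborhoods[a][rng.integers(4)]
        target = graph.neighborhoods[b][rng.integers(4)]
    else:
        raise ValueError(f"unknown relatedness {relatedness!r}")
    return int(prime), int(target)


def count_transitions(record: TrialRecord, baseline_index: int = 16) -> int:
    """Spontaneous semantic attractor transitions during the prime window.

    Counts changes of the converged semantic pattern between prime onset
    and target onset — the latching jumps the network commits on its own
    before the target begins to drive it. The initial convergence from
    baseline onto the first real pattern is not counted, and neither is
    the target-driven convergence after target onset (in most converged
    trials the semantic network ends up on the target concept, so counting
    it would shift every distribution up by one).
    """
    spec = record.spec
    events = [(t, mu) for t, mu in record.sem_events if 0.0 <= t <= spec.soa]
    while events and events[0][1] == baseline_index:
        events.pop(0)
    return max(0, len(events) - 1)


def _trial_rng(spec: TrialSpec, graph: RelationGraph) -> np.random.Generator:
    """The trial's RNG stream, positioned after its stimulus draw.

    Every trial stream starts with the (prime, target) draw for its cell,
    then feeds the simulation noise, so a record is reproducible from its
    spec alone.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.relatedness in RELATEDNESS:
        sample_pair(graph, spec.relatedness, spec.prime_type, rng)
    return rng


def run_trial(
    model: CoupledModel,
    spec: TrialSpec,
    dt: float = 0.66,
    timeout: float = 1000.0,
    burn_in: float = 50.0,
    prime_duration: float = 100.0,
    noise: bool = True,
    depression: bool = True,
    record_trajectory: bool = False,
):
    """Run one trial; identical seed and spec give an identical record."""
    rng = _trial_rng(spec, RelationGraph.default())
    res = simulate_trials(
        model,
        primes=[spec.prime],
        targets=[spec.target],
        soa=spec.soa,
        rngs=[rng],
        dt=dt,
        timeout=timeout,
        burn_in=burn_in,
        prime_duration=prime_duration,
        noise=noise,
        depression=depression,
        record_trajectory=record_trajectory,
    )
    record = TrialRecord(
        spec=spec,
        rt=float(res.rt[0]),
        converged=bool(res.converged[0]),
        sem_events=res.sem_events[0],
        lex_events=res.lex_events[0],
    )
    record.n_transitions = count_transitions(
        record, model.sem_patterns.baseline_index
    )
    if record_trajectory:
        record.trajectory = (res.times, res.sem_traj[0], res.lex_traj[0])
    return record


def _cell_specs(
    condition: str,
    relatedness: str,
    ratio: float,
    soa: float,
    n_trials: int,
    seed_start: int,
    graph: RelationGraph,
) -> list[TrialSpec]:
    """Build the trial specs of one cell with deterministic Type-I allocation."""
    n_typeI = int(round(ratio * n_trials))
    specs = []
    for i in range(n_trials):
        seed = seed_start + i
        if relatedness == "unrelated":
            prime_type = None
        else:
            prime_type = "I" if i < n_typeI else "II"
        rng = np.random.default_rng(seed)
        prime, target = sample_pair(graph, relatedness, prime_type, rng)
        specs.append(
            TrialSpec(
                condition=condition,
                relatedness=relatedness,
                prime_type=prime_type,
                soa=soa,
                ratio=ratio,
                prime=prime,
                target=target,
                seed=seed,
            )
        )
    return specs


def run_session(
    config,
    models: dict[str, CoupledModel] | None = None,
    progress=None,
) -> list[TrialRecord]:
    """Run the full design grid of one experiment.

    Iterates conditions x relatedness x Type-I ratios; each cell runs
    ``config.trials_per_cell`` trials. Trial RNG streams are seeded
    ``base_seed + global_trial_index`` so every trial is reproducible in
    isolation; the Type-I allocation within a related/indirect cell is
    deterministic (``round(ratio * n)`` Type-I trials, the rest Type-II).
    ``models`` may pre-supply the per-condition coupled models (they are
    built from ``config.pattern_seed`` otherwise); ``progress`` is an
    optional callback ``(cell_label, n_done, n_cells)``.
    """
    from .config import build_model  # deferred: config imports this module's users

    graph = RelationGraph.default()
    if models is None:
        models = {}
    cells = list(product(config.conditions, config.relatedness, config.ratios))
    records: list[TrialRecord] = []
    index = 0
    for k, (condition, relatedness, ratio) in enumerate(cells):
        if condition not in models:
            models[condition] = build_model(
                condition, pattern_seed=config.pattern_seed, noise=config.noise
            )
        model = models[condition]
        specs = _cell_specs(
            condition,
            relatedness,
            ratio,
            config.soa,
            config.trials_per_cell,
            config.base_seed + index,
            graph,
        )
        index += len(specs)
        rngs = [_trial_rng(s, graph) for s in specs]
        res = simulate_trials(
            model,
            primes=[s.prime for s in specs],
            targets=[s.target for s in specs],
            soa=config.soa,
            rngs=rngs,
            dt=config.dt,
            timeout=config.timeout,
            burn_in=config.burn_in,
            prime_duration=config.prime_duration,
        )
        for b, s in enumerate(specs):
            rec = TrialRecord(
                spec=s,
                rt=float(res.rt[b]),
                converged=bool(res.converged[b]),
                sem_events=res.sem_events[b],
                lex_events=res.lex_events[b],
            )
            rec.n_transitions = count_transitions(
                rec, model.sem_patterns.baseline_index
            )
            records.append(rec)
        if progress is not None:
            progress((condition, relatedness, ratio), k + 1, len(cells))
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to one row per trial."""
    rows = []
    for r in records:
        s = r.spec
        rows.append(
            {
                "condition": s.condition,
                "soa": s.soa,
                "relatedness": s.relatedness,
                "prime_type": s.prime_type,
                "ratio": s.ratio,
                "prime": s.prime,
                "target": s.target,
                "seed": s.seed,
                "rt_ms": r.rt,
                "n_transitions": r.n_transitions,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


def run_wave_trials(
    model: CoupledModel,
    n_trials: int,
    base_seed: int = 0,
    prime: int = 0,
    target: int = 1,
    soa: float = 200.0,
    wave_times: tuple = (150.0, 200.0),
    dt: float = 0.66,
):
    """Related Type-I trials with a fixed prime, recording the semantic state.

    Used for the statistical spreading-activation analysis: the mean
    correlation of the semantic network with probe patterns at fixed times
    after prime onset, across trials that all start from the same prime.
    Returns the ``SimResult`` with ``wave`` of shape
    ``(n_trials, len(wave_times), n_patterns)``.
    """
    seeds = [base_seed + i for i in range(n_trials)]
    return simulate_trials(
        model,
        primes=[prime] * n_trials,
        targets=[target] * n_trials,
        soa=soa,
        seeds=seeds,
        dt=dt,
        wave_times=wave_times,
    )
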