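"""Canonical parameter set, run configuration and model assembly.

The default values reproduce the published parameter table exactly. The
condition switch ("control" vs "schizophrenic") changes only the two
utilization values — the recurrent-semantic U (0.206 -> 0.2615) and the
lexical-to-semantic U (0.087 -> 0.1104), an ~25% elevation; every other
parameter is identical between conditions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import __version__
from .coupled import CoupledModel
from .dynamics import NetworkParams
from .patterns import (
    PatternSet,
    RelationGraph,
    make_lexical_patterns,
    make_semantic_patterns,
)

__all__ = [
    "CONDITIONS",
    "RunConfig",
    "semantic_params",
    "lexical_params",
    "build_model",
    "load_config",
    "dump_config",
    "make_fixture",
]

CONDITIONS = ("control", "schizophrenic")

#: recurrent-semantic utilization per condition [1/spike]
U_WITHIN = {"control": 0.206, "schizophrenic": 0.2615}
#: lexical-to-semantic utilization per condition [1/spike]
U_BETWEEN = {"control": 0.087, "schizophrenic": 0.1104}
#: semantic noise amplitude presets (the low value is exposed but unused
#: by the two simulated experiments)
SEM_NOISE = {"default": 0.05, "low_latching": 0.02}

G_LS = 2.0  # lexical-to-semantic input gain (raw; normalized per pattern)
G_SL = 0.21  # semantic-to-lexical input gain
G_EXT = 0.56  # external (visual) input gain


def semantic_params(
    condition: str = "control", noise: str = "default"
) -> NetworkParams:
    """Semantic-network parameters (concept layer with latching dynamics)."""
    _check_condition(condition)
    return NetworkParams(
        N=500,
        p=0.06,
        T=0.05,
        tau_n=7.0,
        theta=0.02,
        lam=14.75,
        x_max=100.0,
        theta_ext=1.0,
        eta_amp=SEM_NOISE[noise],
        tau_corr=17.0,
        U_within=U_WITHIN[condition],
        tau_r_within=93.0,
        U_between=0.0,  # semantic-to-lexical synapses are not suppressed
        tau_r_between=1.0,
    )


def lexical_params(condition: str = "control") -> NetworkParams:
    """Lexical-network parameters (word layer; no recurrent adaptation)."""
    _check_condition(condition)
    return NetworkParams(
        N=500,
        p=0.04,
        T=0.05,
        tau_n=13.0,
        theta=0.17,
        lam=27.75,
        x_max=100.0,
        theta_ext=0.25,
        eta_amp=0.025,
        tau_corr=17.0,
        U_within=0.0,  # no adaptation inside the lexical layer
        tau_r_within=1.0,
        U_between=U_BETWEEN[condition],  # outgoing lexical-to-semantic
        tau_r_between=1333.0,
    )


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated experiment."""

    conditions: tuple[str, ...] = CONDITIONS
    soa: float = 200.0  # prime-to-target onset asynchrony [ms]
    relatedness: tuple[str, ...] = ("related", "indirect", "unrelated")
    ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)  # Type-I prime ratios
    trials_per_cell: int = 300
    base_seed: int = 0
    pattern_seed: int = 0
    dt: float = 0.66  # integration step [ms]
    prime_duration: float = 100.0
    burn_in: float = 50.0
    timeout: float = 1000.0  # after target onset
    noise: str = "default"
    smoke: bool = False  # reduced preset (10 trials per cell)

    def __post_init__(self) -> None:
        for c in self.conditions:
            _check_condition(c)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.trials_per_cell <= 0:
            raise ValueError("trials_per_cell must be positive")
        for q in self.ratios:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"Type-I ratio {q} outside [0, 1]")
        unknown = set(self.relatedness) - {"related", "indirect", "unrelated"}
        if unknown:
            raise ValueError(f"unknown relatedness condition(s) {sorted(unknown)}")
        if self.smoke:
            self.trials_per_cell = min(self.trials_per_cell, 10)

    @classmethod
    def sim1(cls, **kw) -> "RunConfig":
        """Short-SOA experiment: 200 ms, related/indirect/unrelated."""
        kw.setdefault("relatedness", ("related", "indirect", "unrelated"))
        return cls(soa=200.0, **kw)

    @classmethod
    def sim2(cls, **kw) -> "RunConfig":
        """Long-SOA experiment: 950 ms, directly related/unrelated only."""
        kw.setdefault("relatedness", ("related", "unrelated"))
        return cls(soa=950.0, **kw)


_LIST_FIELDS = {"conditions", "relatedness", "ratios"}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unset keys fall back to the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    raw.pop("latchnet_version", None)  # provenance echo, not a parameter
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in _LIST_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (with the package version)."""
    payload = asdict(config)
    for key in _LIST_FIELDS:
        payload[key] = list(payload[key])
    payload["latchnet_version"] = __version__
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def build_model(
    condition: str = "control",
    pattern_seed: int = 0,
    noise: str = "default",
    sem_patterns: PatternSet | None = None,
    lex_patterns: PatternSet | None = None,
) -> CoupledModel:
    """Assemble the full coupled model at the default parameters."""
    sp = semantic_params(condition, noise=noise)
    lp = lexical_params(condition)
    if sem_patterns is None:
        sem_patterns = make_semantic_patterns(
            sp.N, sp.p, RelationGraph.default(), rng_seed=pattern_seed
        )
    if lex_patterns is None:
        lex_patterns = make_lexical_patterns(
            lp.N, lp.p, sem_patterns.n_patterns, rng_seed=pattern_seed + 1
        )
    return CoupledModel(
        sem_params=sp,
        lex_params=lp,
        sem_patterns=sem_patterns,
        lex_patterns=lex_patterns,
        g_ls=G_LS,
        g_sl=G_SL,
        g_ext=G_EXT,
        condition=condition,
    )


def make_fixture(
    scale: str = "tiny", condition: str = "control", pattern_seed: int = 0
) -> tuple[tuple[PatternSet, PatternSet], RunConfig]:
    """Pattern sets and a run configuration for testing.

    ``"full"`` is the complete default setup (17 + 17 patterns). ``"tiny"`` is
    a 50-neuron, 3-pattern system (one related pair plus a baseline) with
    the sparseness raised so active-set and overlap counts stay integral;
    it satisfies every PatternSet invariant and a trial runs in well under
    a second.
    """
    if scale == "full":
        sp, lp = semantic_params(condition), lexical_params(condition)
        sem = make_semantic_patterns(
            sp.N, sp.p, RelationGraph.default(), rng_seed=pattern_seed
        )
        lex = make_lexical_patterns(lp.N, lp.p, 17, rng_seed=pattern_seed + 1)
        return (lex, sem), RunConfig(conditions=(condition,))
    if scale != "tiny":
        raise ValueError(f"unknown fixture scale {scale!r}")
    graph = RelationGraph(
        neighborhoods=((0, 1),),
        baseline_index=2,
        strong_within_pairs=((0, 1),),
        typical_within_pairs=(),
        strong_cross_pairs=(),
        typeI_direct_pairs=((0, 1),),
        typeII_direct_pairs=(),
        typeI_indirect_pairs=(),
        typeII_indirect_pairs=(),
        unrelated_neighborhood_pairs=(),
    )
    # p=0.2 -> 10 active of 50; strong overlap round(0.1*10) = 1 neuron
    sem = make_semantic_patterns(50, 0.2, graph, rng_seed=pattern_seed)
    lex = make_lexical_patterns(50, 0.2, 3, rng_seed=pattern_seed + 1)
    cfg = RunConfig(
        conditions=(condition,),
        relatedness=("related",),
        ratios=(1.0,),
        trials_per_cell=2,
        smoke=True,
    )
    return (lex, sem), cfg


def tiny_model(condition: str = "control", pattern_seed: int = 0) -> CoupledModel:
    """A 50-neuron coupled model around the tiny fixture, for fast tests."""
    (lex, sem), _ = make_fixture("tiny", condition, pattern_seed)
    sp = semantic_params(condition).with_(N=50, p=0.2)
    lp = lexical_params(condition).with_(N=50, p=0.2)
    return CoupledModel(
        sem_params=sp,
        lex_params=lp,
        sem_patterns=sem,
        lex_patterns=lex,
        g_ls=G_LS,
        g_sl=G_SL,
        g_ext=G_EXT,
        condition=condition,
    )
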