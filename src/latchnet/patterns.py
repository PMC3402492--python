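"""Binary memory patterns and Hopfield-style connectivity.

Two attractor networks are populated with sparse binary patterns. In the
semantic network, relatedness between concepts is encoded as a designed
overlap between the active-neuron sets of their patterns: four semantic
neighborhoods of four concepts each, one strongly related pair inside each
neighborhood, and four strong links that cross neighborhood boundaries (the
source of indirect, mediated relations). In the lexical network all word
patterns are mutually disjoint. Each network additionally stores a baseline
pattern that overlaps nothing and (in the coupled model) has no
inter-network connections; it serves as the neutral initial state of a
trial.

All pattern indices are 0-based in code. The figures-style 1-based labels
used in docstrings map as ``pattern k`` -> index ``k - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RelationGraph",
    "PatternSet",
    "make_semantic_patterns",
    "make_lexical_patterns",
    "hopfield_weights",
]

#: fraction of a pattern's active neurons shared with a typically related pattern
TYPICAL_STRENGTH = 0.066
#: fraction shared with a strongly related pattern
STRONG_STRENGTH = 0.1


class PatternAllocationError(ValueError):
    """Raised when the requested overlap structure cannot be realised."""


@dataclass(frozen=True)
class RelationGraph:
    """Declared relatedness structure of the semantic network.

    Pairs are stored as 0-based ordered tuples. ``typeI_*`` and ``typeII_*``
    are the canonical (prime, target[, mediator]) lists used to sample
    trials: a Type-I prime is strongly related to a concept inside its own
    neighborhood, a Type-II prime to a concept in a different neighborhood.
    """

    neighborhoods: tuple[tuple[int, ...], ...]
    baseline_index: int
    strong_within_pairs: tuple[tuple[int, int], ...]
    typical_within_pairs: tuple[tuple[int, int], ...]
    strong_cross_pairs: tuple[tuple[int, int], ...]
    typeI_direct_pairs: tuple[tuple[int, int], ...]
    typeII_direct_pairs: tuple[tuple[int, int], ...]
    typeI_indirect_pairs: tuple[tuple[int, int, int], ...]  # (prime, target, mediator)
    typeII_indirect_pairs: tuple[tuple[int, int, int], ...]
    unrelated_neighborhood_pairs: tuple[tuple[int, int], ...]  # neighborhood indices

    @property
    def n_patterns(self) -> int:
        return self.baseline_index + 1

    def declared_pairs(self) -> list[tuple[int, int, str]]:
        """All related pairs with their strength label."""
        out = [(i, j, "strong") for i, j in self.strong_within_pairs]
        out += [(i, j, "strong") for i, j in self.strong_cross_pairs]
        out += [(i, j, "typical") for i, j in self.typical_within_pairs]
        return out

    @classmethod
    def default(cls) -> "RelationGraph":
        """The 17-pattern structure used in the simulations.

        Neighborhoods 1-4, 5-8, 9-12, 13-16 (1-based); strong pairs (1,2),
        (5,6), (9,10), (13,14); cross-neighborhood strong links (2,11),
        (3,9), (6,15), (7,13); pattern 17 is the baseline.
        """
        neighborhoods = tuple(tuple(range(4 * k, 4 * k + 4)) for k in range(4))
        strong_within = ((0, 1), (4, 5), (8, 9), (12, 13))
        typical_within = tuple(
            (i, j)
            for hood in neighborhoods
            for a, i in enumerate(hood)
            for j in hood[a + 1 :]
            if (i, j) not in strong_within
        )
        cross = ((1, 10), (2, 8), (5, 14), (6, 12))
        # Type-I primes (1, 5, 10, 14 in 1-based labels) have their only
        # strong relation inside the neighborhood; Type-II primes (3, 11,
        # 15, 7) have it across neighborhoods.
        typeI_direct = ((0, 1), (4, 5), (9, 8), (13, 12))
        typeII_direct = ((2, 8), (10, 1), (14, 5), (6, 12))
        typeI_indirect = ((0, 10, 1), (4, 14, 5), (9, 2, 8), (13, 6, 12))
        typeII_indirect = ((2, 9, 8), (10, 0, 1), (14, 4, 5), (6, 13, 12))
        # Neighborhood pairs with no cross links at all: any pattern from one
        # is uncorrelated with any pattern from the other.
        unrelated_hoods = ((0, 1), (0, 3), (1, 2), (2, 3))
        return cls(
            neighborhoods=neighborhoods,
            baseline_index=16,
            strong_within_pairs=strong_within,
            typical_within_pairs=typical_within,
            strong_cross_pairs=cross,
            typeI_direct_pairs=typeI_direct,
            typeII_direct_pairs=typeII_direct,
            typeI_indirect_pairs=typeI_indirect,
            typeII_indirect_pairs=typeII_indirect,
            unrelated_neighborhood_pairs=unrelated_hoods,
        )


@dataclass
class PatternSet:
    """A set of binary memory patterns for one network.

    Attributes
    ----------
    patterns
        ``(n_patterns, N)`` array with entries in {0, 1}.
    p
        Sparseness: each pattern has exactly ``round(p * N)`` active neurons.
    baseline_index
        Index of the neutral baseline pattern (overlaps nothing).
    relations
        Declared related pairs ``(i, j, strength)`` with
        ``strength in {"typical", "strong"}``; empty for the lexical network.
    overlap_counts
        Shared-active-neuron count for each declared pair, same order as
        ``relations``.
    neighborhoods
        Partition of the non-baseline pattern indices (empty for lexical).
    """

    patterns: np.ndarray
    p: float
    baseline_index: int
    relations: list[tuple[int, int, str]] = field(default_factory=list)
    overlap_counts: list[int] = field(default_factory=list)
    neighborhoods: tuple[tuple[int, ...], ...] = ()

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_active(self) -> int:
        return int(round(self.p * self.n_neurons))

    def overlap_matrix(self) -> np.ndarray:
        """Pairwise counts of shared active neurons."""
        xi = self.patterns.astype(np.int64)
        return xi @ xi.T

    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on breach."""
        xi = self.patterns
        if not np.isin(xi, (0, 1)).all():
            raise ValueError("patterns must be binary")
        counts = xi.sum(axis=1)
        if not (counts == self.n_active).all():
            bad = int(np.argmax(counts != self.n_active))
            raise ValueError(
                f"pattern {bad} has {counts[bad]} active neurons, "
                f"expected {self.n_active}"
            )
        ov = self.overlap_matrix()
        declared = np.zeros_like(ov)
        for (i, j, _), c in zip(self.relations, self.overlap_counts):
            declared[i, j] = declared[j, i] = c
        off = ov - np.diag(np.diag(ov))
        if not (off == declared).all():
            i, j = np.argwhere(off != declared)[0]
            raise ValueError(
                f"overlap of patterns ({i}, {j}) is {off[i, j]}, "
                f"declared {declared[i, j]}"
            )
        b = self.baseline_index
        if off[b].any():
            raise ValueError("baseline pattern overlaps another pattern")

    # -- serialization (plain JSON, bit-exact round trip) -----------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "p": self.p,
            "baseline_index": self.baseline_index,
            "relations": [list(r) for r in self.relations],
            "overlap_counts": list(self.overlap_counts),
            "neighborhoods": [list(h) for h in self.neighborhoods],
            "patterns": self.patterns.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PatternSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            patterns=np.array(payload["patterns"], dtype=np.uint8),
            p=payload["p"],
            baseline_index=payload["baseline_index"],
            relations=[tuple(r) for r in payload["relations"]],
            overlap_counts=list(payload["overlap_counts"]),
            neighborhoods=tuple(tuple(h) for h in payload["neighborhoods"]),
        )


def _overlap_count(strength: str, n_active: int) -> int:
    frac = STRONG_STRENGTH if strength == "strong" else TYPICAL_STRENGTH
    return int(round(frac * n_active))


def make_semantic_patterns(
    N: int,
    p: float,
    graph: RelationGraph | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> PatternSet:
    """Build concept patterns realising the declared overlap structure exactly.

    Every declared related pair shares exactly ``round(strength * n_active)``
    active neurons (2 for typical, 3 for strong at N=500, p=0.06); shared
    neurons are dedicated to their pair, all remaining active neurons are
    drawn disjointly, so undeclared pairs share no neuron at all.
    """
    graph = graph or RelationGraph.default()
    rng = np.random.default_rng(rng_seed)
    n_active = int(round(p * N))
    n_patterns = graph.n_patterns

    pool = list(rng.permutation(N))
    active: list[list[int]] = [[] for _ in range(n_patterns)]
    relations: list[tuple[int, int, str]] = []
    overlaps: list[int] = []
    for i, j, strength in graph.declared_pairs():
        c = _overlap_count(strength, n_active)
        if len(pool) < c:
            raise PatternAllocationError(
                f"neuron pool exhausted while sharing patterns ({i}, {j})"
            )
        shared = [pool.pop() for _ in range(c)]
        active[i].extend(shared)
        active[j].extend(shared)
        relations.append((i, j, strength))
        overlaps.append(c)
    for mu in range(n_patterns):
        need = n_active - len(active[mu])
        if need < 0:
            raise PatternAllocationError(
                f"pattern {mu} requires {len(active[mu])} shared neurons, "
                f"more than its {n_active} active neurons"
            )
        if len(pool) < need:
            raise PatternAllocationError(
                f"neuron pool exhausted while filling pattern {mu}"
            )
        active[mu].extend(pool.pop() for _ in range(need))

    patterns = np.zeros((n_patterns, N), dtype=np.uint8)
    for mu, idx in enumerate(active):
        patterns[mu, idx] = 1
    ps = PatternSet(
        patterns=patterns,
        p=p,
        baseline_index=graph.baseline_index,
        relations=relations,
        overlap_counts=overlaps,
        neighborhoods=graph.neighborhoods,
    )
    ps.validate()
    return ps


def make_lexical_patterns(
    N: int,
    p: float,
    n_patterns: int = 17,
    rng_seed: int | np.random.Generator = 0,
) -> PatternSet:
    """Build mutually disjoint word patterns (no lexical relations)."""
    rng = np.random.default_rng(rng_seed)
    n_active = int(round(p * N))
    if n_patterns * n_active > N:
        raise PatternAllocationError(
            f"cannot place {n_patterns} disjoint patterns of {n_active} "
            f"active neurons in {N} neurons"
        )
    perm = rng.permutation(N)
    patterns = np.zeros((n_patterns, N), dtype=np.uint8)
    for mu in range(n_patterns):
        patterns[mu, perm[mu * n_active : (mu + 1) * n_active]] = 1
    ps = PatternSet(patterns=patterns, p=p, baseline_index=n_patterns - 1)
    ps.validate()
    return ps


def hopfield_weights(patterns: PatternSet, p: float | None = None) -> np.ndarray:
    """Covariance (sparse-coding Hopfield) connectivity storing all patterns.

    J_ij = (1 / (N p (1 - p))) * sum_mu (xi_i^mu - p)(xi_j^mu - p), with a
    zero diagonal. Symmetric; each stored pattern is a fixed point of the
    noiseless, depression-free rate dynamics at the default parameters.
    """
    if p is None:
        p = patterns.p
    xi = patterns.patterns.astype(np.float64)
    N = patterns.n_neurons
    a = xi - p
    J = (a.T @ a) / (N * p * (1.0 - p))
    np.fill_diagonal(J, 0.0)
    return J
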