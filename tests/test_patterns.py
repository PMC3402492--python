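"""Pattern construction: sparseness, designed overlaps, connectivity rule."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latchnet.dynamics import pattern_correlation
from latchnet.patterns import (
    PatternAllocationError,
    PatternSet,
    hopfield_weights,
    make_lexical_patterns,
    make_semantic_patterns,
)


class TestRelationGraph:
    def test_default_structure(self, graph):
        assert len(graph.neighborhoods) == 4
        assert all(len(h) == 4 for h in graph.neighborhoods)
        assert len(graph.strong_within_pairs) == 4
        assert len(graph.strong_cross_pairs) == 4
        # one strong pair inside each neighborhood
        for hood, pair in zip(graph.neighborhoods, graph.strong_within_pairs):
            assert set(pair) <= set(hood)
        # cross links connect different neighborhoods
        hood_of = {i: k for k, h in enumerate(graph.neighborhoods) for i in h}
        for i, j in graph.strong_cross_pairs:
            assert hood_of[i] != hood_of[j]

    def test_indirect_pairs_are_strongly_mediated(self, graph):
        strong = {frozenset(p) for p in graph.strong_within_pairs}
        strong |= {frozenset(p) for p in graph.strong_cross_pairs}
        declared = strong | {frozenset(p[:2]) for p in graph.typical_within_pairs}
        for prime, target, mediator in (
            graph.typeI_indirect_pairs + graph.typeII_indirect_pairs
        ):
            assert frozenset((prime, mediator)) in strong
            assert frozenset((mediator, target)) in strong
            assert frozenset((prime, target)) not in declared

    def test_unrelated_neighborhood_pairs_share_no_link(self, graph):
        hood_of = {i: k for k, h in enumerate(graph.neighborhoods) for i in h}
        linked = {
            frozenset((hood_of[i], hood_of[j])) for i, j in graph.strong_cross_pairs
        }
        for a, b in graph.unrelated_neighborhood_pairs:
            assert frozenset((a, b)) not in linked


class TestSemanticPatterns:
    def test_active_counts(self, sem_patterns):
        assert sem_patterns.n_active == 30
        assert (sem_patterns.patterns.sum(axis=1) == 30).all()

    def test_declared_overlaps_realised_exactly(self, sem_patterns, graph):
        ov = sem_patterns.overlap_matrix()
        declared = np.zeros_like(ov)
        for (i, j, s), c in zip(
            sem_patterns.relations, sem_patterns.overlap_counts
        ):
            expected = 3 if s == "strong" else 2
            assert c == expected
            declared[i, j] = declared[j, i] = c
        off = ov - np.diag(np.diag(ov))
        assert (off == declared).all()

    def test_self_overlap_and_correlation(self, sem_patterns):
        xi = sem_patterns.patterns[4]
        assert xi @ xi == 30
        assert pattern_correlation(xi, xi) == pytest.approx(1.0)

    def test_baseline_disjoint_from_everything(self, sem_patterns):
        ov = sem_patterns.overlap_matrix()
        b = sem_patterns.baseline_index
        assert ov[b].sum() == ov[b, b] == 30

    def test_unrelated_neighborhoods_share_no_neuron(self, sem_patterns, graph):
        ov = sem_patterns.overlap_matrix()
        for a, b in graph.unrelated_neighborhood_pairs:
            for i in graph.neighborhoods[a]:
                for j in graph.neighborhoods[b]:
                    assert ov[i, j] == 0

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariants_hold_for_any_seed(self, seed):
        ps = make_semantic_patterns(500, 0.06, rng_seed=seed)
        ps.validate()  # raises on any breach

    def test_reproducible(self):
        a = make_semantic_patterns(500, 0.06, rng_seed=42)
        b = make_semantic_patterns(500, 0.06, rng_seed=42)
        assert (a.patterns == b.patterns).all()

    def test_infeasible_allocation_raises(self, graph):
        # 17 patterns of 30 actives need ~446 distinct neurons
        with pytest.raises(PatternAllocationError):
            make_semantic_patterns(300, 0.1, graph, rng_seed=0)

    def test_json_round_trip(self, sem_patterns, tmp_path):
        path = tmp_path / "sem.json"
        sem_patterns.to_json(path)
        back = PatternSet.from_json(path)
        assert (back.patterns == sem_patterns.patterns).all()
        assert back.relations == sem_patterns.relations
        assert back.baseline_index == sem_patterns.baseline_index
        json.loads(path.read_text())  # stays plain JSON


class TestLexicalPatterns:
    def test_disjoint_and_counts(self, lex_patterns):
        assert lex_patterns.n_active == 20
        assert (lex_patterns.patterns.sum(axis=1) == 20).all()
        assert lex_patterns.patterns.sum() == 17 * 20  # union of distinct neurons
        assert (lex_patterns.patterns.sum(axis=0) <= 1).all()

    def test_disjoint_pair_correlation_closed_form(self, lex_patterns):
        # two disjoint binary vectors at sparseness p: corr = -p/(1-p)
        c = pattern_correlation(lex_patterns.patterns[0], lex_patterns.patterns[1])
        assert c == pytest.approx(-0.04 / 0.96, abs=1e-12)

    def test_capacity_exceeded_raises(self):
        with pytest.raises(PatternAllocationError):
            make_lexical_patterns(50, 0.2, n_patterns=10)


@pytest.fixture(scope="module")
def single():
    """One stored pattern: closed-form weights are known."""
    N, p = 100, 0.1
    patterns = np.zeros((1, N), dtype=np.uint8)
    patterns[0, :10] = 1
    ps = PatternSet(patterns=patterns, p=p, baseline_index=0)
    return ps, hopfield_weights(ps)


class TestHopfieldWeights:
    def test_single_pattern_values(self, single):
        ps, J = single
        N, p = 100, 0.1
        assert J[0, 1] == pytest.approx((1 - p) / (N * p))  # both active
        assert J[0, 50] == pytest.approx(-1 / N)  # active -> inactive
        assert J[50, 60] == pytest.approx(p / (N * (1 - p)))  # both inactive

    def test_symmetric_zero_diagonal(self, sem_patterns):
        J = hopfield_weights(sem_patterns)
        assert np.allclose(J, J.T)
        assert np.diag(J).sum() == 0.0
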