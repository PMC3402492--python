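"""Coupled two-network model: projections, factored algebra, trial engine."""

import numpy as np
import pytest

from latchnet.coupled import build_projections, coupled_step, simulate_trials
from latchnet.patterns import hopfield_weights


@pytest.fixture(scope="module")
def mats(control_model):
    return build_projections(
        control_model.lex_patterns, control_model.sem_patterns
    )


class TestBuildProjections:
    def test_connection_weights(self, mats, control_model):
        W_ls, W_sl = mats
        lex = control_model.lex_patterns.patterns.astype(bool)
        sem = control_model.sem_patterns.patterns.astype(bool)
        # bottom-up: gain 2 over 20 active lexical neurons
        block = W_ls[np.ix_(sem[3], lex[3])]
        assert np.allclose(block, 2.0 / 20.0)
        # top-down: gain 0.21 over 30 active semantic neurons
        block = W_sl[np.ix_(lex[3], sem[3])]
        assert np.allclose(block, 0.21 / 30.0)
        assert (W_ls >= 0).all() and (W_sl >= 0).all()

    def test_support_limited_to_corresponding_patterns(self, mats, control_model):
        W_ls, _ = mats
        lex = control_model.lex_patterns.patterns.astype(bool)
        sem = control_model.sem_patterns.patterns.astype(bool)
        allowed = np.zeros(W_ls.shape, dtype=bool)
        for mu in range(16):  # baseline (16) contributes nothing
            allowed |= np.outer(sem[mu], lex[mu])
        assert not W_ls[~allowed].any()

    def test_baseline_has_no_internetwork_connections(self, mats, control_model):
        W_ls, W_sl = mats
        b_lex = control_model.lex_patterns.patterns[16].astype(bool)
        b_sem = control_model.sem_patterns.patterns[16].astype(bool)
        assert not W_ls[:, b_lex].any()  # no outgoing from baseline word
        assert not W_sl[:, b_sem].any()


class TestFactoredAlgebra:
    def test_covariance_factor_matches_dense(self, control_model, rng):
        J = hopfield_weights(control_model.sem_patterns)
        v = rng.random((3, 500))
        assert np.allclose(control_model.J_sem.matvec(v), v @ J.T, atol=1e-12)

    def test_cross_factors_match_dense(self, control_model, rng):
        W_ls, W_sl = build_projections(
            control_model.lex_patterns, control_model.sem_patterns
        )
        v = rng.random((2, 500))
        assert np.allclose(control_model.W_ls.matvec(v), v @ W_ls.T, atol=1e-12)
        assert np.allclose(control_model.W_sl.matvec(v), v @ W_sl.T, atol=1e-12)


def _free_run(model, state, n_steps, rngs, visual=None, dt=0.66):
    N_s, N_l = model.sem_params.N, model.lex_params.N
    for _ in range(n_steps):
        eps_s = np.stack([r.standard_normal(N_s) for r in rngs])
        eps_l = np.stack([r.standard_normal(N_l) for r in rngs])
        state = coupled_step(model, state, visual, dt, eps_sem=eps_s, eps_lex=eps_l)
    return state


class TestCoupledDynamics:
    def test_baseline_holds_without_input(self, control_model):
        """From the neutral initial state with no visual input, the lexical
        network must stay on its baseline attractor for at least 1 s."""
        rngs = [np.random.default_rng(s) for s in (3, 4, 5)]
        state = control_model.baseline_state(3, rngs=rngs)
        state = _free_run(control_model, state, int(1000 / 0.66), rngs)
        corr = control_model.corr_lex(state.x_lex)
        assert (corr[:, 16] > 0.95).all()
        assert (np.delete(corr, 16, axis=1) < 0.5).all()

    def test_word_presentation_drives_and_outlasts_input(self, control_model):
        """100 ms of visual drive on word 1 converges the lexical network on
        pattern 1, and the attractor persists after stimulus offset."""
        rngs = [np.random.default_rng(9)]
        state = control_model.baseline_state(1, rngs=rngs)
        visual = 0.56 * control_model.lex_patterns.patterns[[1]].astype(float)
        state = _free_run(control_model, state, int(100 / 0.66), rngs, visual=visual)
        state = _free_run(control_model, state, int(300 / 0.66), rngs)
        corr = control_model.corr_lex(state.x_lex)
        assert corr[0, 1] > 0.95
        assert np.delete(corr[0], 1).max() < 0.5

    def test_prime_chain_of_events(self, control_model):
        """Lexical convergence on the prime is followed, before target onset,
        by semantic convergence on the corresponding concept in nearly all
        control trials."""
        n = 40
        res = simulate_trials(
            control_model,
            primes=[0] * n,
            targets=[1] * n,
            soa=200.0,
            seeds=range(100, 100 + n),
        )
        chained = 0
        for lex_ev, sem_ev in zip(res.lex_events, res.sem_events):
            t_lex = [t for t, mu in lex_ev if mu == 0 and t <= 200.0]
            t_sem = [t for t, mu in sem_ev if mu == 0 and t <= 200.0]
            if t_lex and t_sem and t_sem[0] >= t_lex[0]:
                chained += 1
        assert chained / n > 0.9

    def test_batch_composition_invariance(self, control_model):
        """A trial's outcome depends only on its own seed, not on which
        other trials share the batch."""
        alone = simulate_trials(
            control_model, primes=[0], targets=[1], soa=200.0, seeds=[42]
        )
        together = simulate_trials(
            control_model,
            primes=[4, 0, 8],
            targets=[5, 1, 9],
            soa=200.0,
            seeds=[41, 42, 43],
        )
        assert together.rt[1] == alone.rt[0]
        assert together.sem_events[1] == alone.sem_events[0]

    def test_identical_seeds_identical_trajectories(self, control_model):
        runs = [
            simulate_trials(
                control_model, primes=[0], targets=[1], soa=200.0, seeds=[7],
                record_trajectory=True, timeout=200.0,
            )
            for _ in range(2)
        ]
        assert runs[0].rt[0] == runs[1].rt[0]
        assert np.array_equal(
            runs[0].sem_traj, runs[1].sem_traj, equal_nan=True
        )

    def test_topdown_ablation_removes_priming(self, control_model):
        """With the semantic-to-lexical gain at zero, related and unrelated
        targets are recognised equally fast: priming requires feedback."""
        from dataclasses import replace

        ablated = replace(control_model, g_sl=0.0)
        n = 30
        rel = simulate_trials(
            ablated, primes=[0] * n, targets=[1] * n, soa=200.0,
            seeds=range(500, 500 + n),
        )
        unrel = simulate_trials(
            ablated, primes=[0] * n, targets=[5] * n, soa=200.0,
            seeds=range(600, 600 + n),
        )
        diff = np.nanmean(unrel.rt) - np.nanmean(rel.rt)
        se = np.sqrt(
            np.nanvar(unrel.rt) / n + np.nanvar(rel.rt) / n
        )
        assert abs(diff) < max(3 * se, 3.0)

    def test_mean_activity_stays_regulated(self, control_model):
        """The regulation term keeps the semantic mean activity within a
        factor two of the coding sparseness p in converged epochs."""
        rngs = [np.random.default_rng(21)]
        state = control_model.baseline_state(1, rngs=rngs)
        state = _free_run(control_model, state, int(400 / 0.66), rngs)
        p = control_model.sem_params.p
        assert p / 2 < state.x_sem.mean() < 2 * p

    def test_rt_robust_to_halving_dt(self, control_model):
        """Integration-scheme check: halving the Euler step changes the
        pooled mean RT by less than 5%."""
        means = []
        for dt in (0.66, 0.33):
            cell_means = []
            for target, seed0 in ((1, 1000), (5, 2000)):  # related, unrelated
                res = simulate_trials(
                    control_model, primes=[0] * 40, targets=[target] * 40,
                    soa=200.0, seeds=range(seed0, seed0 + 40), dt=dt,
                )
                cell_means.append(np.nanmean(res.rt))
            means.append(np.mean(cell_means))
        assert abs(means[1] - means[0]) / means[0] < 0.05

    def test_nonfinite_state_raises(self, control_model):
        state = control_model.baseline_state(1)
        state.h_sem[:] = np.inf
        with np.errstate(invalid="ignore"), pytest.raises(FloatingPointError):
            coupled_step(control_model, state, None, 0.66)
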