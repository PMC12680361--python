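"""SSA engine: event statistics, conservation, determinism, bookkeeping."""

import numpy as np
import pytest

import lignosacc as L
from lignosacc.engine import draw_event, run_state, step
from lignosacc.kinetics import EnzymePool, class_rates


class TestStepStatistics:
    def test_waiting_time_mean_matches_total_propensity(self, free_config):
        """Drawn dt is exponential with the propensity sum as rate: the
        empirical mean over 1e4 draws lies within 3 s.e. of 1/A."""
        rng = np.random.default_rng(0)
        state = L.build_substrate(free_config, rng)
        params = L.KineticParams()
        pool = EnzymePool.from_cocktail(L.CocktailConfig())
        _cls, _dt, rates = draw_event(state, pool, params, rng)
        a_total = float(rates.sum())
        n = 10_000
        draws = np.array([draw_event(state, pool, params, rng)[1] for _ in range(n)])
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - 1.0 / a_total) < 3 * se

    def test_selection_frequencies_follow_propensities(self, free_config):
        """Event-class selection frequencies over 1e4 draws on a frozen
        catalogue match the propensity shares within 3 s.e. (binomial)."""
        params = L.KineticParams()
        state = L.build_substrate(free_config, np.random.default_rng(1))
        pool = EnzymePool.from_cocktail(L.CocktailConfig())
        rng = np.random.default_rng(2)
        n = 10_000
        counts = np.zeros(8)
        for _ in range(n):
            cls, _dt, rates = draw_event(state, pool, params, rng)
            counts[cls] += 1
        probs = rates / rates.sum()
        for k in np.flatnonzero(probs > 0.01):
            se = np.sqrt(probs[k] * (1 - probs[k]) / n)
            assert abs(counts[k] / n - probs[k]) < 3 * se + 1e-12

    def test_bgl_split_stoichiometry(self, free_config, rng):
        state = L.build_substrate(free_config, rng)
        state.pools["cellobiose"] = 5
        state.bgl_split()
        assert state.pools["cellobiose"] == 4
        assert state.pools["glucose"] == 2


class TestRunInvariants:
    def test_conversion_monotone_and_conserved(self, toy_config, small_cocktail):
        params = L.KineticParams().scale_kcat(5)
        checks = []

        def callback(state):
            checks.append(state.glucose_balance() == state.glucose_equivalents_total)

        state = L.build_substrate(toy_config, np.random.default_rng(3), 3)
        tr = run_state(
            state,
            small_cocktail,
            params,
            t_max=48.0,
            rng=np.random.default_rng(4),
            check_callback=callback,
        )
        assert checks and all(checks)
        assert (np.diff(tr.conversion) >= -1e-12).all()
        assert 0.0 <= tr.conversion[0] <= tr.conversion[-1] <= 100.0

    def test_fully_crystalline_indigestible_substrate_stays_at_zero(
        self, toy_config, small_cocktail, rng
    ):
        cfg = toy_config.with_(CF_cellu=1.0, CF_hemi=1.0, r_ca_cellu=0.0, r_ca_hemi=0.0)
        tr = L.run(cfg, small_cocktail, L.KineticParams(), t_max=48.0, rng=rng)
        assert tr.final_conversion() == 0.0

    def test_generous_rates_reach_exhaustion(self, free_config, small_cocktail, rng):
        cfg = free_config.with_(CF_cellu=0.0, CF_hemi=0.0)
        tr = L.run(cfg, small_cocktail, L.KineticParams().scale_kcat(100), t_max=1e4, rng=rng)
        assert tr.final_conversion() == pytest.approx(100.0)

    def test_zero_enzymes_give_flat_zero_trajectory(self, toy_config, rng):
        ck = L.CocktailConfig(total_enz_molecules=0)
        tr = L.run(toy_config, ck, L.KineticParams(), t_max=10.0, rng=rng)
        assert tr.events_applied == 0
        assert (tr.conversion == 0).all()

    def test_max_events_stop_condition(self, free_config, small_cocktail, rng):
        tr = L.run(
            free_config, small_cocktail, L.KineticParams(), t_max=1e4, max_events=10, rng=rng
        )
        assert tr.events_applied == 10

    def test_bgl_pool_decay_matches_rate_equation(self, cellulose_only):
        """BGL-only on a preloaded cellobiose pool: the mean pool decay
        over 200 replicates tracks the matched deterministic
        pseudo-Michaelis-Menten ODE within 3 s.e."""
        from scipy.integrate import solve_ivp

        params = L.KineticParams()
        ck = L.CocktailConfig(pct_EG=0.0, pct_CBH=0.0, pct_BGL=1.0, pct_XYL=0.0,
                              total_enz_molecules=5.0)
        cfg = L.SubstrateConfig(
            composition=cellulose_only,
            length_fibril=2,
            CF_cellu=1.0,
            r_ca_cellu=0.0,  # lattice inert: only the preloaded pool reacts
            free_floating=True,
        )
        n0, t_end, n_rep = 50, 2.0, 200
        omega0 = params.with_omega(0.0)

        def rhs(_t, y):
            return [-3600.0 * omega0.kcat_BGL * 5.0 * y[0] / (omega0.Km_BGL + y[0])]

        ode = solve_ivp(rhs, (0, t_end), [n0], dense_output=True)
        expected = float(ode.sol(t_end)[0])
        finals = []
        for k in range(n_rep):
            state = L.build_substrate(cfg, np.random.default_rng(k), 3)
            state.pools["cellobiose"] = n0
            state.glucose_equivalents_total += 2 * n0  # keep balance consistent
            tr = run_state(state, ck, omega0, t_max=t_end, rng=np.random.default_rng(1000 + k))
            finals.append(state.pools["cellobiose"])
        finals = np.asarray(finals, dtype=float)
        se = finals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(finals.mean() - expected) < 3 * max(se, 0.5)


class TestBookkeepingEquivalence:
    def test_incremental_registries_match_bruteforce_over_a_digestion(
        self, toy_config, small_cocktail
    ):
        """On a small shielded substrate, the incrementally maintained
        event catalogue, exposure flags and free ends equal a from-scratch
        reconstruction after every event."""
        rng = np.random.default_rng(42)
        state = L.build_substrate(toy_config, rng, 3)
        pool = EnzymePool.from_cocktail(small_cocktail)
        params = L.KineticParams().scale_kcat(50)
        for _ in range(1000):
            out = step(state, pool, params, rng)
            if out is None:
                break
            open_snap = [o.copy() for o in state.open_]
            snap = state.registry_snapshot()
            state.rebuild_open()
            state.rebuild_registries()
            assert all((a == b).all() for a, b in zip(open_snap, state.open_))
            assert snap == state.registry_snapshot()
            assert state.glucose_balance() == state.glucose_equivalents_total


class TestReplicateMean:
    def test_single_replicate_equals_one_run(self, free_config, small_cocktail):
        mean = L.replicate_mean(free_config, small_cocktail, n_rep=1, seed=7)
        child = np.random.SeedSequence(7).spawn(1)[0]
        single = L.run(free_config, small_cocktail, rng=np.random.default_rng(child))
        np.testing.assert_allclose(mean.conversion, single.conversion)

    def test_same_master_seed_is_deterministic(self, toy_config, small_cocktail):
        a = L.replicate_mean(toy_config, small_cocktail, n_rep=3, seed=11)
        b = L.replicate_mean(toy_config, small_cocktail, n_rep=3, seed=11)
        np.testing.assert_array_equal(a.conversion, b.conversion)
        np.testing.assert_array_equal(a.glucose, b.glucose)

    def test_sd_shrinks_with_replicate_count(self, free_config, small_cocktail):
        """Mean-of-means dispersion scales roughly as 1/sqrt(n_rep)."""
        means10, means40 = [], []
        for s in range(6):
            means10.append(
                L.replicate_mean(free_config, small_cocktail, n_rep=10, seed=100 + s)
                .final_conversion()
            )
            means40.append(
                L.replicate_mean(free_config, small_cocktail, n_rep=40, seed=200 + s)
                .final_conversion()
            )
        assert np.std(means40) < np.std(means10) * 1.5  # generous: 6-sample spread

    def test_inhibition_ordering_on_replicate_means(self, toy_config, small_cocktail):
        none = L.replicate_mean(
            toy_config, small_cocktail, L.KineticParams().with_omega(0.0), n_rep=20, seed=5
        )
        full = L.replicate_mean(
            toy_config, small_cocktail, L.KineticParams().with_omega(1.0), n_rep=20, seed=5
        )
        assert none.final_conversion() >= full.final_conversion()
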