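"""End-product inhibition, sequestration, propensities, eligibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lignosacc as L
from lignosacc.kinetics import EnzymePool, class_rates
from lignosacc.substrate import ConfigurationError


def make_pool(eg=10.0, cbh=10.0, bgl=10.0, xyl=0.0) -> EnzymePool:
    return EnzymePool(eg0=eg, cbh0=cbh, bgl0=bgl, xyl0=xyl)


class TestEffectiveConcentrations:
    def test_symmetric_worked_example(self):
        """[EG]0=[CBH]0=[BGL]0=10, glc=cbs=10, all omega=1:
        [EG] = 10 - 10*10/30 - 10*10/40 = 4.1667 and [BGL] = 7.5."""
        params = L.KineticParams().with_omega(1.0)
        pool = L.effective_concentrations(make_pool(), glc=10, cbs=10, params=params)
        assert pool.eg_eff == pytest.approx(10 - 100 / 30 - 100 / 40, abs=1e-9)
        assert pool.cbh_eff == pytest.approx(10 - 100 / 30 - 100 / 40, abs=1e-9)
        assert pool.bgl_eff == pytest.approx(7.5, abs=1e-9)

    def test_no_inhibition_strength_leaves_pool_nominal(self):
        params = L.KineticParams().with_omega(0.0)
        pool = L.effective_concentrations(make_pool(), glc=1e6, cbs=1e6, params=params)
        assert (pool.eg_eff, pool.cbh_eff, pool.bgl_eff) == (10.0, 10.0, 10.0)

    def test_zero_inhibitor_pools_leave_pool_nominal(self):
        params = L.KineticParams().with_omega(1.0)
        pool = L.effective_concentrations(make_pool(), glc=0, cbs=0, params=params)
        assert (pool.eg_eff, pool.cbh_eff, pool.bgl_eff) == (10.0, 10.0, 10.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            L.effective_concentrations(make_pool(), glc=-1, cbs=0, params=L.KineticParams())

    def test_clamped_at_zero_in_extreme_regime(self):
        params = L.KineticParams().with_omega(1.0)
        pool = L.effective_concentrations(make_pool(), glc=1e9, cbs=1e9, params=params)
        assert pool.eg_eff >= 0.0 and pool.cbh_eff >= 0.0 and pool.bgl_eff >= 0.0

    @given(w=st.floats(0.0, 1.0), seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_in_each_inhibitor(self, w, seed):
        """Over a 20x20 inhibitor grid, effective concentrations never
        increase along either axis."""
        params = L.KineticParams().with_omega(w)
        grid = np.linspace(0, 200, 20)
        eff = np.empty((20, 20, 3))
        for i, glc in enumerate(grid):
            for j, cbs in enumerate(grid):
                p = L.effective_concentrations(make_pool(), glc=glc, cbs=cbs, params=params)
                eff[i, j] = (p.eg_eff, p.cbh_eff, p.bgl_eff)
        assert (np.diff(eff, axis=0) <= 1e-9).all()
        assert (np.diff(eff, axis=1) <= 1e-9).all()

    def test_equality_to_nominal_only_without_inhibition(self):
        params = L.KineticParams().with_omega(0.4)
        p = L.effective_concentrations(make_pool(), glc=5, cbs=5, params=params)
        assert p.eg_eff < 10.0 and p.cbh_eff < 10.0 and p.bgl_eff < 10.0


class TestLigninSequestration:
    def test_no_lignin_no_sequestration(self):
        pool = L.lignin_sequestration(make_pool(), lignin_units=0, adhesion_rate=100)
        assert pool.seq_eg == pool.seq_cbh == pool.seq_bgl == pool.seq_xyl == 0.0

    def test_floor_rule_and_proportional_split(self):
        pool = L.lignin_sequestration(
            make_pool(eg=10, cbh=10, bgl=10, xyl=0), lignin_units=300, adhesion_rate=100
        )
        total_seq = pool.seq_eg + pool.seq_cbh + pool.seq_bgl + pool.seq_xyl
        assert total_seq == pytest.approx(3.0)
        assert pool.seq_eg == pytest.approx(1.0)

    def test_weaker_adsorption_sequesters_fewer(self):
        strong = L.lignin_sequestration(make_pool(), lignin_units=700, adhesion_rate=100)
        weak = L.lignin_sequestration(make_pool(), lignin_units=700, adhesion_rate=350)
        s = strong.seq_eg + strong.seq_cbh + strong.seq_bgl
        w = weak.seq_eg + weak.seq_cbh + weak.seq_bgl
        assert w < s

    def test_invalid_adhesion_rate(self):
        with pytest.raises(ConfigurationError):
            L.lignin_sequestration(make_pool(), lignin_units=10, adhesion_rate=0)


class TestStericWindow:
    def test_default_radius_gives_three_monomers(self):
        assert L.steric_window(2.5, 0.6) == 3

    @given(r=st.floats(0.5, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_window_nondecreasing_in_radius(self, r):
        assert L.steric_window(r + 1.0, 0.6) >= L.steric_window(r, 0.6)


class TestEligibleTargets:
    def test_fully_exposed_chain_has_196_eg_targets(self, cellulose_only, rng):
        """A free 200-bond chain: all bonds except the two endmost at each
        end are endoglucanase targets."""
        comp = L.Composition(pct_cellulose=1.0, sample_id="one")
        cfg = L.SubstrateConfig(
            composition=comp, mode_code=3, length_fibril=200, free_floating=True, CF_cellu=0.0
        )
        state = L.build_free_substrate(cfg, rng)
        per_chain = {}
        for (c, i) in L.eligible_targets("EG", state):
            per_chain.setdefault(c, 0)
            per_chain[c] += 1
        assert all(n == 196 for n in per_chain.values())

    def test_three_monomer_fragment_has_no_eg_targets(self, rng):
        comp = L.Composition(pct_cellulose=1.0, sample_id="frag")
        cfg = L.SubstrateConfig(
            composition=comp, length_fibril=2, free_floating=True, CF_cellu=0.0
        )
        state = L.build_free_substrate(cfg, rng)
        assert not L.eligible_targets("EG", state)

    def test_empty_cellobiose_pool_means_no_bgl_targets(self, free_config, rng):
        state = L.build_free_substrate(free_config, rng)
        assert not L.eligible_targets("BGL", state)

    def test_hemicellulase_targets_include_endmost_bonds(self, rng):
        comp = L.Composition(pct_cellulose=0.3, pct_hemicellulose=0.3, sample_id="h")
        cfg = L.SubstrateConfig(composition=comp, length_fibril=20, free_floating=True)
        state = L.build_free_substrate(cfg, rng)
        hemi_bonds = sum(ch.n_bonds for ch in state.chains if ch.kind == "hemicellulose")
        assert len(L.eligible_targets("XYL", state)) == hemi_bonds

    def test_larger_enzyme_never_gains_targets(self, toy_config):
        """Steric monotonicity: growing the window can only shrink the
        eligible sets on the same substrate."""
        counts = []
        for h in (1, 2, 3, 5, 8):
            state = L.build_substrate(toy_config, np.random.default_rng(99), steric_window=h)
            counts.append(
                len(L.eligible_targets("EG", state))
                + len(L.eligible_targets("XYL", state))
                + len(L.eligible_targets("CBH", state))
            )
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPropensities:
    def test_equal_rates_when_digestibility_ratio_is_one(self, free_config, rng):
        state = L.build_substrate(free_config.with_(r_ca_cellu=1.0, r_ca_hemi=1.0), rng)
        pool = EnzymePool.from_cocktail(L.CocktailConfig())
        params = L.KineticParams()
        pool = L.effective_concentrations(pool, 0, 0, params)
        rates = class_rates(state, pool, params)
        # per-target EG rate equal for amorphous and crystalline classes
        per_am = rates[0] / max(len(state.eg_am), 1)
        per_cr = rates[1] / max(len(state.eg_cr), 1)
        assert per_am == pytest.approx(per_cr)

    def test_zero_ratio_makes_crystalline_indigestible(self, free_config, rng):
        state = L.build_substrate(free_config.with_(r_ca_cellu=0.0, r_ca_hemi=0.0), rng)
        pool = EnzymePool.from_cocktail(L.CocktailConfig())
        params = L.KineticParams()
        pool = L.effective_concentrations(pool, 0, 0, params)
        rates = class_rates(state, pool, params)
        assert rates[1] == 0.0 and rates[3] == 0.0

    def test_total_propensity_scales_with_kcat_and_enzyme(self, free_config, rng):
        state = L.build_substrate(free_config, rng)
        params = L.KineticParams()
        pool = L.effective_concentrations(
            EnzymePool.from_cocktail(L.CocktailConfig()), 0, 0, params
        )
        base = class_rates(state, pool, params)[0]
        doubled_k = class_rates(state, pool, params.with_(kcat_EG=2 * params.kcat_EG))[0]
        assert doubled_k == pytest.approx(2 * base)
        pool2 = L.effective_concentrations(
            EnzymePool.from_cocktail(L.CocktailConfig(total_enz_molecules=100)), 0, 0, params
        )
        assert class_rates(state, pool2, params)[0] == pytest.approx(2 * base)

    def test_cocktail_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            L.CocktailConfig(pct_EG=0.5, pct_CBH=0.5, pct_BGL=0.5, pct_XYL=0.0)
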