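"""Substrate construction: lattice, crystallinity, exposure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lignosacc as L
from lignosacc.substrate import ConfigurationError, _core_positions


class TestAssignCrystallinity:
    @given(
        n_bonds=st.integers(5, 300),
        cf=st.floats(0.0, 1.0),
        mu=st.floats(0.0, 0.5),
        nd=st.floats(0.0, 1.0),
        outer=st.booleans(),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_crystalline_count_is_exact(self, n_bonds, cf, mu, nd, outer, seed):
        """Exactly round(CF * L) bonds end up crystalline, for any defect
        parameters and seed."""
        rng = np.random.default_rng(seed)
        cryst = L.assign_crystallinity(n_bonds, cf, mu, nd, outer, rng)
        assert int(cryst.sum()) == round(cf * n_bonds)

    @pytest.mark.parametrize("cf,expected", [(0.0, 0), (1.0, 200)])
    def test_degenerate_fractions(self, cf, expected, rng):
        cryst = L.assign_crystallinity(200, cf, 0.3, 1.0, True, rng)
        assert int(cryst.sum()) == expected

    def test_no_defects_puts_amorphous_at_ends(self, rng):
        """mu_defect=0: the amorphous allotment splits between the two chain
        ends (tie to the left), crystalline bonds form one contiguous block."""
        cryst = L.assign_crystallinity(200, 0.5, 0.0, 1.0, True, rng)
        assert int(cryst.sum()) == 100
        assert not cryst[:50].any()
        assert cryst[50:150].all()
        assert not cryst[150:].any()

    def test_odd_amorphous_ties_to_left_end(self, rng):
        cryst = L.assign_crystallinity(10, 0.5, 0.0, 0.0, False, rng)
        # 5 amorphous: 3 left, 2 right
        assert not cryst[:3].any() and cryst[3:8].all() and not cryst[8:].any()

    def test_defect_patches_sit_inside_crystalline_region(self):
        rng = np.random.default_rng(5)
        cryst = L.assign_crystallinity(200, 0.6, 0.5, 1.0, True, rng)
        assert int(cryst.sum()) == 120
        # 80 amorphous: 40 in defects, 40 at the ends (20 + 20)
        amorph_runs = np.flatnonzero(~cryst)
        assert (amorph_runs < 20).sum() == 20
        assert (amorph_runs >= 180).sum() == 20
        interior = amorph_runs[(amorph_runs >= 20) & (amorph_runs < 180)]
        assert len(interior) == 40

    def test_inner_chains_never_carry_defects(self, rng):
        cryst = L.assign_crystallinity(100, 0.5, 0.5, 1.0, False, rng)
        # all amorphous bonds at the ends
        assert cryst[25:75].all()

    def test_cf_out_of_range_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            L.assign_crystallinity(100, 1.2, 0.0, 0.0, False, rng)


class TestMicrofibrilBuild:
    @pytest.mark.parametrize("mode,n_chains", [(1, 24), (3, 18), (4, 18), (5, 36)])
    def test_core_chain_count_follows_mode_code(self, mode, n_chains, toy_composition, rng):
        cfg = L.SubstrateConfig(composition=toy_composition, mode_code=mode, length_fibril=20)
        state = L.build_microfibril(cfg, rng)
        cellulose = [ch for ch in state.chains if ch.kind == "cellulose"]
        assert len(cellulose) == n_chains
        assert all(ch.n_bonds == 20 for ch in cellulose)

    def test_default_mode_gives_3600_cellulose_bonds(self, cellulose_only, rng):
        cfg = L.SubstrateConfig(composition=cellulose_only, mode_code=3, length_fibril=200)
        state = L.build_microfibril(cfg, rng)
        n_bonds = sum(ch.n_bonds for ch in state.chains if ch.kind == "cellulose")
        assert n_bonds == 18 * 200

    def test_unknown_mode_code_rejected(self, cellulose_only):
        with pytest.raises(ConfigurationError):
            L.SubstrateConfig(composition=cellulose_only, mode_code=7)

    def test_zero_cellulose_rejected(self):
        with pytest.raises(ConfigurationError):
            L.Composition(pct_cellulose=0.0) and L.SubstrateConfig(
                composition=L.Composition(pct_cellulose=0.0)
            )

    def test_pure_cellulose_has_empty_shells_and_full_surface_exposure(
        self, cellulose_only, rng
    ):
        cfg = L.SubstrateConfig(composition=cellulose_only, length_fibril=20)
        state = L.build_microfibril(cfg, rng)
        assert state.lignin_units == 0
        assert state.xylose_equivalents_total == 0
        # every bond of every boundary chain must be reachable
        for c, ch in enumerate(state.chains):
            if ch.kind == "cellulose" and ch.is_outer:
                assert all(state.bond_open(c, i) for i in range(ch.n_bonds))

    def test_shell_budgets_follow_composition_ratios(self, toy_config, rng):
        state = L.build_microfibril(toy_config, rng)
        c_total = 18 * 21
        comp = toy_config.composition
        expect_hemi = round(c_total * comp.pct_hemicellulose / comp.pct_cellulose)
        expect_lign = round(c_total * comp.pct_lignin / comp.pct_cellulose)
        assert abs(state.xylose_equivalents_total - expect_hemi) <= 2
        assert abs(state.lignin_units - expect_lign) <= 2

    def test_microfibril_shields_some_bonds(self, toy_config, rng):
        state = L.build_microfibril(toy_config, rng)
        assert 0.0 < state.exposure_fraction() < 1.0

    def test_interior_core_chains_start_shielded(self, cellulose_only, rng):
        cfg = L.SubstrateConfig(composition=cellulose_only, length_fibril=20)
        state = L.build_microfibril(cfg, rng)
        inner = [c for c, ch in enumerate(state.chains) if ch.kind == "cellulose" and not ch.is_outer]
        assert inner  # the 18-chain cross-section has interior chains
        for c in inner:
            assert not any(state.bond_open(c, i) for i in range(state.chains[c].n_bonds))


class TestFreeSubstrate:
    def test_everything_exposed(self, free_config, rng):
        state = L.build_free_substrate(free_config, rng)
        assert state.exposure_fraction() == 1.0

    def test_zero_lignin_means_no_adsorber_pool(self, cellulose_only, rng):
        cfg = L.SubstrateConfig(composition=cellulose_only, free_floating=True, length_fibril=20)
        state = L.build_free_substrate(cfg, rng)
        assert state.lignin_units == 0

    def test_dissolved_lignin_does_not_shield(self, rng):
        plain = L.Composition(pct_cellulose=0.4, sample_id="a")
        mixed = L.Composition(pct_cellulose=0.4, pct_lignin=0.5, sample_id="b")
        st_a = L.build_free_substrate(
            L.SubstrateConfig(composition=plain, free_floating=True, length_fibril=20),
            np.random.default_rng(0),
        )
        st_b = L.build_free_substrate(
            L.SubstrateConfig(composition=mixed, free_floating=True, length_fibril=20),
            np.random.default_rng(0),
        )
        assert st_b.lignin_units > 0
        assert st_a.exposure_fraction() == st_b.exposure_fraction() == 1.0

    def test_dispatch_checks_flag(self, toy_config, free_config, rng):
        with pytest.raises(ConfigurationError):
            L.build_free_substrate(toy_config, rng)
        with pytest.raises(ConfigurationError):
            L.build_microfibril(free_config, rng)


class TestAverageCrystallinity:
    def test_equal_components_give_that_fraction(self, toy_config, rng):
        state = L.build_substrate(toy_config.with_(CF_cellu=0.37, CF_hemi=0.37), rng)
        # per-chain rounding leaves at most a small discretisation error
        assert L.average_crystallinity(state) == pytest.approx(0.37, abs=0.02)

    def test_no_hemicellulose_returns_cellulose_cf(self, cellulose_only, rng):
        cfg = L.SubstrateConfig(composition=cellulose_only, CF_cellu=0.22, length_fibril=100)
        assert L.average_crystallinity(cfg) == pytest.approx(0.22)
        state = L.build_substrate(cfg, rng)
        assert L.average_crystallinity(state) == pytest.approx(0.22, abs=0.005)

    def test_config_level_average_weights_by_monomer_budget(self, toy_composition):
        cfg = L.SubstrateConfig(composition=toy_composition, CF_cellu=0.6, CF_hemi=0.2)
        avg = L.average_crystallinity(cfg)
        assert 0.2 < avg < 0.6
        w_hemi = toy_composition.pct_hemicellulose / (
            toy_composition.pct_cellulose + toy_composition.pct_hemicellulose
        )
        assert avg == pytest.approx(0.6 * (1 - w_hemi) + 0.2 * w_hemi)


class TestLatticeGeometry:
    @pytest.mark.parametrize("n", [18, 24, 36])
    def test_core_positions_are_distinct_and_counted(self, n):
        pos = _core_positions(n)
        assert len(set(pos)) == n

    def test_snapshot_roundtrips_as_json(self, toy_config, rng):
        import json

        state = L.build_substrate(toy_config, rng)
        payload = json.loads(state.to_json())
        assert payload["config"]["mode_code"] == toy_config.mode_code
        assert len(payload["chains"]) == len(state.chains)
        assert payload["exposed_bonds"]
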