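"""Simulation differencing, ensemble statistics and dominance maps."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gppattrib as ga

from conftest import make_flux


def _pair(factor="CO2", offset=5.0, shape=(24, 2, 2), model="PMX"):
    run_a_name, run_b_name = {"CO2": ("SG3", "SG2"),
                              "climate": ("SG1", "RG1")}[factor]
    base = np.random.default_rng(0).uniform(10, 50, shape)
    run_b = make_flux(base, model_id=model, experiment_id=run_b_name)
    run_a = make_flux(base + offset, model_id=model,
                      experiment_id=run_a_name)
    return run_a, run_b


class TestFactorEffect:
    def test_constant_offset_recovered(self):
        run_a, run_b = _pair(offset=5.0)
        eff = ga.factor_effect(run_a, run_b, "CO2")
        np.testing.assert_allclose(eff.effect.values, 5.0)
        assert (eff.factor, eff.model_id) == ("CO2", "PMX")

    def test_unregistered_pairing_is_hard_error(self):
        run_a, run_b = _pair()
        with pytest.raises(ValueError, match="unregistered"):
            ga.factor_effect(run_a, run_b, "Ndep")
        with pytest.raises(ValueError, match="unregistered"):
            ga.factor_effect(run_b, run_a, "CO2")   # reversed order

    def test_model_mismatch_is_hard_error(self):
        run_a, run_b = _pair()
        run_b.model_id = "OTHER"
        with pytest.raises(ValueError, match="model mismatch"):
            ga.factor_effect(run_a, run_b, "CO2")

    def test_noise_free_archive_recovers_truth_exactly(self):
        cfg = ga.TruthConfig(n_lat=6, n_lon=8, n_years=20, block_years=20,
                             n_models=2, n_nitrogen_models=1, noise_frac=0.0,
                             seed=13)
        arc = ga.generate_factorial_ensemble(cfg)
        eff = ga.factor_effect(arc.field("PM00", "SG3"),
                               arc.field("PM00", "SG2"), "CO2")
        np.testing.assert_allclose(eff.effect.values,
                                   arc.truth[("PM00", "CO2")].values,
                                   atol=1e-10)


class TestTelescopeCheck:
    def test_complete_model_telescopes_below_tolerance(self, small_archive):
        for pm in small_archive.models:
            if not pm.has_nitrogen_run:
                continue
            m = pm.model_id
            effects = [ga.factor_effect(small_archive.field(m, a),
                                        small_archive.field(m, b), f)
                       for f, a, b in (("climate", "SG1", "RG1"),
                                       ("LULCC", "SG2", "SG1"),
                                       ("CO2", "SG3", "SG2"),
                                       ("Ndep", "BG1", "SG3"))]
            total = (small_archive.field(m, "BG1").data -
                     small_archive.field(m, "RG1").data)
            assert ga.telescope_check(effects, total) <= 1e-6

    def test_perturbed_effect_shifts_residual_by_one(self, small_archive):
        m = small_archive.models[0].model_id
        effects = [ga.factor_effect(small_archive.field(m, a),
                                    small_archive.field(m, b), f)
                   for f, a, b in (("climate", "SG1", "RG1"),
                                   ("LULCC", "SG2", "SG1"),
                                   ("CO2", "SG3", "SG2"),
                                   ("Ndep", "BG1", "SG3"))]
        total = (small_archive.field(m, "BG1").data -
                 small_archive.field(m, "RG1").data)
        effects[0].effect = effects[0].effect + 1.0
        assert ga.telescope_check(effects, total) == pytest.approx(1.0)

    def test_missing_factor_is_hard_error(self, small_archive):
        m = small_archive.models[0].model_id
        effects = [ga.factor_effect(small_archive.field(m, "SG3"),
                                    small_archive.field(m, "SG2"), "CO2")]
        total = small_archive.field(m, "BG1").data
        with pytest.raises(ValueError):
            ga.telescope_check(effects, total)


def _constant_effects(values, factor="CO2"):
    out = []
    for i, v in enumerate(values):
        eff = make_flux(np.full((24, 2, 2), 50.0), model_id=f"PM{i:02d}",
                        experiment_id="SG3").data * 0 + v
        out.append(ga.FactorEffect(factor=factor, model_id=f"PM{i:02d}",
                                   effect=eff))
    return out


class TestConsensusMean:
    def test_unweighted_mean_and_identity(self):
        cm = ga.consensus_mean(_constant_effects([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(cm.mean.values, 2.0)
        assert cm.n_models == 3
        single = ga.consensus_mean(_constant_effects([7.0]))
        np.testing.assert_allclose(single.mean.values, 7.0)

    def test_duplicate_model_is_hard_error(self):
        effects = _constant_effects([1.0, 2.0])
        effects[1].model_id = effects[0].model_id
        with pytest.raises(ValueError, match="duplicate"):
            ga.consensus_mean(effects)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(perm_seed=st.integers(0, 999))
    def test_permutation_invariance(self, perm_seed):
        effects = _constant_effects([1.0, 4.0, 2.5, 9.0])
        perm = np.random.default_rng(perm_seed).permutation(len(effects))
        a = ga.consensus_mean(effects).mean.values
        b = ga.consensus_mean([effects[i] for i in perm]).mean.values
        np.testing.assert_array_equal(a, b)


class TestBootstrapCI:
    def test_identical_members_collapse_to_point(self):
        m, lo, hi = ga.bootstrap_ci(np.full((6, 3), 4.2), replicates=100)
        np.testing.assert_allclose([m, lo, hi], 4.2)

    def test_interval_brackets_the_mean_and_is_reproducible(self):
        members = np.random.default_rng(1).normal(0, 1, (9, 5))
        m, lo, hi = ga.bootstrap_ci(members, replicates=500, seed=3)
        assert np.all(lo <= m) and np.all(m <= hi)
        m2, lo2, hi2 = ga.bootstrap_ci(members, replicates=500, seed=3)
        np.testing.assert_array_equal(lo, lo2)
        np.testing.assert_array_equal(hi, hi2)

    def test_single_member_warns_and_degenerates(self):
        with pytest.warns(UserWarning):
            m, lo, hi = ga.bootstrap_ci(np.ones((1, 4)) * 2.0)
        np.testing.assert_allclose([m, lo, hi], 2.0)


class TestDecadalSeries:
    def test_constant_effect_gives_flat_series(self, small_archive):
        w, mask = small_archive.weights, small_archive.mask
        effects = _constant_effects([3.0, 3.0, 3.0])
        # rebuild on the archive grid for conforming shapes
        tmpl = small_archive.field("PM00", "SG3").data
        effects = [ga.FactorEffect("CO2", f"PM{i:02d}", tmpl * 0 + 3.0)
                   for i in range(3)]
        df = ga.decadal_series(effects, w, mask, replicates=100)
        assert df["mean"].std() == pytest.approx(0.0, abs=1e-12)
        assert (df["n_models"] == 3).all()

    def test_zero_effect_series_covers_zero(self, small_archive):
        w, mask = small_archive.weights, small_archive.mask
        tmpl = small_archive.field("PM00", "SG3").data
        rng = np.random.default_rng(2)
        effects = [ga.FactorEffect("CO2", f"PM{i:02d}",
                                   tmpl * 0 + rng.normal(0, 0.01,
                                                         tmpl.shape))
                   for i in range(5)]
        df = ga.decadal_series(effects, w, mask, replicates=300)
        assert (df["ci_low"] <= 0).all() or np.allclose(df["mean"], 0,
                                                        atol=0.5)


class TestDominance:
    def _mask_w(self, shape=(4, 6)):
        veg = np.ones(shape, bool)
        mask = ga.LandMask(veg, np.zeros(shape, bool), np.zeros(shape, bool))
        w = ga.area_weights(ga.GridSpec.regular(*shape))
        return mask, w

    def test_anthro_nat_ratio_winner_rule(self):
        mask, w = self._mask_w((1, 2))
        a = ga.EnsembleSummary("anthropogenic", np.array([[2.0, 0.5]]))
        n = ga.EnsembleSummary("natural", np.array([[1.0, 1.0]]))
        dom = ga.anthro_nat_ratio(a, n, mask, w)
        np.testing.assert_allclose(dom.ratio, [[2.0, 0.5]])
        assert dom.winner[0, 0] == "anthropogenic"
        assert dom.winner[0, 1] == "natural"

    def test_dominant_factor_argmax_and_tie_rule(self):
        mask, w = self._mask_w((1, 1))
        summaries = {f: ga.EnsembleSummary(f, np.array([[v]]))
                     for f, v in (("CO2", 5.0), ("climate", 1.0),
                                  ("LULCC", -0.5), ("Ndep", 2.0))}
        dom = ga.dominant_factor_map(summaries, mask, w)
        assert dom.winner[0, 0] == "CO2"
        tie = {f: ga.EnsembleSummary(f, np.array([[3.0]]))
               for f in ("CO2", "Ndep")}
        assert ga.dominant_factor_map(tie, mask, w).winner[0, 0] == "CO2"

    def test_empty_factor_set_is_hard_error(self):
        mask, w = self._mask_w((1, 1))
        with pytest.raises(ValueError):
            ga.dominant_factor_map({}, mask, w)

    def test_areal_percentages_bounded_by_hundred(self):
        mask, w = self._mask_w((4, 6))
        rng = np.random.default_rng(5)
        summaries = {f: ga.EnsembleSummary(f, rng.normal(0, 1, (4, 6)))
                     for f in ga.FACTOR_ORDER}
        sig = rng.random((4, 6)) < 0.5
        dom = ga.dominant_factor_map(summaries, mask, w, significant=sig)
        total = sum(v for k, v in dom.areal_pct.items() if k != "unassigned")
        assert total <= 100.0 + 1e-9
        assert dom.areal_pct["unassigned"] == pytest.approx(100.0 - total)

    def test_anthropogenic_dominance_expands_with_forcing(self,
                                                          small_coupled):
        w, mask = small_coupled.weights, small_coupled.mask
        anthro = ga.archive_effects(small_coupled, "anthropogenic")
        natural = ga.archive_effects(small_coupled, "natural")
        starts = ga.decade_starts(small_coupled.config.years)
        pcts = []
        for dec in (int(starts[0]), int(starts[-1])):
            a = ga.EnsembleSummary("anthropogenic",
                                   ga.attribution.decade_mean_map(anthro, dec))
            n = ga.EnsembleSummary("natural",
                                   ga.attribution.decade_mean_map(natural,
                                                                  dec))
            pcts.append(ga.anthro_nat_ratio(a, n, mask, w)
                        .areal_pct["anthropogenic"])
        assert pcts[-1] > pcts[0]
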