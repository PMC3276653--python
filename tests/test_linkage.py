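"""Interval mapping: transmission HMM, scans, thresholds, confidence intervals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subtypeqtl import (
    MarkerMap,
    QTLScanResult,
    SimulationConfig,
    adjust_phenotype,
    empirical_threshold,
    haldane_recombination,
    leave_one_subtype_out_scans,
    lod_drop_ci,
    scan_chromosome,
    simulate_study,
    transmission_probabilities,
)
from subtypeqtl.linkage import LOD_PER_LRT

from conftest import brute_force_posterior


def _profile(obs_rows, positions, grid=None, names=None):
    names = names or [f"M{i}" for i in range(len(positions))]
    mm = MarkerMap(names=tuple(names), positions=np.asarray(positions, dtype=float))
    inherit = pd.DataFrame(
        np.asarray(obs_rows, dtype=float),
        index=[f"a{i}" for i in range(len(obs_rows))],
        columns=names,
    )
    inherit = inherit.replace(0.0, np.nan)
    return transmission_probabilities(inherit, mm, grid=grid)


class TestAdjustPhenotype:
    def _pheno(self, n, rng, hatch_shift=0.0):
        hatch = rng.integers(1, 3, size=n)
        return pd.DataFrame(
            {
                "trait": rng.normal(size=n) + hatch_shift * (hatch == 2),
                "hatch": hatch,
                "dam": rng.integers(1, 4, size=n),
                "body_weight": rng.normal(size=n),
            },
            index=[f"a{i}" for i in range(n)],
        )

    def test_no_injected_effects_returns_centered_trait(self, rng):
        pheno = self._pheno(400, rng)
        adj = adjust_phenotype(pheno)
        assert abs(adj.mean()) < 1e-10
        # adjustment only removes what the design explains (little, here)
        assert np.corrcoef(adj, pheno["trait"] - pheno["trait"].mean())[0, 1] > 0.98

    def test_injected_hatch_shift_removed(self, rng):
        pheno = self._pheno(300, rng, hatch_shift=10.0)
        adj = adjust_phenotype(pheno)
        means = adj.groupby(pheno["hatch"]).mean()
        assert np.abs(means).max() < 0.3

    def test_residuals_orthogonal_to_design(self, rng):
        pheno = self._pheno(120, rng, hatch_shift=2.0)
        adj = adjust_phenotype(pheno).to_numpy()
        assert abs(adj @ pheno["body_weight"].to_numpy()) < 1e-8
        for level in pheno["dam"].unique():
            assert abs(adj[(pheno["dam"] == level).to_numpy()].sum()) < 1e-8

    def test_singleton_level_pooled_with_warning(self, rng):
        pheno = self._pheno(40, rng)
        pheno.iloc[0, pheno.columns.get_loc("dam")] = 99
        with pytest.warns(UserWarning, match="pooled"):
            adjust_phenotype(pheno)


class TestTransmissionProbabilities:
    def test_informative_marker_is_certain(self):
        prof = _profile([[1, 2]], [10.0, 30.0], grid=[10.0, 30.0])
        np.testing.assert_allclose(prof.pi.iloc[0].to_numpy(), [1.0, 0.0], atol=1e-12)

    def test_midpoint_between_concordant_flankers(self):
        # flankers 10 cM apart, both Q-origin; posterior at the midpoint is
        # (1-c)^2 / ((1-c)^2 + c^2) with c = Haldane(5 cM)
        prof = _profile([[1, 1]], [0.0, 10.0], grid=[5.0])
        c = haldane_recombination(5.0)
        expected = (1 - c) ** 2 / ((1 - c) ** 2 + c ** 2)
        assert prof.pi.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.99752, abs=5e-5)

    def test_conflicting_flankers_at_equal_distance(self):
        prof = _profile([[1, 2]], [0.0, 10.0], grid=[5.0])
        assert prof.pi.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_unknown_markers_are_uninformative(self):
        known = _profile([[1, 0, 1]], [0.0, 10.0, 20.0], grid=[10.0])
        no_middle = _profile([[1, 1]], [0.0, 20.0], grid=[10.0])
        assert known.pi.iloc[0, 0] == pytest.approx(no_middle.pi.iloc[0, 0], abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        # exact equality (1e-10) with full path enumeration, <= 6 markers
        for _ in range(60):
            n_mark = int(rng.integers(2, 7))
            pos = np.sort(rng.uniform(0, 100, size=n_mark))
            pos += np.arange(n_mark) * 1e-3  # ensure strictly increasing
            obs = rng.integers(0, 3, size=n_mark)
            grid_pos = float(rng.uniform(0, 100))
            all_pos = np.sort(np.append(pos, grid_pos))
            qidx = int(np.searchsorted(all_pos, grid_pos))
            full_obs = np.zeros(len(all_pos), dtype=int)
            for p, o in zip(pos, obs):
                full_obs[np.searchsorted(all_pos, p)] = o
            expected = brute_force_posterior(all_pos, full_obs, qidx)
            prof = _profile([obs], pos, grid=[grid_pos])
            assert prof.pi.iloc[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_impossible_origin_path_flagged(self):
        # conflicting observations across a zero-distance transition have
        # zero likelihood; flagged, never silently dropped
        from subtypeqtl.linkage import _forward_backward

        with pytest.warns(UserWarning, match="inconsistent"):
            post = _forward_backward(np.array([1, 2]), np.array([0.0]))
        np.testing.assert_allclose(post, 0.5)


class TestScan:
    def _study_profile(self, seed=17, **kw):
        cfg = SimulationConfig(n_genes=10, n_trait_genes=2, n_distal_eqtl_genes=0,
                               n_interacting_eqtl_genes=0, **kw)
        study = simulate_study(cfg, seed=seed)
        prof = transmission_probabilities(
            study.inheritance, study.marker_map, chromosome_length=cfg.chromosome_length
        )
        return study, prof

    def test_lrt_nonnegative_and_max_consistent(self):
        study, prof = self._study_profile()
        scan = scan_chromosome(adjust_phenotype(study.phenotypes), prof)
        assert (scan.lrt >= 0).all()
        assert scan.max_lrt == scan.lrt.max()
        assert scan.ci[0] <= scan.max_pos <= scan.ci[1]

    def test_affine_trait_transform_leaves_lrt_unchanged(self):
        study, prof = self._study_profile()
        y = adjust_phenotype(study.phenotypes)
        a = scan_chromosome(y, prof)
        b = scan_chromosome(3.7 * y - 11.0, prof)
        np.testing.assert_allclose(a.lrt, b.lrt, atol=1e-9)

    def test_zero_variance_trait_rejected(self):
        study, prof = self._study_profile()
        y = pd.Series(1.0, index=study.phenotypes.index)
        with pytest.raises(ValueError, match="variance"):
            scan_chromosome(y, prof)

    def test_effect_sign_and_size_recovered_at_strong_qtl(self):
        study, prof = self._study_profile(
            seed=23, effect_distal=1.5, effect_proximal_given_distal_Q=0.0,
            effect_proximal_given_distal_q=0.0, missing_marker_rate=0.0,
        )
        scan = scan_chromosome(adjust_phenotype(study.phenotypes), prof)
        assert scan.ci[0] <= 168.0 <= scan.ci[1]
        assert abs(scan.max_pos - 168.0) < 30
        assert scan.effect > 0.75  # Q-q difference, trait units


class TestEmpiricalThreshold:
    def test_level_one_returns_minimum(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        thr = empirical_threshold(prof, n_sim=200, level=1.0, rng=0)
        assert thr.value == pytest.approx(thr.maxima.min())

    def test_threshold_monotone_decreasing_in_level(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        rng = np.random.default_rng(5)
        t10 = empirical_threshold(prof, n_sim=400, level=0.10, rng=rng)
        rng = np.random.default_rng(5)
        t01 = empirical_threshold(prof, n_sim=400, level=0.01, rng=rng)
        assert t01.value > t10.value

    def test_stability_under_doubled_nsim(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        t1 = empirical_threshold(prof, n_sim=1000, rng=1)
        t2 = empirical_threshold(prof, n_sim=2000, rng=2)
        # bootstrap SE of the 95% quantile at n=1000 is ~0.25 here
        boot = np.random.default_rng(3)
        ses = np.std(
            [np.quantile(boot.choice(t1.maxima, size=1000), 0.95) for _ in range(200)]
        )
        assert abs(t1.value - t2.value) < 4 * ses + 0.2

    def test_too_few_simulations_rejected(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        with pytest.raises(ValueError, match="n_sim"):
            empirical_threshold(prof, n_sim=50)


class TestLodDropCI:
    def _scan_from_curve(self, positions, lrt):
        i = int(np.argmax(lrt))
        return QTLScanResult(
            positions=np.asarray(positions, dtype=float),
            lrt=np.asarray(lrt, dtype=float),
            max_pos=float(positions[i]),
            max_lrt=float(lrt[i]),
            effect=0.0,
            effect_sd=0.0,
            n=45,
        )

    def test_quadratic_curve_inverts_in_closed_form(self):
        # LRT(x) = 40 - (x-100)^2/10 crosses max - 2 ln10 at 100 +- 6.786
        x = np.arange(0.0, 200.0, 0.1)
        scan = self._scan_from_curve(x, 40 - (x - 100) ** 2 / 10)
        lo, hi = lod_drop_ci(scan, drop_lod=1.0)
        assert lo == pytest.approx(100 - np.sqrt(10 * 2 * np.log(10)), abs=0.1)
        assert hi == pytest.approx(100 + np.sqrt(10 * 2 * np.log(10)), abs=0.1)

    def test_single_point_spike(self):
        x = np.arange(0.0, 10.0)
        lrt = np.zeros_like(x)
        lrt[4] = 50.0
        lo, hi = lod_drop_ci(self._scan_from_curve(x, lrt))
        assert lo == hi == 4.0

    def test_flat_scan_flags_full_range(self):
        x = np.arange(0.0, 10.0)
        scan = self._scan_from_curve(x, np.ones_like(x))
        assert lod_drop_ci(scan) == (0.0, 9.0)
        assert scan.flat

    @given(st.floats(min_value=0.1, max_value=3.0), st.floats(min_value=0.1, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_widening_drop_never_shrinks_interval(self, d1, d2):
        x = np.arange(0.0, 200.0, 1.0)
        rng = np.random.default_rng(7)
        scan = self._scan_from_curve(x, np.abs(rng.normal(5, 3, size=x.size)))
        small, large = sorted([d1, d2])
        lo_s, hi_s = lod_drop_ci(scan, drop_lod=small)
        lo_l, hi_l = lod_drop_ci(scan, drop_lod=large)
        assert lo_l <= lo_s and hi_l >= hi_s

    def test_lod_conversion_factor(self):
        assert LOD_PER_LRT == pytest.approx(1 / (2 * np.log(10)))


class TestLeaveOneSubtypeOut:
    def test_empty_omission_identical_to_full(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        y = adjust_phenotype(small_study.phenotypes)
        subtypes = pd.Series("one", index=y.index)
        out = leave_one_subtype_out_scans(
            y, prof, subtypes, n_sim=150, rng=0, group_names=["ghost"]
        )
        np.testing.assert_allclose(out["full"].lrt, out["without_ghost"].lrt)

    def test_reduced_families_have_own_thresholds(self, small_study):
        prof = transmission_probabilities(
            small_study.inheritance, small_study.marker_map, chromosome_length=200
        )
        y = adjust_phenotype(small_study.phenotypes)
        subtypes = pd.Series(
            ["g1"] * 10 + ["g2"] * 35, index=y.index
        )
        with pytest.warns(UserWarning, match="half the family"):
            out = leave_one_subtype_out_scans(y, prof, subtypes, n_sim=150, rng=0)
        assert out["without_g1"].n == 35
        assert out["without_g2"].n == 10
        assert out["without_g1"].threshold.value != out["without_g2"].threshold.value
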