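"""QTL x QTL interaction: ANOVA oracle, nested scans, candidate filter."""

import numpy as np
import pandas as pd
import pytest

from subtypeqtl import (
    SimulationConfig,
    adjust_phenotype,
    eqtl_candidate_filter,
    haplotype_table,
    interaction_scan,
    intervals_overlap,
    simulate_study,
    transmission_probabilities,
    two_qtl_additive_scan,
    two_way_anova_interaction,
)


def _table(prox, dist, idx):
    return haplotype_table(
        pd.Series(prox, index=idx), pd.Series(dist, index=idx)
    )


def anova_2x2_oracle(y, a, b):
    """From-scratch Type-II sums of squares for a 2x2 design with interaction.

    Model comparisons: each main effect against the two-main-effects model,
    the interaction against the full model; F with the full-model residual.
    """
    def rss(design):
        X = np.column_stack(design)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return ((y - X @ beta) ** 2).sum()

    one = np.ones_like(y)
    ab = a * b
    rss_full = rss([one, a, b, ab])
    rss_main = rss([one, a, b])
    rss_no_a = rss([one, b])
    rss_no_b = rss([one, a])
    df_resid = y.size - 4
    ms_resid = rss_full / df_resid
    from scipy import stats

    out = {}
    for name, num in (
        ("a", rss_no_a - rss_main),
        ("b", rss_no_b - rss_main),
        ("ab", rss_main - rss_full),
    ):
        F = num / ms_resid
        out[name] = (F, stats.f.sf(F, 1, df_resid))
    return out


class TestTwoWayAnova:
    def test_equal_cell_means_give_zero_f(self):
        # two animals per cell with exactly mirrored deviations: all cell
        # means equal, so every factor sum of squares is exactly zero
        idx = [f"a{i}" for i in range(8)]
        prox = ["Q", "Q", "Q", "Q", "q", "q", "q", "q"]
        dist = ["Q", "Q", "q", "q", "Q", "Q", "q", "q"]
        y = pd.Series([1.0, -1.0] * 4, index=idx)
        res = two_way_anova_interaction(y, _table(prox, dist, idx))
        assert res.anova.loc["proximal", "F"] == pytest.approx(0.0, abs=1e-10)
        assert res.p_interaction == pytest.approx(1.0)

    def test_matches_from_scratch_sums_of_squares(self, rng):
        # balanced 2x2, cell means (0, 0, 0, 10), within-cell SD 1, n=40
        n_cell = 10
        prox = np.repeat(["Q", "Q", "q", "q"], n_cell)
        dist = np.tile(np.repeat(["Q", "q"], n_cell), 2)
        mu = np.where((prox == "q") & (dist == "q"), 10.0, 0.0)
        y_vals = mu + rng.normal(size=40)
        idx = [f"a{i}" for i in range(40)]
        y = pd.Series(y_vals, index=idx)
        res = two_way_anova_interaction(y, _table(list(prox), list(dist), idx))
        oracle = anova_2x2_oracle(
            y_vals, (prox == "Q").astype(float), (dist == "Q").astype(float)
        )
        assert res.anova.loc["proximal", "F"] == pytest.approx(oracle["a"][0], rel=1e-6)
        assert res.anova.loc["distal", "F"] == pytest.approx(oracle["b"][0], rel=1e-6)
        assert res.anova.loc["proximal:distal", "F"] == pytest.approx(oracle["ab"][0], rel=1e-6)
        assert res.p_interaction == pytest.approx(oracle["ab"][1], rel=1e-6)

    def test_matches_permutation_oracle(self, rng):
        # permute proximal labels within distal strata: the interaction
        # p-value should agree with the parametric one on a mild toy
        n_cell = 8
        prox = np.repeat(["Q", "q", "Q", "q"], n_cell)
        dist = np.repeat(["Q", "q"], 2 * n_cell)
        y_vals = 0.8 * ((prox == "Q") & (dist == "Q")) + rng.normal(size=4 * n_cell)
        idx = [f"a{i}" for i in range(4 * n_cell)]
        res = two_way_anova_interaction(
            pd.Series(y_vals, index=idx), _table(list(prox), list(dist), idx)
        )
        obs_f = res.anova.loc["proximal:distal", "F"]
        n_perm, hits = 3000, 0
        for _ in range(n_perm):
            perm = prox.copy()
            for d in ("Q", "q"):
                sel = dist == d
                perm[sel] = rng.permutation(perm[sel])
            o = anova_2x2_oracle(
                y_vals, (perm == "Q").astype(float), (dist == "Q").astype(float)
            )
            hits += o["ab"][0] >= obs_f
        p_perm = (hits + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_interaction - p_perm) < max(4 * se, 0.02)

    def test_empty_cell_rejected(self):
        idx = [f"a{i}" for i in range(6)]
        prox = ["Q", "Q", "Q", "q", "q", "q"]
        dist = ["Q", "Q", "Q", "Q", "Q", "Q"]  # no distal-q animals at all
        y = pd.Series(np.arange(6.0), index=idx)
        with pytest.raises(ValueError, match="empty haplotype cell"):
            two_way_anova_interaction(y, _table(prox, dist, idx))

    def test_sign_pattern_of_conditional_differences(self):
        # gram-scale family: positive proximal difference under distal Q,
        # negative under distal q, majority of study-sized replicates
        from subtypeqtl.haplotypes import call_haplotype

        good = 0
        for seed in range(7):
            cfg = SimulationConfig.gram_scale(include_fine_mapping_snps=True)
            study = simulate_study(cfg, seed=60 + seed)
            trait = adjust_phenotype(study.phenotypes)
            table = haplotype_table(
                call_haplotype(study.inheritance, study.marker_map, 85.0, 20.0),
                call_haplotype(study.inheritance, study.marker_map, 168.0, 15.0),
            )
            try:
                res = two_way_anova_interaction(trait, table)
            except ValueError:
                continue
            if res.diff_given_distal_Q > 0 and res.diff_given_distal_Q > res.diff_given_distal_q:
                good += 1
        assert good >= 5


class TestNestedScans:
    @pytest.fixture(scope="class")
    def family(self):
        cfg = SimulationConfig(n_genes=10, n_trait_genes=2, n_distal_eqtl_genes=0,
                               n_interacting_eqtl_genes=0, include_fine_mapping_snps=True)
        study = simulate_study(cfg, seed=71)
        prof = transmission_probabilities(
            study.inheritance, study.marker_map, chromosome_length=200
        )
        return adjust_phenotype(study.phenotypes), prof

    def test_interaction_lrt_dominates_additive_everywhere(self, family):
        y, prof = family
        i_scan = interaction_scan(y, prof, 168.0, n_sim=0)
        a_scan = two_qtl_additive_scan(y, prof, 168.0, n_sim=0)
        assert (i_scan.lrt >= a_scan.lrt - 1e-8).all()

    def test_affine_invariance(self, family):
        y, prof = family
        a = interaction_scan(y, prof, 168.0, n_sim=0)
        b = interaction_scan(-2.0 * y + 5.0, prof, 168.0, n_sim=0)
        np.testing.assert_allclose(a.lrt, b.lrt, atol=1e-8)

    def test_uninformative_conditioning_collapses_to_plain_scan(self, family):
        y, prof = family
        flat = prof.pi.copy()
        flat.iloc[:, :] = prof.pi.to_numpy()
        flat.iloc[:, 0] = 0.5  # position 0: no information
        from subtypeqtl import TransmissionProfile, scan_chromosome

        prof_flat = TransmissionProfile(grid=prof.grid, pi=flat)
        with pytest.warns(UserWarning, match="collapses"):
            i_scan = interaction_scan(y, prof_flat, 0.0, n_sim=0)
        plain = scan_chromosome(y, prof_flat)
        np.testing.assert_allclose(i_scan.lrt, plain.lrt, atol=1e-6)

    def test_null_calibration_against_empirical_threshold(self, family):
        _, prof = family
        rng = np.random.default_rng(8)
        n = len(prof.animals)
        thr = None
        hits, n_fresh = 0, 300
        from subtypeqtl import empirical_threshold
        thr = empirical_threshold(prof, n_sim=500, rng=rng, model="interaction", fixed_pos=168.0)
        from subtypeqtl.linkage import _lrt_matrix
        Y = rng.standard_normal((n, n_fresh))
        w_fixed = 2.0 * prof.column(168.0) - 1.0
        lrt, _ = _lrt_matrix(Y, prof.w(), model="interaction", w_fixed=w_fixed)
        rate = (lrt.max(axis=0) > thr.value).mean()
        assert rate == pytest.approx(0.05, abs=0.035)


class TestCandidateFilter:
    def test_interval_overlap_properties(self):
        assert intervals_overlap((0, 5), (5, 9))
        assert intervals_overlap((5, 9), (0, 5))
        assert intervals_overlap((2, 4), (2, 4))
        assert not intervals_overlap((0, 1), (2, 3))

    def test_engineered_interacting_genes_recovered(self):
        # four genes carry the two-locus interacting signal; with the two
        # lean subtypes in the study's configuration (lean1 contains
        # distal-Q birds, lean2 is all distal-q) the three-part filter
        # recovers them with few or no bystanders
        cfg = SimulationConfig(include_fine_mapping_snps=True)
        study = simulate_study(cfg, seed=2)
        prof = transmission_probabilities(
            study.inheritance, study.marker_map, chromosome_length=200
        )
        from subtypeqtl.famt import FactorAnalysisMT

        res = FactorAnalysisMT(study.expression, study.phenotypes["trait"]).fit(q=6)
        genes = res.significant_genes()
        interacting = [g for g in study.truth.interacting_gene_ids if g in genes]
        assert len(interacting) >= 3  # engineered genes reach the list
        # truth-labeled lean subtypes: the 8 leanest distal-Q and the 8
        # leanest distal-q animals
        trait = study.phenotypes["trait"]
        dist_q = pd.Series(study.truth.distal_origin == 1, index=study.truth.animals)
        subtypes = pd.Series("mixed", index=trait.index)
        subtypes[trait[dist_q].nsmallest(8).index] = "lean1"
        subtypes[trait[~dist_q].nsmallest(8).index] = "lean2"
        out = eqtl_candidate_filter(
            study.expression.loc[genes],
            prof,
            distal_trait_ci=(150.0, 185.0),
            proximal_trait_ci=(70.0, 110.0),
            subtypes=subtypes,
            fixed_pos=168.0,
            n_sim=300,
            rng=5,
        )
        found = set(out.index[out["candidate"]])
        assert len(set(interacting) & found) >= 2, "engineered genes not recovered"
        # bystanders are rare relative to the hundreds screened
        assert len(found - set(study.truth.interacting_gene_ids)) <= 4

    def test_no_eqtl_genes_give_empty_list(self):
        cfg = SimulationConfig(n_genes=60, n_trait_genes=0, n_distal_eqtl_genes=0,
                               n_interacting_eqtl_genes=0, include_fine_mapping_snps=True)
        study = simulate_study(cfg, seed=77)
        prof = transmission_probabilities(
            study.inheritance, study.marker_map, chromosome_length=200
        )
        subtypes = pd.Series("mixed", index=study.phenotypes.index)
        with pytest.warns(UserWarning, match="lean1/lean2"):
            out = eqtl_candidate_filter(
                study.expression, prof,
                distal_trait_ci=(150.0, 185.0), proximal_trait_ci=(70.0, 110.0),
                subtypes=subtypes, fixed_pos=168.0, n_sim=300, rng=6,
            )
        assert out["candidate"].sum() <= 2  # ~ alpha-level bystanders at most
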