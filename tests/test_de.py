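"""Normalization and differential-expression statistics.

TMM and the exact test carry frozen cross-check values computed with
edgeR 4.0.16 (calcNormFactors / exactTest) on the `toy_counts` fixture, plus
independent straight-from-the-formula oracles written here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import degpattern as dp
from degpattern.de import (
    _conditional_nb_logpmf,
    _minlike_two_sided,
    estimate_common_dispersion,
    _design_matrices,
)

# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def tmm_factor_oracle(y, ref_col, obs_col, trim_m=0.30, trim_a=0.05):
    """Straight-from-the-formula TMM factor (sort-based trimming)."""
    obs, ref = y[:, obs_col].astype(float), y[:, ref_col].astype(float)
    n_obs, n_ref = y[:, obs_col].sum(), y[:, ref_col].sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 100, 50, 3])
        df = pd.DataFrame(
            np.column_stack([col, col, col]), columns=["a", "b", "c"]
        )
        nf = dp.tmm_factors(df)
        assert np.allclose(nf.factors, 1.0)

    def test_doubled_sample_absorbed_by_library_size(self):
        """Doubling every count of a sample only doubles its library size;
        all M-values are zero after adjustment so both factors stay 1."""
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=30)
        df = pd.DataFrame({"a": base, "b": 2 * base, "c": base + 1})
        nf = dp.tmm_factors(df)
        fa = nf.factors[list(df.columns).index("a")]
        fb = nf.factors[list(df.columns).index("b")]
        assert fa == pytest.approx(fb, abs=1e-12)

    def test_four_gene_toy_matches_formula_oracle(self):
        y = np.array([[10, 30], [20, 25], [100, 90], [5, 40]])
        df = pd.DataFrame(y, columns=["s0", "s1"])
        nf = dp.tmm_factors(df, reference="s0")
        expected = tmm_factor_oracle(y, ref_col=0, obs_col=1)
        expected = np.array([1.0, expected])
        expected = expected / np.exp(np.mean(np.log(expected)))
        assert np.allclose(nf.factors, expected, atol=1e-10)

    def test_random_matrix_matches_formula_oracle(self, toy_counts):
        nf = dp.tmm_factors(toy_counts)
        y = toy_counts.values
        ref = list(toy_counts.sample_ids).index(nf.reference_sample)
        raw = np.array(
            [
                1.0 if j == ref else tmm_factor_oracle(y, ref, j)
                for j in range(y.shape[1])
            ]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(nf.factors, expected, atol=1e-10)

    def test_matches_frozen_edger_factors(self, toy_counts):
        """Frozen output of edgeR::calcNormFactors(method='TMM')."""
        edger = np.array(
            [1.03799159, 0.98777852, 0.94790251, 1.00865278, 1.03943373, 0.98139629]
        )
        nf = dp.tmm_factors(toy_counts)
        assert np.allclose(nf.factors, edger, atol=1e-7)

    def test_unit_geometric_mean(self, toy_counts):
        nf = dp.tmm_factors(toy_counts)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            dp.tmm_factors(df)

    def test_scale_invariance_of_downstream_ratios(self, toy_counts):
        """Multiplying one sample's counts by c leaves effective-size ratios
        (hence logFC) unchanged."""
        nf1 = dp.tmm_factors(toy_counts)
        scaled = toy_counts.counts.copy()
        scaled["s2"] = scaled["s2"] * 5
        nf2 = dp.tmm_factors(scaled)
        r1 = nf1.effective_library_sizes / nf1.effective_library_sizes[0]
        r2 = nf2.effective_library_sizes / nf2.effective_library_sizes[0]
        r2 = r2 / np.where(np.arange(6) == 2, 5.0, 1.0)
        assert np.allclose(r1, r2, rtol=0.02)


class TestLogNormalizedExpression:
    def test_counts_proportional_to_libsize_give_constant_rows(self, unit_factors):
        nf = dp.NormFactors(
            np.array([1.0, 1.0]), np.array([1e6, 2e6]), np.array(["s0", "s1"])
        )
        df = pd.DataFrame({"s0": [100, 10], "s1": [200, 20]})
        out = dp.log_normalized_expression(df, nf)
        assert np.allclose(out.iloc[:, 0], out.iloc[:, 1])

    def test_joint_doubling_invariance(self):
        df = pd.DataFrame({"s0": [100, 10, 3], "s1": [150, 20, 7]})
        nf1 = dp.NormFactors(
            np.ones(2), np.array([1e6, 1.5e6]), np.array(["s0", "s1"])
        )
        nf2 = dp.NormFactors(
            np.ones(2), np.array([2e6, 3e6]), np.array(["s0", "s1"])
        )
        out1 = dp.log_normalized_expression(df, nf1)
        out2 = dp.log_normalized_expression(2 * df, nf2)
        assert np.allclose(out1, out2)

    def test_toy_matrix_matches_direct_formula(self):
        df = pd.DataFrame(
            {"s0": [0, 10, 100], "s1": [5, 20, 50], "s2": [1, 1, 1]}
        )
        nf = dp.NormFactors(
            np.array([1.1, 0.9, 1.0]),
            np.array([110.0, 75.0, 3.0]),
            np.array(["s0", "s1", "s2"]),
        )
        out = dp.log_normalized_expression(df, nf, prior_count=0.5)
        eff = nf.library_sizes * nf.factors
        expected = np.log2(df.to_numpy() / eff[None, :] * 1e6 + 0.5)
        assert np.allclose(out.to_numpy(), expected)
        assert np.all(np.isfinite(out.to_numpy()))

    def test_dimension_mismatch_rejected(self, toy_counts):
        nf = dp.NormFactors(np.ones(2), np.ones(2) * 1e6, np.array(["a", "b"]))
        with pytest.raises(ValueError, match="match"):
            dp.log_normalized_expression(toy_counts, nf)

    def test_transformer_api(self, toy_counts):
        norm = dp.TMMNormalizer().fit(toy_counts)
        out = norm.transform(toy_counts)
        assert out.shape == toy_counts.counts.shape
        assert norm.factors_.shape == (6,)


# ---------------------------------------------------------------------------
# two-factor GLM
# ---------------------------------------------------------------------------


class TestTwoFactorGLM:
    def test_common_dispersion_recovered(self):
        d = dp.SimDesign(
            n_genes=400, fraction_null=1.0, dispersion=0.1, seed=2
        )
        cm, _ = dp.simulate_counts(d)
        nf = dp.tmm_factors(cm)
        x_full, _, _ = _design_matrices(cm.samples)
        phi = estimate_common_dispersion(
            cm.values.astype(float), x_full, np.log(nf.effective_library_sizes)
        )
        assert 0.07 < phi < 0.14

    def test_interaction_effect_recovered_within_analytic_se(self):
        """Planted interaction log2FC = 2 at phi = 0.05: estimates fall
        within 3 Fisher-information SEs of the truth for >=90% of genes.

        The analytic SE for the interaction coefficient in a 2x2 design with
        n replicates per cell is sqrt(sum_cells(phi/n + 1/(n mu)))/ln2 in
        log2 units, which at these settings is ~0.37 — so a fixed +/-0.3
        band is not an attainable oracle; the 3-SE band is.
        """
        tmpl = np.array([[0.0, 0.0, 2.0]])
        d = dp.SimDesign(
            n_genes=150,
            fraction_null=0.8,
            n_profile_clusters=1,
            cluster_effect_templates=tmpl,
            dispersion=0.05,
            baseline_log_mean_range=(np.log(200), np.log(2000)),
            seed=8,
        )
        cm, truth = dp.simulate_counts(d)
        res = dp.fit_two_factor_glm(cm, dp.tmm_factors(cm), dispersion="common")
        est = res.contrast("interaction")["logFC"].to_numpy()
        planted = truth.cluster_labels >= 0
        mu = truth.extra["mu"][planted]
        # var(beta_int) = sum_cells (phi + 1/mu_cell) / n, n=3 per cell
        var_ln = (4 * 0.05 + (1.0 / mu).sum(axis=1) / 3) / 3
        se = np.sqrt(var_ln) / np.log(2)
        frac = np.mean(np.abs(est[planted] - 2.0) <= 3 * se)
        assert frac >= 0.90

    def test_tight_recovery_at_small_dispersion(self):
        """At phi = 0.005 the same analytic oracle puts +/-0.3 at ~2.5 SEs,
        so >=90% of planted genes must land inside it."""
        tmpl = np.array([[0.0, 0.0, 2.0]])
        d = dp.SimDesign(
            n_genes=150,
            fraction_null=0.8,
            n_profile_clusters=1,
            cluster_effect_templates=tmpl,
            dispersion=0.005,
            baseline_log_mean_range=(np.log(500), np.log(5000)),
            seed=8,
        )
        cm, truth = dp.simulate_counts(d)
        res = dp.fit_two_factor_glm(cm, dp.tmm_factors(cm), dispersion="common")
        est = res.contrast("interaction")["logFC"].to_numpy()
        planted = truth.cluster_labels >= 0
        assert np.mean(np.abs(est[planted] - 2.0) <= 0.3) >= 0.90

    def test_all_zero_gene_flagged_untested(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.poisson(40, size=(20, 8)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(8)],
        )
        counts.iloc[0] = 0
        meta = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "factor_a": ["X"] * 4 + ["Y"] * 4,
                "factor_b": ["P", "P", "L", "L"] * 2,
            }
        )
        cm = dp.CountMatrix(counts, meta)
        res = dp.fit_two_factor_glm(cm, dispersion=0.1)
        tab = res.contrast("main_a")
        assert tab.iloc[0]["status"] == "not_tested"
        assert np.isnan(tab.iloc[0]["fdr"])
        # FDR over tested genes only: max raw p must map to fdr <= 1
        tested = tab[tab["status"] == "tested"]
        assert (tested["fdr"] >= tested["pvalue"] - 1e-12).all()

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({"s0": [1, 2], "s1": [3, 4], "s2": [5, 6], "s3": [7, 8]})
        meta = pd.DataFrame(
            {
                "sample_id": df.columns,
                "factor_a": ["X", "X", "Y", "Y"],
                "factor_b": ["P", "P", "L", "L"],  # aliased with factor_a
            }
        )
        cm = dp.CountMatrix(df, meta)
        with pytest.raises(ValueError, match="rank"):
            dp.fit_two_factor_glm(cm, dispersion=0.1)

    def test_estimator_api(self):
        d = dp.SimDesign(n_genes=60, fraction_null=0.5, seed=3)
        cm, _ = dp.simulate_counts(d)
        model = dp.TwoFactorDE(dispersion="common").fit(cm)
        assert "interaction" in model.results_.contrasts
        assert sum("_vs_" in c for c in model.results_.contrasts) == 4
        params = model.get_params()
        assert params["dispersion"] == "common"


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------


class TestExactTest:
    def test_group_swap_symmetry(self, toy_counts):
        nf = dp.tmm_factors(toy_counts)
        g1, g2 = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        p1, lfc1 = dp.pairwise_exact_test(toy_counts, nf, g1, g2, 0.1)
        p2, lfc2 = dp.pairwise_exact_test(toy_counts, nf, g2, g1, 0.1)
        assert np.allclose(p1, p2)
        assert np.allclose(lfc1, -lfc2)

    def test_matches_frozen_edger_exacttest(self, toy_counts):
        """Frozen output of edgeR::exactTest at common dispersion 0.1."""
        edger_p = np.array(
            [0.58610015, 0.12052846, 0.61456109, 0.30530233, 0.73827730]
        )
        nf = dp.tmm_factors(toy_counts)
        p, _ = dp.pairwise_exact_test(
            toy_counts, nf, ["s0", "s1", "s2"], ["s3", "s4", "s5"], 0.1
        )
        assert np.allclose(p[:5], edger_p, atol=1e-7)

    def test_poisson_limit_matches_conditional_binomial(self, unit_factors):
        """phi -> 0 with equal offsets: agrees with the minimum-likelihood
        two-sided conditional binomial p to 1e-8 (spot check; the exhaustive
        sweep lives in the acceptance suite)."""
        rows = [(a, t - a) for t in (1, 7, 23, 50) for a in range(t + 1)]
        df = pd.DataFrame(rows, columns=["s0", "s1"], dtype=int)
        df.index = [f"g{i}" for i in range(len(df))]
        p, _ = dp.pairwise_exact_test(
            df, unit_factors(2), ["s0"], ["s1"], dispersion=1e-12
        )
        for i, (a, b) in enumerate(rows):
            t = a + b
            pmf = stats.binom.pmf(np.arange(t + 1), t, 0.5)
            oracle = min(pmf[pmf <= pmf[a] * (1 + 1e-7)].sum(), 1.0)
            assert p[i] == pytest.approx(oracle, abs=1e-8)

    def test_all_zero_gene_convention(self, unit_factors):
        df = pd.DataFrame({"s0": [0, 5], "s1": [0, 5]})
        p, lfc = dp.pairwise_exact_test(df, unit_factors(2), ["s0"], ["s1"], 0.1)
        assert p[0] == 1.0 and lfc[0] == 0.0

    def test_overlapping_groups_rejected(self, toy_counts):
        nf = dp.tmm_factors(toy_counts)
        with pytest.raises(ValueError, match="overlap"):
            dp.pairwise_exact_test(toy_counts, nf, ["s0", "s1"], ["s1", "s2"], 0.1)

    def test_p_in_unit_interval(self, toy_counts):
        nf = dp.tmm_factors(toy_counts)
        p, _ = dp.pairwise_exact_test(
            toy_counts, nf, ["s0", "s1", "s2"], ["s3", "s4", "s5"], 0.1
        )
        assert np.all((p > 0) & (p <= 1))


# ---------------------------------------------------------------------------
# BH FDR and DEG filter
# ---------------------------------------------------------------------------


def bh_oracle(p):
    """Brute-force BH: adj_i = min over cutoffs j with p_(j) >= p_i of m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for i in range(m):
        cands = [m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i] - 1e-15]
        adj[i] = min(1.0, min(cands))
    return adj


class TestBHFdr:
    def test_single_p(self):
        assert dp.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup_example(self):
        assert np.allclose(dp.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, size=37)
        perm = rng.permutation(37)
        assert np.allclose(dp.bh_fdr(p)[perm], dp.bh_fdr(p[perm]))

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(1, 40)
            p = rng.uniform(1e-6, 1, size=n)
            assert np.allclose(dp.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.0001, 1, size=100)
        adj = dp.bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            dp.bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            dp.bh_fdr([0.5, 1.2])


def _filter_fixture():
    """Six genes engineered so exactly 2 pass up, 1 passes down."""
    gene_ids = np.array([f"g{i}" for i in range(6)])
    res = dp.DEResult(gene_ids)
    #            up ok   up ok   down ok  lowFC    highFDR  lowcount
    logfc = [3.0, 1.5, -2.0, 0.5, 4.0, 3.0]
    pvals = [1e-5, 1e-4, 1e-4, 1e-5, 0.5, 1e-5]
    res.add_contrast("X:L_vs_P", np.array(logfc), np.array(pvals))
    counts = pd.DataFrame(
        {
            "s0": [50, 40, 80, 50, 50, 1],
            "s1": [50, 40, 80, 50, 50, 2],
            "s2": [400, 115, 20, 70, 800, 30],
            "s3": [400, 115, 20, 70, 800, 30],
        },
        index=gene_ids,
    )
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "factor_a": ["X"] * 4,
            "factor_b": ["P", "P", "L", "L"],
        }
    )
    cm = dp.CountMatrix(counts, meta)
    g1 = cm.group_mask(factor_b="P")
    g2 = cm.group_mask(factor_b="L")
    return res, cm, g1, g2


class TestFilterDegs:
    def test_engineered_fixture_counts(self):
        """Strict FC > 2, FDR < 0.05, both group means > 2: (2 up, 1 down)."""
        res, cm, g1, g2 = _filter_fixture()
        up, down = dp.filter_degs(res, cm, "X:L_vs_P", g1, g2)
        assert sorted(up) == ["g0", "g1"]
        assert down == ["g2"]

    def test_zero_fdr_threshold_empties_lists(self):
        res, cm, g1, g2 = _filter_fixture()
        up, down = dp.filter_degs(
            res, cm, "X:L_vs_P", g1, g2, fdr_threshold=1e-300
        )
        assert up == [] and down == []

    def test_boundary_mean_count_is_strict(self):
        """A gene whose group mean is exactly the threshold is excluded."""
        gene_ids = np.array(["g0"])
        res = dp.DEResult(gene_ids)
        res.add_contrast("c", np.array([5.0]), np.array([1e-6]))
        counts = pd.DataFrame(
            {"s0": [2], "s1": [2], "s2": [100], "s3": [100]}, index=gene_ids
        )
        meta = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "factor_a": ["X"] * 4,
                "factor_b": ["P", "P", "L", "L"],
            }
        )
        cm = dp.CountMatrix(counts, meta)
        up, _ = dp.filter_degs(
            res, cm, "c", cm.group_mask(factor_b="P"), cm.group_mask(factor_b="L")
        )
        assert up == []

    def test_unknown_contrast_rejected(self):
        res, cm, g1, g2 = _filter_fixture()
        with pytest.raises(ValueError, match="unknown contrast"):
            dp.filter_degs(res, cm, "nope", g1, g2)
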