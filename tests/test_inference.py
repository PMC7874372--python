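"""GLM standardization, resampling inference and multiple-testing control."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmn_subsys import inference as inf
from dmn_subsys import network_metrics as netm
from dmn_subsys.connectivity import ConnectivityMatrix
from dmn_subsys.rois import RoiSet


def make_design(rng, n=200):
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "age": rng.uniform(6, 18, n),
        "group": np.repeat(["ASC", "CMP"], n // 2),
        "fiq": rng.normal(107, 11, n),
    })


class TestFitGlm:
    def test_outcome_equal_to_age_gives_unit_beta(self, rng):
        X = make_design(rng)
        y = (X["age"] - X["age"].mean()) / X["age"].std()
        beta = inf.fit_glm(y, X, ("age", "group", "age_x_group", "fiq"))
        assert beta["age"] == pytest.approx(1.0, abs=1e-8)
        assert abs(beta["group"]) < 1e-8
        assert abs(beta["fiq"]) < 1e-8

    def test_independent_noise_small_betas(self, rng):
        X = make_design(rng, n=1000)
        y = rng.normal(size=1000)
        beta = inf.fit_glm(y, X, ("age", "group", "age_x_group", "fiq"))
        assert np.all(np.abs(beta.to_numpy()) < 0.1)

    def test_row_duplication_invariance(self, rng):
        X = make_design(rng, n=60)
        y = rng.normal(size=60)
        cols = ("age", "group", "age_x_group", "fiq")
        b1 = inf.fit_glm(y, X, cols)
        X2 = pd.concat([X, X], ignore_index=True)
        b2 = inf.fit_glm(np.concatenate([y, y]), X2, cols)
        assert np.allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-10)

    def test_age_rescaling_invariance(self, rng):
        """Years → months leaves every standardized coefficient unchanged."""
        X = make_design(rng, n=150)
        y = 0.3 * X["age"] + rng.normal(size=150)
        cols = ("age", "group", "age_x_group", "fiq")
        b1 = inf.fit_glm(y, X, cols)
        X2 = X.assign(age=X["age"] * 12.0)
        b2 = inf.fit_glm(y, X2, cols)
        assert np.allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-10)

    def test_zero_variance_outcome_rejected(self, rng):
        X = make_design(rng, n=30)
        with pytest.raises(ValueError, match="zero variance"):
            inf.fit_glm(np.ones(30), X, ("age", "group"))


class TestBootstrapPermutation:
    def test_determinism(self, rng):
        X = make_design(rng, n=80)
        y = rng.normal(size=80)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=200, seed=11)
        r1 = inf.bootstrap_permutation_test(y, X, spec)
        r2 = inf.bootstrap_permutation_test(y, X, spec)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        for c in r1.boot_distribution:
            assert np.array_equal(r1.boot_distribution[c], r2.boot_distribution[c])

    def test_perfect_association_floor_p(self, rng):
        X = make_design(rng, n=100)
        y = (X["age"] - X["age"].mean()) / X["age"].std()
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=200, seed=1)
        res = inf.bootstrap_permutation_test(y, X, spec)
        p_age = res.table.set_index("coef").loc["age", "p_raw"]
        assert p_age == pytest.approx(1.0 / 201.0, abs=1e-12)

    def test_result_structure(self, rng):
        X = make_design(rng, n=60)
        y = rng.normal(size=60)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=150, seed=2)
        res = inf.bootstrap_permutation_test(y, X, spec)
        tab = res.table.set_index("coef")
        for c in ("age", "group", "age_x_group"):
            assert len(res.boot_distribution[c]) == 150
            assert len(res.null_distribution[c]) == 150
            assert 0 < tab.loc[c, "p_raw"] <= 1
            assert tab.loc[c, "ci_lo"] <= tab.loc[c, "beta_median"] <= tab.loc[c, "ci_hi"]

    def test_planted_interaction_detected(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = make_design(r, n=400)
            g = np.where(X["group"] == "ASC", 0.5, -0.5)
            az = (X["age"] - X["age"].mean()) / X["age"].std()
            y = 0.4 * az * g + r.normal(size=400)
            spec = inf.GlmSpec(nuisance=("fiq",), n_boot=200, seed=seed)
            res = inf.bootstrap_permutation_test(y, X, spec)
            p = res.table.set_index("coef").loc["age_x_group", "p_raw"]
            hits += p <= 0.05
        assert hits >= 17

    def test_null_pvalues_uniform(self):
        """Kolmogorov–Smirnov check of p-value uniformity under the null."""
        ps = []
        for seed in range(300):
            r = np.random.default_rng(10_000 + seed)
            X = make_design(r, n=100)
            y = r.normal(size=100)
            spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=seed)
            res = inf.bootstrap_permutation_test(y, X, spec)
            ps.append(res.table.set_index("coef").loc["age_x_group", "p_raw"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_subjects_rejected(self, rng):
        X = make_design(rng, n=60).iloc[:2]
        with pytest.raises(ValueError, match="at least 3"):
            inf.bootstrap_permutation_test(np.array([1.0, 2.0]), X,
                                           inf.GlmSpec(nuisance=("fiq",), n_boot=100))


class TestMultipleTesting:
    def test_bh_hand_case(self):
        adj = inf.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_bh_single_p_unchanged(self):
        assert inf.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_bh_equal_ps_unchanged(self):
        assert np.allclose(inf.bh_fdr([0.2] * 5), 0.2)

    def test_bh_matches_brute_force(self, rng):
        """Step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j) / j)."""
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            ps = p[order]
            adj_sorted = np.minimum.accumulate(
                (m * ps / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(inf.bh_fdr(p), expected, atol=1e-12)

    def test_bh_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            inf.bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            inf.bh_fdr([0.5, 1.2])

    def test_bonferroni_multiplies_and_caps(self):
        assert inf.bonferroni([0.012], m=4)[0] == pytest.approx(0.048)
        assert inf.bonferroni([0.6], m=4)[0] == 1.0


from hypothesis import given, settings, strategies as st


@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_bh_fdr_step_up_properties(p):
    """Adjusted values never fall below raw, are capped at 1, and are
    monotone non-decreasing in the sorted order of the raw p-values."""
    p = np.asarray(p)
    adj = inf.bh_fdr(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


class TestMedianSplit:
    def test_even_group(self):
        pheno = pd.DataFrame({"group": ["ASC"] * 4,
                              "age": [8.0, 10.0, 12.0, 14.0]})
        bands = inf.median_split(pheno)
        assert list(bands) == ["younger", "younger", "older", "older"]

    def test_odd_group_median_goes_younger(self):
        pheno = pd.DataFrame({"group": ["CMP"] * 3, "age": [8.0, 11.0, 14.0]})
        bands = inf.median_split(pheno)
        assert list(bands) == ["younger", "younger", "older"]

    def test_partition_exhaustive_per_group(self, rng):
        pheno = make_design(rng, n=50)[["group", "age"]]
        bands = inf.median_split(pheno)
        assert bands.notna().all()
        assert set(bands.unique()) <= {"younger", "older"}


def simulate_edge_inputs(rng, n=40):
    rois = RoiSet.default()
    pheno = make_design(rng, n=n)
    mats = []
    for sid in pheno["subject_id"]:
        a = rng.normal(size=(11, 11)) * 0.1
        z = (a + a.T) / 2
        np.fill_diagonal(z, 0.0)
        mats.append(ConnectivityMatrix(sid, z, rois.labels))
    return rois, pheno, mats


class TestEdgewise:
    def test_row_counts_and_fdr_columns(self, rng):
        rois, pheno, mats = simulate_edge_inputs(rng)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=0)
        out = inf.edgewise_analysis(mats, pheno, None, spec,
                                    partition=rois.partition())
        assert (out["coef"] == "age").sum() == 55
        assert (out["coef"] == "age_x_group").sum() == 55
        assert out.loc[out["role"] == "predictor", "p_fdr"].notna().all()
        assert {"MTL", "MTL--dMPFC"} <= set(out["module_pair"])

    def test_subject_mismatch_listed(self, rng):
        rois, pheno, mats = simulate_edge_inputs(rng)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=0)
        with pytest.raises(ValueError, match="s000"):
            inf.edgewise_analysis(mats[1:], pheno, None, spec)


class TestModuleLevel:
    def make_inputs(self, rng, n=60):
        pheno = make_design(rng, n=n)
        summaries = pd.DataFrame({
            "subject_id": pheno["subject_id"],
            "Q": rng.normal(0.2, 0.05, n),
            "within_MTL": rng.normal(2, 0.5, n),
            "within_dMPFC": rng.normal(1.5, 0.5, n),
            "within_Core": rng.normal(0.4, 0.2, n),
            "between": rng.normal(8, 1.5, n),
        })
        qc = pd.DataFrame({"subject_id": pheno["subject_id"],
                           "mean_fd": rng.uniform(0.05, 0.4, n),
                           "mean_dvars": rng.uniform(1, 4, n)})
        return pheno, summaries, qc

    def test_families_and_corrections(self, rng):
        pheno, summaries, qc = self.make_inputs(rng)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=3)
        out = inf.module_level_analysis(summaries, pheno, None, spec)
        strengths = out[out["outcome"].isin(inf.STRENGTH_OUTCOMES)]
        assert (strengths["correction"] == "Bonferroni").all()
        assert np.allclose(strengths["p_corrected"],
                           np.minimum(strengths["p_raw"] * 4, 1.0))
        q_rows = out[out["outcome"] == "Q"]
        assert (q_rows["correction"] == "none").all()
        assert np.allclose(q_rows["p_corrected"], q_rows["p_raw"])

    def test_exclude_outliers_noop_when_none_flagged(self, rng):
        pheno, summaries, qc = self.make_inputs(rng)
        qc["mean_fd"] = 0.2  # identical values: nobody flagged
        qc["mean_dvars"] = 3.0
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=4)
        full = inf.module_level_analysis(summaries, pheno, None, spec)
        excl = inf.module_level_analysis(summaries, pheno, None, spec,
                                         exclude_outliers=True, qc=qc)
        pd.testing.assert_frame_equal(
            full.drop(columns=["excluded_outliers"]),
            excl.drop(columns=["excluded_outliers"]),
        )

    def test_exclude_outliers_drops_flagged(self, rng):
        pheno, summaries, qc = self.make_inputs(rng, n=100)
        spec = inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=5)
        excl = inf.module_level_analysis(summaries, pheno, None, spec,
                                         exclude_outliers=True, qc=qc)
        assert excl["n_subjects"].iloc[0] < 100


class TestSymptomAssociation:
    def test_five_measures_five_rows(self, rng):
        pheno = make_design(rng, n=60)
        summaries = pd.DataFrame({
            "subject_id": pheno["subject_id"],
            "Q": rng.normal(size=60), "between": rng.normal(size=60),
            "within_MTL": rng.normal(size=60),
            "within_dMPFC": rng.normal(size=60),
            "within_Core": rng.normal(size=60),
        })
        scores = pd.Series(rng.normal(size=60),
                           index=pheno["subject_id"].to_numpy())
        out = inf.symptom_association(scores, summaries, pheno, None,
                                      inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=6))
        assert len(out) == 5
        assert set(out["measure"]) == {"Q"} | set(inf.STRENGTH_OUTCOMES)

    def test_planted_identity_recovered(self, rng):
        pheno = make_design(rng, n=80)
        between = rng.normal(size=80)
        summaries = pd.DataFrame({
            "subject_id": pheno["subject_id"], "Q": rng.normal(size=80),
            "between": between, "within_MTL": rng.normal(size=80),
            "within_dMPFC": rng.normal(size=80),
            "within_Core": rng.normal(size=80),
        })
        scores = pd.Series(between + rng.normal(0, 0.05, 80),
                           index=pheno["subject_id"].to_numpy())
        out = inf.symptom_association(scores, summaries, pheno, None,
                                      inf.GlmSpec(nuisance=("fiq",), n_boot=200, seed=7))
        row = out.set_index("measure").loc["between"]
        assert row["beta_median"] > 0.9
        assert row["p_raw"] == pytest.approx(1.0 / 201.0, abs=1e-12)

    def test_missing_scores_dropped(self, rng):
        pheno = make_design(rng, n=50)
        summaries = pd.DataFrame({
            "subject_id": pheno["subject_id"], "Q": rng.normal(size=50),
            "between": rng.normal(size=50), "within_MTL": rng.normal(size=50),
            "within_dMPFC": rng.normal(size=50),
            "within_Core": rng.normal(size=50),
        })
        scores = pd.Series(rng.normal(size=50), index=pheno["subject_id"].to_numpy())
        scores.iloc[:20] = np.nan
        out = inf.symptom_association(scores, summaries, pheno, None,
                                      inf.GlmSpec(nuisance=("fiq",), n_boot=100, seed=8))
        assert (out["n"] == 30).all()
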