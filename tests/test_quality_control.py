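"""Motion summaries, exclusion rules, IQM factors and leakage checks."""
import numpy as np
import pandas as pd
import pytest

from dmn_subsys import quality_control as qc
from dmn_subsys import synthetic_data as sd


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert np.allclose(qc.framewise_displacement(np.zeros((10, 6))), 0.0)

    def test_translation_step(self):
        m = np.zeros((5, 6))
        m[3:, 0] = 0.1  # 0.1 mm x-translation step at frame 3
        fd = qc.framewise_displacement(m)
        assert fd[3] == pytest.approx(0.1, abs=1e-15)
        assert fd[0] == 0.0
        assert np.all(fd[[1, 2, 4]] == 0.0)

    def test_rotation_step_converted_on_head_sphere(self):
        m = np.zeros((5, 6))
        m[2:, 4] = 0.002  # 0.002 rad rotation step → 50·0.002 = 0.1 mm
        fd = qc.framewise_displacement(m)
        assert fd[2] == pytest.approx(0.1, abs=1e-15)

    def test_mean_translation_invariance(self, rng):
        m = rng.normal(size=(50, 6))
        fd1 = qc.framewise_displacement(m)
        fd2 = qc.framewise_displacement(m + 100.0)
        assert np.allclose(fd1, fd2)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="T×6"):
            qc.framewise_displacement(np.zeros((10, 4)))


class TestDvars:
    def test_constant_data(self):
        assert np.allclose(qc.dvars(np.full((10, 5), 7.0)), 0.0)

    def test_uniform_jump_is_one_percent(self):
        data = np.full((10, 20), 100.0)
        data[5:] += 1.0
        d = qc.dvars(data)
        assert d[5] == pytest.approx(100.0 * 1.0 / data.mean(), abs=1e-12)
        assert np.all(np.delete(d, 5) == 0.0)

    def test_doubling_jump_doubles_dvars(self):
        a = np.full((10, 20), 100.0)
        b = a.copy()
        a[5:] += 1.0
        b[5:] += 2.0
        # raw DVARS doubles; the % standardization rescales by the means
        assert qc.dvars(b)[5] / qc.dvars(a)[5] == pytest.approx(
            2.0 * a.mean() / b.mean(), rel=1e-12
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="grand mean"):
            qc.dvars(np.zeros((5, 5)))


def exclusion_fixture():
    """12 subjects with known rule violations (first matching rule wins)."""
    pheno = pd.DataFrame(
        {
            "subject_id": [f"s{i:02d}" for i in range(12)],
            "group": ["ASC", "CMP"] * 6,
            "age": np.linspace(7, 17, 12),
            "fiq": [100, 100, 80, 135, 100, 100, 82, 131, 100, 100, 100, 100],
        }
    )
    qc_tab = pd.DataFrame(
        {
            "subject_id": pheno["subject_id"],
            # s00 clean, s04 FD, s05 DVARS, s06 would be IQ_low but also FD
            "mean_fd": [0.2, 0.3, 0.1, 0.1, 0.6, 0.2, 0.7, 0.1, 0.1, 0.2, 0.49, 0.1],
            "mean_dvars": [3.0, 2.0, 3.0, 3.0, 2.0, 5.5, 2.0, 3.0, 5.1, 2.0, 3.0, 4.9],
        }
    )
    expected_reasons = {
        "s02": "IQ_low", "s03": "IQ_high", "s04": "FD", "s05": "DVARS",
        "s06": "FD", "s07": "IQ_high", "s08": "DVARS",
    }
    retained = ["s00", "s01", "s09", "s10", "s11"]
    return pheno, qc_tab, expected_reasons, retained


class TestExclusions:
    def test_fixture_reasons_and_retained_set(self):
        pheno, qc_tab, expected, retained = exclusion_fixture()
        kept, log = qc.apply_exclusions(pheno, qc_tab)
        assert dict(zip(log["subject_id"], log["reason"])) == expected
        assert list(kept["subject_id"]) == retained

    def test_idempotent(self):
        pheno, qc_tab, _, _ = exclusion_fixture()
        once, _ = qc.apply_exclusions(pheno, qc_tab)
        twice, log2 = qc.apply_exclusions(once, qc_tab)
        pd.testing.assert_frame_equal(once, twice)
        assert len(log2) == 0

    def test_missing_qc_names_subject(self):
        pheno, qc_tab, _, _ = exclusion_fixture()
        with pytest.raises(ValueError, match="s11"):
            qc.apply_exclusions(pheno, qc_tab[qc_tab["subject_id"] != "s11"])

    def test_boundary_values_retained(self):
        """Thresholds are strict: exactly 0.5 mm / 5 % / 83 / 130 stay in."""
        pheno = pd.DataFrame({"subject_id": ["a", "b"], "group": ["ASC", "CMP"],
                              "age": [10, 11], "fiq": [83.0, 130.0]})
        qc_tab = pd.DataFrame({"subject_id": ["a", "b"],
                               "mean_fd": [0.5, 0.2], "mean_dvars": [5.0, 3.0]})
        kept, log = qc.apply_exclusions(pheno, qc_tab)
        assert len(kept) == 2 and len(log) == 0


class TestMovementOutliers:
    def test_five_percent_flagged_continuous(self, rng):
        tab = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(100)],
            "mean_fd": rng.uniform(0.05, 0.4, 100),
            "mean_dvars": rng.uniform(1, 4, 100),
        })
        flags = qc.movement_outliers(tab)
        assert flags["fd_outlier"].sum() == 5
        assert flags["dvars_outlier"].sum() == 5

    def test_identical_values_flag_nobody(self):
        tab = pd.DataFrame({"subject_id": [f"s{i}" for i in range(30)],
                            "mean_fd": 0.2, "mean_dvars": 3.0})
        flags = qc.movement_outliers(tab)
        assert not flags["fd_outlier"].any()
        assert not flags["dvars_outlier"].any()

    def test_extreme_subject_gets_flagged(self, rng):
        tab = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(100)],
            "mean_fd": rng.uniform(0.05, 0.4, 100),
            "mean_dvars": rng.uniform(1, 4, 100),
        })
        before = qc.movement_outliers(tab)
        extra = pd.concat([tab, pd.DataFrame({"subject_id": ["huge"],
                                              "mean_fd": [5.0],
                                              "mean_dvars": [2.0]})],
                          ignore_index=True)
        after = qc.movement_outliers(extra)
        assert bool(after.loc[after["subject_id"] == "huge", "fd_outlier"].iloc[0])
        # the pooled percentile shifts by at most one order statistic, so
        # at most one previously flagged subject can drop out
        flagged_before = set(before.loc[before["fd_outlier"], "subject_id"])
        flagged_after = set(after.loc[after["fd_outlier"], "subject_id"])
        assert len(flagged_before - flagged_after) <= 1
        assert flagged_after - {"huge"} <= flagged_before


class TestIqmPca:
    def make_iqm(self, seed=6, n=60, noise=1e-6, site_sd=0.0):
        cfg = sd.SimulationConfig(n_per_group=n // 2, T=100, noise_sd=noise,
                                  site_effect_sd=site_sd, seed=seed)
        ph = sd.generate_phenotypes(cfg)
        return sd.generate_iqm_table(ph, cfg)

    def test_rank_four_recovery(self):
        factors, explained = qc.iqm_pca(self.make_iqm())
        assert explained.sum() > 0.99

    def test_scores_zero_mean_and_orthogonal(self):
        factors, _ = qc.iqm_pca(self.make_iqm(noise=0.5))
        x = factors[["f1", "f2", "f3", "f4"]].to_numpy()
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-8)
        corr = np.corrcoef(x, rowvar=False)
        assert np.allclose(corr - np.eye(4), 0.0, atol=1e-8)

    def test_scale_invariance(self):
        iqm = self.make_iqm(noise=0.5)
        scaled = iqm.copy()
        scaled["efc"] = scaled["efc"] * 100.0
        f1, _ = qc.iqm_pca(iqm)
        f2, _ = qc.iqm_pca(scaled)
        pd.testing.assert_frame_equal(f1, f2)

    def test_explained_variance_non_increasing(self):
        _, explained = qc.iqm_pca(self.make_iqm(noise=1.0))
        assert np.all(np.diff(explained) <= 1e-12)

    def test_constant_column_dropped(self, caplog):
        import logging
        iqm = self.make_iqm(noise=0.5)
        iqm["efc"] = 1.0
        with caplog.at_level(logging.WARNING, logger="dmn_subsys.quality_control"):
            factors, _ = qc.iqm_pca(iqm)
        assert "efc" in caplog.text
        assert factors.shape[1] == 5


class TestSiteLeakage:
    def planted(self, rng, n=300, p=30, offset=1.0, sites=3):
        site = np.array([f"site{i % sites}" for i in range(n)])
        x = rng.normal(size=(n, p))
        offsets = rng.normal(0, offset, size=(sites, p))
        for k in range(sites):
            x[site == f"site{k}"] += offsets[k]
        return x, site

    def test_permuted_labels_at_chance(self, rng):
        x, site = self.planted(rng, offset=1.0)
        perm_site = rng.permutation(site)
        acc = qc.site_leakage_check(x, perm_site, mode="raw", seed=1)
        assert abs(acc - 1.0 / 3.0) < 0.1

    def test_planted_offset_detected_raw(self, rng):
        x, site = self.planted(rng, offset=1.0)
        acc = qc.site_leakage_check(x, site, mode="raw", seed=1)
        assert acc > 1.0 / 3.0 + 0.2

    def test_site_regression_removes_offset(self, rng):
        x, site = self.planted(rng, offset=1.0)
        acc = qc.site_leakage_check(x, site, mode="site_regressed", seed=1)
        assert abs(acc - 1.0 / 3.0) < 0.1

    def test_too_few_sites_rejected(self, rng):
        x = rng.normal(size=(20, 5))
        with pytest.raises(ValueError, match="two sites"):
            qc.site_leakage_check(x, np.array(["a"] * 20), mode="raw")


class TestSampleDescriptives:
    def test_identical_groups_null_statistics(self):
        half = pd.DataFrame({
            "subject_id": [f"a{i}" for i in range(20)],
            "group": "ASC",
            "age": np.linspace(8, 16, 20),
            "fiq": np.linspace(90, 120, 20),
        })
        other = half.copy()
        other["subject_id"] = [f"c{i}" for i in range(20)]
        other["group"] = "CMP"
        res = qc.sample_descriptives(pd.concat([half, other], ignore_index=True))
        assert res["welch"]["age"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["welch"]["age"]["d"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_effect_size(self, rng):
        n = 100
        pheno = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "group": ["ASC"] * n + ["CMP"] * n,
            "age": np.concatenate([rng.normal(12, 2, n), rng.normal(14, 2, n)]),
            "fiq": rng.normal(107, 11, 2 * n),
        })
        res = qc.sample_descriptives(pheno)
        assert 0.7 <= abs(res["welch"]["age"]["d"]) <= 1.3

    def test_welch_df_bounded_by_pooled(self, rng):
        pheno = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(60)],
            "group": ["ASC"] * 30 + ["CMP"] * 30,
            "age": np.concatenate([rng.normal(12, 1, 30), rng.normal(12, 4, 30)]),
            "fiq": rng.normal(107, 11, 60),
        })
        res = qc.sample_descriptives(pheno)
        assert res["welch"]["age"]["df"] <= 58.0

    def test_site_statistics_present(self):
        cfg = sd.SimulationConfig(n_per_group=40, T=100, seed=8)
        pheno = sd.generate_phenotypes(cfg)
        res = qc.sample_descriptives(pheno)
        assert "site_counts" in res
        aov = res["age_by_site_anova"]
        assert aov["p"] < 0.05  # sites are age-banded by construction
        assert 0 <= aov["omega2"] <= aov["eta2"] <= 1

    def test_single_group_rejected(self):
        pheno = pd.DataFrame({"subject_id": ["a", "b"], "group": ["ASC", "ASC"],
                              "age": [10, 12], "fiq": [100, 110]})
        with pytest.raises(ValueError, match="two groups"):
            qc.sample_descriptives(pheno)
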