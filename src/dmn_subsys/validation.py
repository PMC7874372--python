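"""Simulation experiments that characterise the pipeline's operating
properties: type-I error calibration of the bootstrap-permutation GLM,
power / effect-size recovery for the planted age × group interaction,
and the site-leakage classifier ordering (raw > residualized ≈ chance).

These are the package's own validation studies, run both by the test
suite and by ``scripts/acceptance.py``.  Problem sizes are chosen so a
full run completes in minutes on one CPU.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .rois import RoiSet
from . import synthetic_data as synth
from . import connectivity as conn
from . import network_metrics as netm
from . import quality_control as qc_mod
from .inference import GlmSpec, bootstrap_permutation_test


def _child_seed(seed: int, tag: int, k: int = 0) -> int:
    return int(np.random.SeedSequence((seed, tag, k)).generate_state(1)[0] % (2**31))


def type_i_error(
    n_datasets: int = 500,
    n: int = 100,
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of each coefficient under the global null.

    Each dataset has a realistic design (uniform ages, balanced groups,
    normal IQ) and a pure-noise outcome; a well-calibrated test rejects
    at close to `alpha` for every coefficient.
    """
    coefs = ("age", "group", "age_x_group")
    pvals = {c: np.empty(n_datasets) for c in coefs}
    for d in range(n_datasets):
        rng = np.random.default_rng(_child_seed(seed, 1, d))
        X = pd.DataFrame({
            "age": rng.uniform(6, 18, n),
            "group": np.repeat(["ASC", "CMP"], n // 2),
            "fiq": rng.normal(107, 11, n),
        })
        y = rng.normal(size=n)
        spec = GlmSpec(nuisance=("fiq",), n_boot=n_boot,
                       seed=_child_seed(seed, 2, d))
        res = bootstrap_permutation_test(y, X, spec)
        tab = res.table.set_index("coef")
        for c in coefs:
            pvals[c][d] = tab.loc[c, "p_raw"]
    out = {c: float((pvals[c] <= alpha).mean()) for c in coefs}
    out["p_values"] = pvals
    out["n_datasets"] = n_datasets
    return out


def _cohort_outcomes(config: synth.SimulationConfig, roiset: RoiSet) -> pd.DataFrame:
    """Simulate a cohort and push it through connectivity + metrics."""
    partition = roiset.partition()
    pheno = synth.generate_phenotypes(config)
    rows = []
    for _, r in pheno.iterrows():
        ts = synth.generate_timeseries(r, roiset, config)
        cm = conn.subject_connectivity(ts)
        within, between = netm.module_strengths(cm.z, partition, cm.labels)
        rows.append({
            "subject_id": r["subject_id"],
            "between": between,
            "Q": netm.modularity_index(cm.z, partition, cm.labels),
        })
    return pheno.merge(pd.DataFrame(rows), on="subject_id")


def power_recovery(
    n_replicates: int = 100,
    n_per_group: int = 200,
    T: int = 200,
    n_boot: int = 200,
    target_beta: float = -0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Detection rate and recovered effect size for a planted interaction.

    The generator's between-subsystem slope is calibrated so the
    standardized age × group coefficient on between-module strength
    equals `target_beta`; each replicate simulates a fresh cohort, runs
    the full connectivity → metrics → GLM chain, and records the
    interaction p-value on between-module strength and on Q plus the
    recovered coefficient.
    """
    roiset = RoiSet.default()
    base = synth.SimulationConfig(n_per_group=n_per_group, T=T,
                                  seed=_child_seed(seed, 3))
    cal = synth.calibrate_interaction(base, target_beta=target_beta)

    betas = np.empty(n_replicates)
    hit_between = np.zeros(n_replicates, dtype=bool)
    hit_q = np.zeros(n_replicates, dtype=bool)
    for rep in range(n_replicates):
        cfg = replace(cal, seed=_child_seed(seed, 4, rep))
        tab = _cohort_outcomes(cfg, roiset)
        for outcome in ("between", "Q"):
            spec = GlmSpec(nuisance=("fiq",), n_boot=n_boot,
                           seed=_child_seed(seed, 5, rep))
            res = bootstrap_permutation_test(tab[outcome], tab, spec)
            row = res.table.set_index("coef").loc["age_x_group"]
            if outcome == "between":
                betas[rep] = row["beta_median"]
                hit_between[rep] = row["p_raw"] <= alpha
            else:
                hit_q[rep] = row["p_raw"] <= alpha
    return {
        "planted_beta": float(target_beta),
        "calibrated_slope_per_year": float(cal.beta_interaction),
        "median_beta_hat": float(np.median(betas)),
        "detection_between": float(hit_between.mean()),
        "detection_q": float(hit_q.mean()),
        "sign_recovery": float((np.sign(betas) == np.sign(target_beta)).mean()),
        "n_replicates": n_replicates,
    }


def leakage_experiment(
    n: int = 300,
    n_sites: int = 3,
    n_features: int = 55,
    offset_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Site-classification accuracy before and after residualization.

    Emulates site leakage mediated by image quality: sites shift the
    latent quality factors (through the cohort generator), and each
    subject's edge features are contaminated in proportion to that
    subject's quality-factor scores.  Because sites differ in quality,
    the features carry site information; a linear SVM then predicts
    site from the features raw, after regressing out the four estimated
    quality factors, and after regressing out site indicators.
    """
    cfg = synth.SimulationConfig(
        n_per_group=n // 2, T=100, n_sites=n_sites, site_effect_sd=2.0,
        seed=_child_seed(seed, 6),
    )
    pheno = synth.generate_phenotypes(cfg)
    iqm = synth.generate_iqm_table(pheno, cfg)
    factors, _ = qc_mod.iqm_pca(iqm)
    fac = factors.drop(columns=["subject_id"]).to_numpy()

    rng = np.random.default_rng(_child_seed(seed, 7))
    site = pheno["site"].to_numpy()
    fac_z = (fac - fac.mean(axis=0)) / fac.std(axis=0)
    mixing = rng.normal(0.0, offset_sd, size=(fac.shape[1], n_features))
    x = rng.normal(size=(n, n_features)) + fac_z @ mixing
    out = {
        mode: qc_mod.site_leakage_check(
            x, site, mode=mode, seed=_child_seed(seed, 8), quality=fac
        )
        for mode in ("raw", "quality_regressed", "site_regressed")
    }
    out["chance"] = 1.0 / n_sites
    return out
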