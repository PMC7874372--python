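"""Motion and image-quality control.

Covers the per-frame motion summaries (framewise displacement, DVARS),
the sample-level exclusion rules (mean FD > 0.5 mm, mean DVARS > 5 %,
full-scale IQ outside [83, 130]), movement-outlier flagging at the pooled
95th percentile, reduction of 30 image-quality metrics to four principal
components, an SVM check for acquisition-site leakage in connectivity
features, and descriptive group comparisons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

log = logging.getLogger(__name__)

FD_MAX_MM = 0.5
DVARS_MAX_PCT = 5.0
IQ_LOW = 83.0
IQ_HIGH = 130.0
HEAD_RADIUS_MM = 50.0
OUTLIER_PERCENTILE = 95.0


def framewise_displacement(
    motion: np.ndarray | pd.DataFrame, head_radius: float = HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement from 6 rigid-body parameters.

    ``fd_t = Σ|Δtrans_t| + head_radius · Σ|Δrot_t|`` with translations in
    mm (columns 0–2), rotations in radians (columns 3–5) converted to arc
    length on a `head_radius` mm sphere.  The first frame is 0 by
    convention.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must be T×6, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least two frames")
    d = np.abs(np.diff(m, axis=0))
    fd = np.zeros(m.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return fd


def dvars(data: np.ndarray) -> np.ndarray:
    """Standardized DVARS in percent of the grand mean signal.

    Raw DVARS at frame t is the RMS over voxels (or ROIs) of the backward
    temporal difference; it is scaled to 100·raw/mean(data).  First frame 0.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be T×V with T >= 2")
    grand_mean = x.mean()
    if grand_mean == 0:
        raise ValueError("grand mean signal is zero; cannot standardize DVARS")
    raw = np.sqrt((np.diff(x, axis=0) ** 2).mean(axis=1))
    out = np.zeros(x.shape[0])
    out[1:] = 100.0 * raw / grand_mean
    return out


@dataclass(frozen=True)
class QcSeries:
    """Per-subject motion/quality summaries."""

    subject_id: str
    fd: np.ndarray
    dvars: np.ndarray

    @property
    def mean_fd(self) -> float:
        return float(np.mean(self.fd))

    @property
    def mean_dvars(self) -> float:
        return float(np.mean(self.dvars))


def qc_from_subject(subject_id: str, confounds: pd.DataFrame, data: np.ndarray) -> QcSeries:
    """Compute FD (from the 6 motion confounds) and DVARS (from the data)."""
    motion = confounds[["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]]
    return QcSeries(subject_id, framewise_displacement(motion.to_numpy(float)), dvars(data))


def qc_summary_table(qc: list[QcSeries]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [q.subject_id for q in qc],
            "mean_fd": [q.mean_fd for q in qc],
            "mean_dvars": [q.mean_dvars for q in qc],
        }
    )


def apply_exclusions(
    pheno: pd.DataFrame,
    qc: pd.DataFrame,
    fd_max: float = FD_MAX_MM,
    dvars_max: float = DVARS_MAX_PCT,
    iq_low: float = IQ_LOW,
    iq_high: float = IQ_HIGH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the motion and IQ exclusion rules.

    Rules, in order (the first match is the recorded reason): mean FD
    above `fd_max` ("FD"), mean DVARS above `dvars_max` ("DVARS"),
    full-scale IQ below `iq_low` ("IQ_low") or above `iq_high`
    ("IQ_high").

    Parameters
    ----------
    qc :
        Table with subject_id, mean_fd, mean_dvars (see qc_summary_table).

    Returns
    -------
    (retained, exclusion_log) :
        `retained` is the filtered phenotype table; `exclusion_log` has
        columns (subject_id, reason).
    """
    qc_idx = qc.set_index("subject_id")
    missing = [s for s in pheno["subject_id"] if s not in qc_idx.index]
    if missing:
        raise ValueError(f"no QC data for subjects: {missing}")
    reasons = []
    for _, row in pheno.iterrows():
        q = qc_idx.loc[row["subject_id"]]
        if q["mean_fd"] > fd_max:
            reasons.append("FD")
        elif q["mean_dvars"] > dvars_max:
            reasons.append("DVARS")
        elif row["fiq"] < iq_low:
            reasons.append("IQ_low")
        elif row["fiq"] > iq_high:
            reasons.append("IQ_high")
        else:
            reasons.append(None)
    reasons = pd.Series(reasons, index=pheno.index)
    excluded = pd.DataFrame(
        {"subject_id": pheno.loc[reasons.notna(), "subject_id"],
         "reason": reasons.dropna()}
    ).reset_index(drop=True)
    retained = pheno.loc[reasons.isna()].reset_index(drop=True)
    return retained, excluded


def movement_outliers(
    qc: pd.DataFrame, percentile: float = OUTLIER_PERCENTILE
) -> pd.DataFrame:
    """Flag subjects above the pooled 95th percentile of mean FD or DVARS.

    Percentiles use linear interpolation between order statistics; flags
    require strict exceedance, so identical values never flag anyone.
    """
    if len(qc) < 20:
        log.warning("fewer than 20 subjects; the %gth percentile is unstable",
                    percentile)
    fd_thr = np.percentile(qc["mean_fd"], percentile)
    dv_thr = np.percentile(qc["mean_dvars"], percentile)
    return pd.DataFrame(
        {
            "subject_id": qc["subject_id"],
            "fd_outlier": qc["mean_fd"].to_numpy() > fd_thr,
            "dvars_outlier": qc["mean_dvars"].to_numpy() > dv_thr,
        }
    )


def iqm_pca(iqm: pd.DataFrame, n_factors: int = 4) -> tuple[pd.DataFrame, np.ndarray]:
    """Reduce the image-quality-metric table to principal-component scores.

    Metric columns are z-scored; unrotated principal components are
    extracted and the first `n_factors` scores returned.  Each
    component's sign is fixed so its largest-|loading| metric loads
    positively, making the output deterministic.  Constant columns are
    dropped with a warning.

    Returns
    -------
    (factors, explained) :
        `factors` has subject_id plus f1..f{n_factors} (zero mean);
        `explained` gives the variance fraction of each factor.
    """
    if "subject_id" not in iqm.columns:
        raise ValueError("IQM table needs a subject_id column")
    metrics = iqm.drop(columns=["subject_id"])
    if len(iqm) < n_factors + 2:
        raise ValueError("need at least n_factors + 2 subjects")
    sd = metrics.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        log.warning("dropping constant IQM columns: %s", constant)
        metrics = metrics.drop(columns=constant)
        sd = sd.drop(constant)
    x = ((metrics - metrics.mean()) / sd).to_numpy(float)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| metric positive per component
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    explained = s**2 / (s**2).sum()
    factors = pd.DataFrame(
        scores[:, :n_factors], columns=[f"f{i + 1}" for i in range(n_factors)]
    )
    factors.insert(0, "subject_id", iqm["subject_id"].to_numpy())
    return factors, explained[:n_factors]


def _residualize(features: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    x = np.column_stack([covariates, np.ones(len(covariates))])
    beta = np.linalg.pinv(x) @ features
    return features - x @ beta


def site_leakage_check(
    features: pd.DataFrame | np.ndarray,
    site: pd.Series | np.ndarray,
    mode: str = "raw",
    seed: int = 0,
    quality: pd.DataFrame | np.ndarray | None = None,
    test_fraction: float = 1.0 / 3.0,
) -> float:
    """Balanced accuracy of a linear SVM predicting acquisition site.

    Features (subject × edge connectivity values) are optionally
    residualized per column: mode ``"quality_regressed"`` regresses out
    the four quality factors, ``"site_regressed"`` regresses out site
    indicator columns, ``"raw"`` leaves them untouched.  The
    residualization (like the feature z-scoring) is fitted on the
    training split only and applied to both splits, so no information
    crosses the split in either direction.  The classifier (linear
    kernel, C = 1) is trained on a seeded, stratified two-thirds split
    and class-size-adjusted accuracy on the held-out third is returned.
    """
    x = np.asarray(features, dtype=float)
    site = np.asarray(site)
    classes, counts = np.unique(site, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two sites")
    if counts.min() < 6:
        raise ValueError("need at least 6 subjects per site")
    if mode not in ("raw", "quality_regressed", "site_regressed"):
        raise ValueError(f"unknown mode {mode!r}")

    idx_tr, idx_te = train_test_split(
        np.arange(len(site)), test_size=test_fraction, stratify=site,
        random_state=seed,
    )
    if mode == "quality_regressed":
        if quality is None:
            raise ValueError("quality factors required for quality_regressed mode")
        q = np.asarray(
            quality.drop(columns=["subject_id"]) if isinstance(quality, pd.DataFrame)
            and "subject_id" in quality.columns else quality,
            dtype=float,
        )
        cov = np.column_stack([q, np.ones(len(q))])
    elif mode == "site_regressed":
        dummies = (site[:, None] == classes[None, :]).astype(float)
        cov = np.column_stack([dummies[:, :-1], np.ones(len(site))])
    else:
        cov = None
    if cov is not None:
        beta = np.linalg.pinv(cov[idx_tr]) @ x[idx_tr]
        x = x - cov @ beta

    x_tr, x_te = x[idx_tr], x[idx_te]
    y_tr, y_te = site[idx_tr], site[idx_te]
    mu, sd = x_tr.mean(axis=0), x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((x_tr - mu) / sd, y_tr)
    pred = clf.predict((x_te - mu) / sd)
    return float(balanced_accuracy_score(y_te, pred))


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def sample_descriptives(
    pheno: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    group_col: str = "group",
) -> dict:
    """Descriptive group comparisons for the sample table.

    Welch-corrected t tests (with Cohen's d) for age, FIQ and — when QC
    is supplied — mean FD and DVARS; a χ² test of per-site counts by
    group; and a one-way ANOVA of age on site with η² and ω² effect
    sizes.
    """
    groups = pheno[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = sorted(groups)
    tab = pheno.copy()
    if qc is not None:
        tab = tab.merge(qc, on="subject_id", how="left")

    out: dict = {"groups": (g1, g2), "welch": {}}
    for col in ["age", "fiq", "mean_fd", "mean_dvars"]:
        if col not in tab.columns:
            continue
        a = tab.loc[tab[group_col] == g1, col].dropna().to_numpy(float)
        b = tab.loc[tab[group_col] == g2, col].dropna().to_numpy(float)
        res = stats.ttest_ind(a, b, equal_var=False)
        out["welch"][col] = {
            "t": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
            "d": _cohens_d(a, b),
        }

    if "site" in tab.columns and tab["site"].nunique() > 1:
        counts = pd.crosstab(tab["site"], tab[group_col])
        chi2, p, dof, _ = stats.chi2_contingency(counts)
        out["site_counts"] = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}

        site_groups = [g["age"].to_numpy(float) for _, g in tab.groupby("site")]
        f, p = stats.f_oneway(*site_groups)
        k, n = len(site_groups), len(tab)
        grand = tab["age"].mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in site_groups)
        ss_t = ((tab["age"] - grand) ** 2).sum()
        ms_w = (ss_t - ss_b) / (n - k)
        eta2 = ss_b / ss_t if ss_t > 0 else 0.0
        omega2 = (ss_b - (k - 1) * ms_w) / (ss_t + ms_w) if ss_t + ms_w > 0 else 0.0
        out["age_by_site_anova"] = {
            "F": float(f), "df": (k - 1, n - k), "p": float(p),
            "eta2": float(eta2), "omega2": float(max(omega2, 0.0)),
        }
    return out
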