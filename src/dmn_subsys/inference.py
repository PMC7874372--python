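"""Bootstrap-permutation GLM inference for connectivity outcomes.

Every outcome (an edge's Fisher-z value, a module's summed strength, the
modularity index, or a symptom score) is modelled with an ordinary
least-squares GLM on standardized variables: continuous predictors and
the outcome are z-scored, group is coded −0.5 (CMP) / +0.5 (ASC), and
the age × group interaction is the product of the coded columns.

Significance is assessed without distributional assumptions:

1. `n_boot` bootstrap resamples (subjects drawn with replacement) give a
   coefficient distribution whose median is the reported standardized β
   and whose 5th/95th percentiles form the reported interval.
2. A null distribution of the same size is built from resamples in which
   the outcome is scrambled relative to the predictors, removing any
   outcome-predictor association while preserving both marginals.  By
   default the outcome is permuted within each bootstrap resample; this
   keeps the null coefficient variance equal to that of the observed
   bootstrap median and makes the test well calibrated.  Scrambling the
   full sample before resampling (`null_scheme="permute_before"`) is
   also available but is markedly conservative, because the resampling
   step then adds a second, independent layer of coefficient variance
   on top of the permutation variance.
3. ``p = (1 + #{|β_null| ≥ |median β_boot|}) / (1 + n_boot)``, two-sided.

Multiple-testing families: Benjamini–Hochberg FDR across the 55 edges
(separately per coefficient), Bonferroni (m = 4) across the four summed
strength outcomes; the modularity index forms its own family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network_metrics import NetworkSummary
from .quality_control import movement_outliers

log = logging.getLogger(__name__)

GROUP_CODES = {"CMP": -0.5, "ASC": 0.5}

DEFAULT_PREDICTORS = ("age", "group", "age_x_group")
DEFAULT_NUISANCE = ("fiq", "f1", "f2", "f3", "f4")

STRENGTH_OUTCOMES = ("between", "within_MTL", "within_dMPFC", "within_Core")


@dataclass(frozen=True)
class GlmSpec:
    """Model layout and resampling parameters for one GLM family."""

    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    nuisance: tuple[str, ...] = DEFAULT_NUISANCE
    n_boot: int = 1000
    seed: int = 0
    tail: str = "two_sided"
    null_scheme: str = "permute_within_resample"

    def __post_init__(self) -> None:
        if set(self.predictors) & set(self.nuisance):
            raise ValueError("predictors and nuisance must be disjoint")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.tail != "two_sided":
            raise ValueError("only two-sided tests are implemented")
        if self.null_scheme not in ("permute_within_resample", "permute_before"):
            raise ValueError(f"unknown null_scheme {self.null_scheme!r}")

    @property
    def design_columns(self) -> tuple[str, ...]:
        return tuple(self.predictors) + tuple(self.nuisance)


@dataclass
class GlmResult:
    """Per-outcome coefficients, intervals, distributions and p-values."""

    outcome: str
    table: pd.DataFrame
    boot_distribution: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    null_distribution: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _code_column(name: str, values: pd.Series | np.ndarray) -> np.ndarray:
    """Raw column → numeric (z-scoring of continuous columns happens per fit)."""
    v = pd.Series(np.asarray(values).ravel())
    if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == bool:
        levels = sorted(v.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(f"column {name!r} must have exactly 2 levels, got {levels}")
        if set(levels) == {"ASC", "CMP"}:
            codes = v.astype(str).map(GROUP_CODES)
        else:
            codes = v.astype(str).map({levels[0]: -0.5, levels[1]: 0.5})
        return codes.to_numpy(float)
    return v.to_numpy(float)


def _parse_design(
    X: pd.DataFrame, columns: tuple[str, ...]
) -> tuple[list[str], dict[str, np.ndarray], set[str], list[tuple[str, str, str]]]:
    """Split design columns into base columns and `_x_` interaction terms."""
    base: dict[str, np.ndarray] = {}
    binary: set[str] = set()
    interactions: list[tuple[str, str, str]] = []
    for name in columns:
        if "_x_" in name and name not in X.columns:
            a, b = name.split("_x_", 1)
            for parent in (a, b):
                if parent not in X.columns:
                    raise ValueError(
                        f"interaction {name!r} needs column {parent!r} in the design"
                    )
            interactions.append((name, a, b))
            continue
        if name not in X.columns:
            raise ValueError(f"design column {name!r} missing from X")
    needed = {c for _, a, b in interactions for c in (a, b)}
    needed |= {c for c in columns if "_x_" not in c or c in X.columns}
    for name in needed:
        vals = X[name]
        coded = _code_column(name, vals)
        base[name] = coded
        raw = pd.Series(np.asarray(vals).ravel())
        if raw.dtype == object or isinstance(raw.dtype, pd.CategoricalDtype) \
                or raw.dtype == bool or set(np.unique(coded)) <= {-0.5, 0.5}:
            binary.add(name)
    return list(columns), base, binary, interactions


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """Z-score along the last-but-one axis (per resample), guarding sd=0."""
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _batch_fit(
    y: np.ndarray,
    idx_x: np.ndarray,
    idx_y: np.ndarray,
    base: dict[str, np.ndarray],
    binary: set[str],
    columns: list[str],
    interactions: list[tuple[str, str, str]],
) -> np.ndarray:
    """Standardized OLS coefficients for a batch of (resampled) fits.

    idx_x / idx_y are (B, n) row-index matrices for the design and the
    outcome respectively (they differ only for scrambled null draws).
    Returns (B, K) coefficients in `columns` order (intercept dropped).
    """
    b_n = idx_x.shape
    processed: dict[str, np.ndarray] = {}
    for name, vals in base.items():
        sampled = vals[idx_x]
        processed[name] = sampled if name in binary else _zscore_rows(sampled)
    for name, a, b in interactions:
        processed[name] = processed[a] * processed[b]

    design = np.stack([processed[c] for c in columns] + [np.ones(b_n)], axis=-1)
    yz = _zscore_rows(y[idx_y])

    gram = np.einsum("bnk,bnl->bkl", design, design)
    rhs = np.einsum("bnk,bn->bk", design, yz)
    try:
        coef = np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        log.warning("singular design in batch fit; using pseudo-inverse")
        coef = np.einsum("bkl,bl->bk", np.linalg.pinv(gram), rhs)
    return coef[:, :-1]


def fit_glm(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    columns: tuple[str, ...] | None = None,
) -> pd.Series:
    """Standardized OLS coefficients for one outcome.

    The outcome and continuous predictors are z-scored, two-level
    columns are coded ±0.5, and any requested ``a_x_b`` column is built
    as the product of the processed parents.  An intercept is included
    but not reported.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("y and X must have the same number of rows")
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    cols = columns if columns is not None else tuple(X.columns)
    order, base, binary, inter = _parse_design(X, cols)
    idx = np.arange(len(y))[None, :]
    coef = _batch_fit(y, idx, idx, base, binary, order, inter)[0]
    return pd.Series(coef, index=list(order), name="beta")


def bootstrap_permutation_test(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    spec: GlmSpec,
    outcome: str = "y",
) -> GlmResult:
    """Bootstrap median coefficients against a scrambled-association null.

    See the module docstring for the procedure.  Identical (data, spec)
    always reproduce the identical result.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects to scramble associations")
    if n < 20:
        log.warning("n = %d subjects; resampling inference is unstable below 20", n)
    if y.std() == 0:
        raise ValueError("outcome has zero variance")

    order, base, binary, inter = _parse_design(X, spec.design_columns)
    rng = np.random.default_rng(spec.seed)
    nb = spec.n_boot

    idx_boot = rng.integers(0, n, size=(nb, n))
    boot = _batch_fit(y, idx_boot, idx_boot, base, binary, order, inter)

    idx_null = rng.integers(0, n, size=(nb, n))
    if spec.null_scheme == "permute_within_resample":
        idx_null_y = rng.permuted(idx_null, axis=1)
    else:  # permute_before: scramble the sample, then resample jointly
        perms = np.argsort(rng.random((nb, n)), axis=1)
        idx_null_y = np.take_along_axis(perms, idx_null, axis=1)
    null = _batch_fit(y, idx_null, idx_null_y, base, binary, order, inter)

    med = np.median(boot, axis=0)
    lo, hi = np.percentile(boot, [5.0, 95.0], axis=0)
    p_raw = (1.0 + (np.abs(null) >= np.abs(med)[None, :]).sum(axis=0)) / (1.0 + nb)

    table = pd.DataFrame(
        {
            "coef": list(order),
            "beta_median": med,
            "ci_lo": lo,
            "ci_hi": hi,
            "p_raw": p_raw,
        }
    )
    table["role"] = [
        "predictor" if c in spec.predictors else "nuisance" for c in order
    ]
    return GlmResult(
        outcome=outcome,
        table=table,
        boot_distribution={c: boot[:, k] for k, c in enumerate(order)},
        null_distribution={c: null[:, k] for k, c in enumerate(order)},
    )


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(p: np.ndarray | pd.Series, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, m defaulting to the family size."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(p * (m if m is not None else len(p)), 1.0)


def _check_alignment(ids_a: pd.Series, ids_b: pd.Series, what: str) -> None:
    a, b = set(ids_a), set(ids_b)
    if a != b:
        raise ValueError(
            f"subject mismatch in {what}: only-left={sorted(a - b)[:5]}, "
            f"only-right={sorted(b - a)[:5]}"
        )


def _design_frame(
    pheno: pd.DataFrame, quality: pd.DataFrame | None, spec: GlmSpec
) -> pd.DataFrame:
    tab = pheno.copy()
    if quality is not None:
        _check_alignment(pheno["subject_id"], quality["subject_id"], "quality factors")
        tab = tab.merge(quality, on="subject_id")
    missing = [
        c for c in spec.design_columns
        if "_x_" not in c and c not in tab.columns
    ]
    if missing:
        raise ValueError(f"design columns missing from inputs: {missing}")
    return tab


def edgewise_analysis(
    conn_matrices: list,
    pheno: pd.DataFrame,
    quality: pd.DataFrame | None,
    spec: GlmSpec,
    partition=None,
) -> pd.DataFrame:
    """Bootstrap-permutation GLM on every ROI-pair edge.

    Runs one test per unordered ROI pair (55 for 11 nodes) with the
    edge's Fisher-z value as the outcome, then applies BH-FDR across
    edges separately within each predictor family.

    Returns a tidy table: one row per (edge, coefficient) with
    beta_median, the 5–95 % interval, p_raw and p_fdr (predictors only).
    """
    ids = pd.Series([c.subject_id for c in conn_matrices])
    _check_alignment(ids, pheno["subject_id"], "connectivity matrices")
    by_id = {c.subject_id: c for c in conn_matrices}
    ordered = [by_id[s] for s in pheno["subject_id"]]
    labels = ordered[0].labels
    stack = np.stack([c.z for c in ordered])  # subjects × N × N

    tab = _design_frame(pheno, quality, spec)
    mod_of = partition.assignment if partition is not None else None

    iu, ju = np.triu_indices(len(labels), k=1)
    rows = []
    for e, (i, j) in enumerate(zip(iu, ju)):
        edge_spec = GlmSpec(
            predictors=spec.predictors, nuisance=spec.nuisance,
            n_boot=spec.n_boot,
            seed=int(np.random.SeedSequence((spec.seed, e)).generate_state(1)[0] % (2**31)),
            null_scheme=spec.null_scheme,
        )
        res = bootstrap_permutation_test(
            stack[:, i, j], tab, edge_spec, outcome=f"{labels[i]}--{labels[j]}"
        )
        for _, r in res.table.iterrows():
            row = {
                "roi_i": labels[i],
                "roi_j": labels[j],
                "coef": r["coef"],
                "role": r["role"],
                "beta_median": r["beta_median"],
                "ci_lo": r["ci_lo"],
                "ci_hi": r["ci_hi"],
                "p_raw": r["p_raw"],
            }
            if mod_of is not None:
                mi, mj = mod_of[labels[i]], mod_of[labels[j]]
                row["module_pair"] = f"{mi}--{mj}" if mi != mj else mi
            rows.append(row)
    out = pd.DataFrame(rows)

    out["p_fdr"] = np.nan
    for coef in spec.predictors:
        mask = out["coef"] == coef
        out.loc[mask, "p_fdr"] = bh_fdr(out.loc[mask, "p_raw"])
    return out


def module_level_analysis(
    summaries: pd.DataFrame,
    pheno: pd.DataFrame,
    quality: pd.DataFrame | None,
    spec: GlmSpec,
    exclude_outliers: bool = False,
    qc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """GLMs on module strengths and the modularity index.

    Outcomes are the four summed strengths (between, within each
    subsystem) and Q.  The strength family is Bonferroni-corrected
    (m = 4); Q forms its own family and is reported uncorrected.  With
    `exclude_outliers`, subjects above the pooled 95th FD/DVARS
    percentile (per `qc`) are dropped before fitting.
    """
    if isinstance(summaries, list) and summaries and isinstance(summaries[0], NetworkSummary):
        from .network_metrics import summaries_table
        summaries = summaries_table(summaries)
    _check_alignment(summaries["subject_id"], pheno["subject_id"], "network summaries")

    tab = pheno.merge(summaries, on="subject_id")
    if quality is not None:
        _check_alignment(pheno["subject_id"], quality["subject_id"], "quality factors")
        tab = tab.merge(quality, on="subject_id")
    if exclude_outliers:
        if qc is None:
            raise ValueError("qc table required to exclude movement outliers")
        flags = movement_outliers(qc)
        bad = flags.loc[flags["fd_outlier"] | flags["dvars_outlier"], "subject_id"]
        tab = tab[~tab["subject_id"].isin(set(bad))].reset_index(drop=True)

    outcomes = [c for c in STRENGTH_OUTCOMES if c in tab.columns] + ["Q"]
    rows = []
    for k, outcome in enumerate(outcomes):
        o_spec = GlmSpec(
            predictors=spec.predictors, nuisance=spec.nuisance,
            n_boot=spec.n_boot,
            seed=int(np.random.SeedSequence((spec.seed, 1000 + k)).generate_state(1)[0] % (2**31)),
            null_scheme=spec.null_scheme,
        )
        res = bootstrap_permutation_test(
            tab[outcome], tab, o_spec, outcome=outcome
        )
        sub = res.table[res.table["role"] == "predictor"].copy()
        sub.insert(0, "outcome", outcome)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)

    out["p_corrected"] = out["p_raw"]
    out["correction"] = "none"
    strength_mask = out["outcome"].isin(STRENGTH_OUTCOMES)
    m = out.loc[strength_mask, "outcome"].nunique()
    out.loc[strength_mask, "p_corrected"] = bonferroni(
        out.loc[strength_mask, "p_raw"], m
    )
    out.loc[strength_mask, "correction"] = "Bonferroni"
    out["n_subjects"] = len(tab)
    out["excluded_outliers"] = exclude_outliers
    return out


def symptom_association(
    scores: pd.Series,
    summaries: pd.DataFrame,
    pheno: pd.DataFrame,
    quality: pd.DataFrame | None,
    spec: GlmSpec | None = None,
    measures: tuple[str, ...] = ("Q",) + STRENGTH_OUTCOMES,
) -> pd.DataFrame:
    """Symptom score as outcome, one GLM per DMN measure.

    Nuisance terms: full-scale IQ, the four quality factors (when
    provided) and age both linear and squared (age is centred before
    squaring).  Subjects with missing scores are dropped (logged).
    """
    spec = spec or GlmSpec()
    tab = pheno.merge(summaries, on="subject_id")
    if quality is not None:
        tab = tab.merge(quality, on="subject_id")
    tab = tab.set_index("subject_id")
    tab["score"] = scores
    n_missing = tab["score"].isna().sum()
    if n_missing:
        log.info("dropping %d subjects without symptom scores", n_missing)
    tab = tab.dropna(subset=["score"]).reset_index()
    if len(tab) < 20:
        log.warning("only %d subjects with scores; proceeding", len(tab))

    age_c = tab["age"] - tab["age"].mean()
    tab["age_sq"] = age_c**2
    nuisance = ["fiq", "age", "age_sq"]
    if quality is not None:
        nuisance += [c for c in ("f1", "f2", "f3", "f4") if c in tab.columns]

    rows = []
    for k, measure in enumerate(measures):
        m_spec = GlmSpec(
            predictors=(measure,), nuisance=tuple(nuisance),
            n_boot=spec.n_boot,
            seed=int(np.random.SeedSequence((spec.seed, 2000 + k)).generate_state(1)[0] % (2**31)),
            null_scheme=spec.null_scheme,
        )
        res = bootstrap_permutation_test(
            tab["score"], tab, m_spec, outcome=f"score~{measure}"
        )
        r = res.table[res.table["coef"] == measure].iloc[0]
        rows.append(
            {
                "measure": measure,
                "beta_median": r["beta_median"],
                "ci_lo": r["ci_lo"],
                "ci_hi": r["ci_hi"],
                "p_raw": r["p_raw"],
                "n": len(tab),
            }
        )
    return pd.DataFrame(rows)


def median_split(pheno: pd.DataFrame) -> pd.Series:
    """Per-group median split of age into "younger" / "older" labels.

    Subjects at or below their group's median age are "younger".  Used
    for visualisation only; all models treat age as continuous.
    """
    labels = pd.Series(index=pheno.index, dtype=object)
    for _, idx in pheno.groupby("group").groups.items():
        ages = pheno.loc[idx, "age"]
        if len(ages) < 2:
            raise ValueError("need at least 2 subjects per group for a median split")
        med = ages.median()
        labels.loc[idx] = np.where(ages <= med, "younger", "older")
    return labels.rename("age_band")
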