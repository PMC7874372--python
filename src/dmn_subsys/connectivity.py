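"""From BOLD signals to per-subject Fisher-z connectivity matrices.

The processing chain mirrors a standard resting-state connectivity
pipeline: extract sphere-averaged ROI time series from a 4D volume (or
load them directly as tables), regress out a 32-column nuisance design
(6 motion parameters, CSF and white-matter means, their temporal
derivatives, squares and squared derivatives) optionally augmented with
CompCor components, detrend and band-pass filter (0.008–0.1 Hz), then
correlate all ROI pairs and apply Fisher's r-to-z transform.

Denoising order is fixed as detrend → confound regression → band-pass,
so that filtered-out confound frequencies are not reintroduced.  The
band-pass is a zero-phase 4th-order Butterworth applied forward-backward.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .rois import RoiSet

log = logging.getLogger(__name__)

#: fMRIPrep-dialect confound columns used as the regression base set.
BASE_CONFOUND_COLUMNS = (
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "csf",
    "white_matter",
)

DEFAULT_BAND_HZ = (0.008, 0.1)
FISHER_CLIP = 1e-7


@dataclass
class SubjectTimeSeries:
    """One subject's T×N ROI signal matrix plus confounds and TR."""

    subject_id: str
    data: np.ndarray
    tr: float
    confounds: pd.DataFrame | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (time × ROI)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in time series of {self.subject_id}")
        if not self.labels:
            self.labels = [f"roi{i}" for i in range(self.data.shape[1])]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N×N Fisher-z connectivity with zero diagonal."""

    subject_id: str
    z: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if not np.allclose(z, z.T, atol=1e-12, rtol=0.0):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity matrix contains non-finite values")
        z = z.copy()
        np.fill_diagonal(z, 0.0)
        object.__setattr__(self, "z", z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.labels, columns=self.labels)

    def edge_table(self) -> pd.DataFrame:
        """Long-format upper-triangle edges: (roi_i, roi_j, z)."""
        iu, ju = np.triu_indices(len(self.labels), k=1)
        return pd.DataFrame(
            {
                "roi_i": [self.labels[i] for i in iu],
                "roi_j": [self.labels[j] for j in ju],
                "z": self.z[iu, ju],
            }
        )


def extract_roi_timeseries(
    volume: np.ndarray, affine: np.ndarray, roiset: RoiSet
) -> np.ndarray:
    """Average the 4D volume within each ROI sphere, per time point.

    A voxel belongs to an ROI when its centre (mapped through `affine`
    to mm coordinates) lies within the ROI radius of the ROI centre.

    Parameters
    ----------
    volume :
        4-D array (x, y, z, t) in the same space as the ROI coordinates.
    affine :
        4×4 voxel-to-mm transform (NIfTI convention).

    Returns
    -------
    T×N matrix of sphere-averaged signals, columns ordered as the ROI set.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    nx, ny, nz, nt = volume.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    flat = volume.reshape(-1, nt)

    out = np.empty((nt, roiset.n))
    for k, (centre, radius, label) in enumerate(
        zip(roiset.coords, roiset.radii, roiset.labels)
    ):
        inside = np.einsum("ij,ij->i", mm - centre, mm - centre) <= radius**2
        if not inside.any():
            raise ValueError(f"ROI sphere {label!r} contains no voxels")
        out[:, k] = flat[inside].mean(axis=0)
    return out


def extract_from_nifti(path: str | Path, roiset: RoiSet) -> np.ndarray:
    """Sphere-averaged ROI time series from a 4D NIfTI-1 volume.

    The image's affine places voxels in the ROI coordinate (MNI mm)
    space; images without a usable affine are rejected.
    """
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got {img.ndim}-D")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise ValueError(f"{path}: no usable affine (sform/qform)")
    return extract_roi_timeseries(np.asarray(img.get_fdata()), affine, roiset)


def build_confound_matrix(confounds: pd.DataFrame) -> np.ndarray:
    """Expand 8 base confounds to the 32-column nuisance design.

    Column order: 8 base, 8 temporal derivatives (backward difference,
    first row zero-padded), 8 squared base, 8 squared derivatives.
    """
    missing = [c for c in BASE_CONFOUND_COLUMNS if c not in confounds.columns]
    if missing:
        raise ValueError(f"confound table missing columns: {missing}")
    base = confounds[list(BASE_CONFOUND_COLUMNS)].to_numpy(float)
    deriv = np.zeros_like(base)
    deriv[1:] = np.diff(base, axis=0)
    return np.column_stack([base, deriv, base**2, deriv**2])


def compcor_components(
    voxel_data: np.ndarray,
    n_components: int = 5,
    variance_fraction: float = 0.05,
) -> np.ndarray:
    """CompCor: principal-component time courses of high-variance voxels.

    Selects the ``ceil(variance_fraction · V)`` voxels with the highest
    temporal variance, mean-centres each, and returns the first
    `n_components` left singular vectors (unit-norm time courses).
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    t, v = voxel_data.shape
    if v < 20:
        raise ValueError("need at least 20 voxels for CompCor")
    if t <= n_components:
        raise ValueError("need more time points than components")
    n_sel = int(np.ceil(variance_fraction * v))
    if n_sel < n_components:
        raise ValueError(
            f"only {n_sel} voxels selected at fraction {variance_fraction}, "
            f"need >= {n_components}"
        )
    var = voxel_data.var(axis=0)
    sel = np.argsort(var)[::-1][:n_sel]
    x = voxel_data[:, sel] - voxel_data[:, sel].mean(axis=0)
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :n_components]


def regress_out(ts: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of `ts` against `design` + intercept."""
    x = np.column_stack([design, np.ones(design.shape[0])])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        log.warning("rank-deficient nuisance design; using pseudo-inverse")
    return ts - x @ (np.linalg.pinv(x) @ ts)


def denoise_timeseries(
    ts: np.ndarray,
    design: np.ndarray | None,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    filter_order: int = 4,
) -> np.ndarray:
    """Detrend, regress out the nuisance design, and band-pass filter.

    Steps per column: linear detrend → OLS residuals against the design
    (an intercept is appended internally) → zero-phase Butterworth
    band-pass.  Residuals are orthogonal to the design before filtering.

    Parameters
    ----------
    design :
        T×K nuisance matrix, or None for detrend + filter only.
    band :
        (low, high) in Hz; high must be below Nyquist = 1/(2·tr).
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= nyquist:
        raise ValueError(f"band high {high} Hz >= Nyquist {nyquist} Hz")

    out = signal.detrend(ts, axis=0, type="linear")
    if design is not None and design.shape[1] > 0:
        if design.shape[0] != ts.shape[0]:
            raise ValueError("design and time series row counts differ")
        if design.shape[1] >= ts.shape[0]:
            raise ValueError("more nuisance regressors than time points")
        out = regress_out(out, design)

    sos = signal.butter(filter_order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, out, axis=0)


def connectivity_matrix(
    ts: np.ndarray, subject_id: str = "", labels: list[str] | None = None
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI residuals, Fisher-z transformed.

    r is clipped to ±(1 − 1e-7) before atanh so degenerate perfectly
    correlated columns stay finite; the diagonal is set to 0.
    """
    ts = np.asarray(ts, dtype=float)
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        labels = labels or [f"roi{i}" for i in range(ts.shape[1])]
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI series: {bad}")
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    if labels is None:
        labels = [f"roi{i}" for i in range(ts.shape[1])]
    return ConnectivityMatrix(subject_id=subject_id, z=z, labels=labels)


def subject_connectivity(
    ts: SubjectTimeSeries,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    use_confounds: bool = True,
) -> ConnectivityMatrix:
    """Full per-subject chain: confound design → denoise → Fisher-z matrix."""
    design = None
    if use_confounds and ts.confounds is not None:
        design = build_confound_matrix(ts.confounds)
    clean = denoise_timeseries(ts.data, design, tr=ts.tr, band=band)
    return connectivity_matrix(clean, subject_id=ts.subject_id, labels=ts.labels)


def roi_tsnr(
    ts_collection: list[SubjectTimeSeries],
    site: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Temporal SNR per ROI per subject, with ANOVAs across ROIs.

    tSNR = temporal mean / temporal SD of the raw (un-denoised) series.
    A one-way ANOVA tests for tSNR differences between ROIs; when `site`
    is given (indexed by subject id), a two-way ANOVA with a site × ROI
    interaction is added.

    Returns
    -------
    (table, anova) :
        `table` is long format (subject_id, roi, tsnr); `anova` holds
        'roi' → (F, df, p) and optionally 'site_x_roi' → (F, df, p).
    """
    if len(ts_collection) < 2:
        raise ValueError("need at least two subjects")
    rows = []
    for ts in ts_collection:
        mu = ts.data.mean(axis=0)
        sd = ts.data.std(axis=0, ddof=1)
        for lab, m, s in zip(ts.labels, mu, sd):
            if s == 0:
                log.warning("zero temporal SD for %s/%s; tSNR undefined, skipped",
                            ts.subject_id, lab)
                continue
            rows.append({"subject_id": ts.subject_id, "roi": lab, "tsnr": m / s})
    table = pd.DataFrame(rows)
    if table["roi"].nunique() < 2:
        raise ValueError("need at least two ROIs")

    groups = [g["tsnr"].to_numpy() for _, g in table.groupby("roi")]
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = len(table)
    anova: dict = {"roi": {"F": float(f), "df": (k - 1, n - k), "p": float(p)}}

    if site is not None:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        tab = table.copy()
        tab["site"] = tab["subject_id"].map(site).astype(str)
        fit = ols("tsnr ~ C(roi) * C(site)", data=tab).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        inter = aov.loc["C(roi):C(site)"]
        anova["site_x_roi"] = {
            "F": float(inter["F"]),
            "df": (int(inter["df"]), int(aov.loc["Residual", "df"])),
            "p": float(inter["PR(>F)"]),
        }
    return table, anova


def load_roi_timeseries_tsv(
    path: str | Path,
    tr: float,
    confounds_path: str | Path | None = None,
    subject_id: str | None = None,
) -> SubjectTimeSeries:
    """Read a T×N ROI time-series TSV (header = ROI labels)."""
    path = Path(path)
    tab = pd.read_csv(path, sep="\t")
    conf = pd.read_csv(confounds_path, sep="\t") if confounds_path else None
    return SubjectTimeSeries(
        subject_id=subject_id or path.stem.replace("_timeseries", ""),
        data=tab.to_numpy(float),
        tr=tr,
        confounds=conf,
        labels=list(tab.columns),
    )
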