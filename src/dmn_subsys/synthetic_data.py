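"""Synthetic cohorts with planted DMN subsystem effects.

Generates everything the downstream pipeline consumes without any real
data: a phenotype table (two groups, uniform ages, clipped-normal IQ,
age-banded acquisition sites), per-subject multivariate ROI time series
whose target correlation matrix has the three-subsystem block structure
— between-subsystem coupling declining with age, and declining faster in
the ASC group (the planted age × group interaction) — plus simulated
motion/CSF/WM confounds, small paintable 4D volumes, and a 30-column
image-quality-metric table driven by four latent factors with additive
site offsets.

Every generator is a pure function of (config, seed): the same
configuration reproduces byte-identical tables.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rois import RoiSet
from . import connectivity as conn
from . import network_metrics as netm

log = logging.getLogger(__name__)

#: arbitrary BOLD baseline added to all signals; sets the DVARS scale
#: (unit-variance fluctuations on this mean give ~2-3 % DVARS, the range
#: typical of the printed sample tables).
BOLD_BASELINE = 50.0

#: 30 image-quality-metric column names (MRIQC functional dialect).
IQM_COLUMNS = (
    "aor", "aqi", "dvars_nstd", "dvars_std", "dvars_vstd", "efc", "fber",
    "fd_mean", "fd_num", "fd_perc", "fwhm_avg", "fwhm_x", "fwhm_y",
    "fwhm_z", "gcor", "gsr_x", "gsr_y", "snr", "tsnr", "summary_bg_k",
    "summary_bg_mean", "summary_bg_stdv", "summary_fg_k",
    "summary_fg_mean", "summary_fg_stdv", "dummy_trs", "spikes_num",
    "outlier_frac", "ghost_ratio", "smoothness_ratio",
)

GROUPS = ("ASC", "CMP")

# motion simulation scales (random-walk innovation SDs)
_TRANS_STEP_MM = 0.03
_ROT_STEP_RAD = 0.0005
_SPIKE_STEP_MM = 0.5
# per-subject lognormal spread of noise and motion amplitude
_NOISE_LOGSD = 0.15
_MOTION_LOGSD = 0.4


def _rng(seed: int, tag: str, extra: int = 0) -> np.random.Generator:
    """Deterministic child generator for a named stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(tag.encode()), extra))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modelled study design at desk scale: two groups
    of 200 male participants aged 6–18 years, ~6.7 minutes of
    resting-state data at TR = 2 s, moderate within-subsystem coupling,
    weaker between-subsystem coupling that declines with age and
    declines roughly twice as fast in the ASC group, three acquisition
    sites confounded with age bands, and occasional motion spikes.

    Parameters
    ----------
    within_module_r :
        Correlation between nodes of the same subsystem (age-constant).
    between_module_r_base :
        Between-subsystem correlation at the mid-point of the age range.
    beta_age :
        Change of the between-subsystem correlation per year of age.
    beta_interaction :
        Additional per-year change in the ASC group only.
    noise_sd :
        SD of white measurement noise added to the unit-variance signal
        (each subject's noise scale varies mildly, lognormal around it).
    site_effect_sd :
        SD of additive per-site offsets (time-series mean shift and IQM
        shift).
    motion_spike_prob :
        Per-frame probability of a large motion step.
    """

    n_per_group: int = 200
    age_range: tuple[float, float] = (6.0, 18.0)
    T: int = 200
    TR: float = 2.0
    within_module_r: float = 0.5
    between_module_r_base: float = 0.25
    beta_age: float = -0.008
    beta_interaction: float = -0.008
    noise_sd: float = 0.4
    n_sites: int = 3
    site_effect_sd: float = 1.0
    motion_spike_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range
        if lo >= hi:
            raise ValueError(f"invalid age_range {self.age_range}: min >= max")
        if not 0 <= self.within_module_r < 1:
            raise ValueError("within_module_r must be in [0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        # every age/group combination must yield a (repairable) PD target
        roiset = RoiSet.default()
        for age in self.age_range:
            for group in GROUPS:
                target_covariance(age, group, roiset, self)

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


def generate_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    """Phenotype table: 2·n_per_group rows of (id, group, age, FIQ, site).

    Ages are uniform over the configured range; full-scale IQ is
    normal(107, 11) clipped to the inclusion window [84, 130]; symptom
    z-scores (SRS, ADOS) are generated for the ASC group only.  When
    more than one site is configured, sites are assigned by contiguous
    age band, deliberately confounding site with age.
    """
    rng = _rng(config.seed, "phenotypes")
    n = 2 * config.n_per_group
    ages = rng.uniform(*config.age_range, size=n)
    fiq = np.clip(rng.normal(107.0, 11.0, size=n), 84.0, 130.0)
    group = np.repeat(GROUPS, config.n_per_group)
    srs = np.where(group == "ASC", rng.normal(size=n), np.nan)
    ados = np.where(group == "ASC", rng.normal(size=n), np.nan)

    pheno = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "group": group,
            "age": ages,
            "fiq": fiq,
            "srs_z": srs,
            "ados_z": ados,
        }
    )
    if config.n_sites > 1:
        band = pd.qcut(pheno["age"], q=config.n_sites, labels=False)
        pheno["site"] = [f"site{int(b) + 1}" for b in band]
    else:
        pheno["site"] = "site1"
    return pheno


def _nearest_pd(c: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest positive-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(c)
    repaired = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def target_covariance(
    age: float, group: str, roiset: RoiSet, config: SimulationConfig
) -> np.ndarray:
    """Target inter-ROI correlation matrix for one subject.

    Block structure over the subsystem partition: diagonal 1,
    within-subsystem entries at ``within_module_r``, between-subsystem
    entries at ``between_module_r_base + beta_age·(age − mid) +
    1[ASC]·beta_interaction·(age − mid)``, clipped to ±0.95.  If the
    result is not positive definite it is repaired by eigenvalue
    clipping (logged).
    """
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range {config.age_range}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    da = age - config.age_mid
    between = config.between_module_r_base + config.beta_age * da
    if group == "ASC":
        between += config.beta_interaction * da
    between = float(np.clip(between, -0.95, 0.95))

    ci = roiset.partition().indices(roiset.labels)
    same = ci[:, None] == ci[None, :]
    c = np.where(same, config.within_module_r, between)
    np.fill_diagonal(c, 1.0)

    min_eig = np.linalg.eigvalsh(c).min()
    if min_eig <= 1e-8:
        log.warning(
            "target covariance not PD (min eig %.3g) at age %.1f group %s; "
            "applying nearest-PD repair", min_eig, age, group,
        )
        c = _nearest_pd(c)
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("target covariance not repairable to PD")
    return c


def simulate_motion(
    rng: np.random.Generator,
    T: int,
    spike_prob: float,
    amplitude: float = 1.0,
    spike_frames: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk rigid-body parameters with optional spike steps.

    Returns (motion T×6 [trans mm ×3, rot rad ×3], spike frame indices).
    """
    steps = np.column_stack(
        [
            rng.normal(0.0, _TRANS_STEP_MM * amplitude, size=(T, 3)),
            rng.normal(0.0, _ROT_STEP_RAD * amplitude, size=(T, 3)),
        ]
    )
    steps[0] = 0.0
    if spike_frames is None:
        spike_frames = np.flatnonzero(rng.random(T) < spike_prob)
        spike_frames = spike_frames[spike_frames > 0]
    else:
        spike_frames = np.asarray(spike_frames, dtype=int)
    for t in spike_frames:
        axis = rng.integers(0, 3)
        steps[t, axis] += rng.choice([-1.0, 1.0]) * _SPIKE_STEP_MM
    return np.cumsum(steps, axis=0), spike_frames


def generate_timeseries(
    pheno_row: pd.Series | dict,
    roiset: RoiSet,
    config: SimulationConfig,
    spike_frames: np.ndarray | None = None,
) -> conn.SubjectTimeSeries:
    """One subject's T×11 ROI signals plus an fMRIPrep-style confound table.

    Signals are multivariate-normal draws with the subject's target
    correlation matrix, plus a per-site additive offset, a BOLD baseline
    and white noise.  Confounds comprise six random-walk motion
    parameters (with spikes at random or caller-fixed frames, recorded
    in ``confounds.attrs["spike_frames"]``) and AR(1) CSF/WM signals.
    """
    row = dict(pheno_row)
    if config.T < 50:
        raise ValueError("T must be >= 50")
    sub_idx = int(str(row["subject_id"]).split("-")[-1])
    rng = _rng(config.seed, "timeseries", sub_idx)

    c = target_covariance(row["age"], row["group"], roiset, config)
    l_chol = np.linalg.cholesky(c)
    signal = rng.standard_normal((config.T, roiset.n)) @ l_chol.T

    noise_scale = config.noise_sd * float(np.exp(rng.normal(0.0, _NOISE_LOGSD)))
    noise = rng.normal(0.0, 1.0, size=signal.shape) * noise_scale

    site_rng = _rng(config.seed, "site_offsets")
    offsets = site_rng.normal(0.0, config.site_effect_sd, size=max(config.n_sites, 1))
    site_idx = int(str(row.get("site", "site1")).replace("site", "")) - 1
    data = BOLD_BASELINE + offsets[site_idx] + signal + noise

    motion_amp = float(np.exp(rng.normal(0.0, _MOTION_LOGSD)))
    motion, spikes = simulate_motion(
        rng, config.T, config.motion_spike_prob, motion_amp, spike_frames
    )
    ar = np.empty((config.T, 2))
    ar[0] = rng.normal(size=2)
    eps = rng.normal(0.0, np.sqrt(1 - 0.7**2), size=(config.T, 2))
    for t in range(1, config.T):
        ar[t] = 0.7 * ar[t - 1] + eps[t]
    confounds = pd.DataFrame(
        np.column_stack([motion, ar]),
        columns=list(conn.BASE_CONFOUND_COLUMNS),
    )
    confounds.attrs["spike_frames"] = spikes
    return conn.SubjectTimeSeries(
        subject_id=str(row["subject_id"]),
        data=data,
        tr=config.TR,
        confounds=confounds,
        labels=roiset.labels,
    )


def volume_geometry(
    roiset: RoiSet, voxel_size_mm: float = 3.0, margin_mm: float = 12.0
) -> tuple[tuple[int, int, int], np.ndarray]:
    """A voxel grid and affine that enclose all ROI spheres with margin."""
    lo = roiset.coords.min(axis=0) - roiset.radii.max() - margin_mm
    hi = roiset.coords.max(axis=0) + roiset.radii.max() + margin_mm
    shape = tuple(int(np.ceil(s)) for s in (hi - lo) / voxel_size_mm + 1)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = lo
    return shape, affine


def generate_volume(
    ts: conn.SubjectTimeSeries,
    roiset: RoiSet,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    background_noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Paint each ROI's series into its sphere of a 4D volume.

    Every voxel whose centre lies within the ROI radius receives that
    ROI's time series; background voxels are white noise.  Spheres must
    fit inside the field of view and must not overlap.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    affine = np.asarray(affine, dtype=float)
    coords = roiset.coords
    radii = roiset.radii
    for i in range(roiset.n):
        for j in range(i + 1, roiset.n):
            dist = np.linalg.norm(coords[i] - coords[j])
            if dist <= radii[i] + radii[j]:
                raise ValueError(
                    f"ROI spheres overlap: {roiset.labels[i]} / {roiset.labels[j]}"
                )

    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    mm = vox @ affine[:3, :3].T + affine[:3, 3]
    lo_mm, hi_mm = mm.min(axis=0), mm.max(axis=0)

    t = ts.n_frames
    vol = rng.normal(0.0, background_noise_sd, size=(nx * ny * nz, t)) \
        if background_noise_sd > 0 else np.zeros((nx * ny * nz, t))
    for k, (centre, radius, label) in enumerate(zip(coords, radii, roiset.labels)):
        if np.any(centre - radius < lo_mm) or np.any(centre + radius > hi_mm):
            raise ValueError(f"ROI sphere {label!r} outside the field of view")
        inside = np.einsum("ij,ij->i", mm - centre, mm - centre) <= radius**2
        if not inside.any():
            raise ValueError(f"ROI sphere {label!r} contains no voxels")
        vol[inside] = ts.data[:, k]
    return vol.reshape(nx, ny, nz, t)


def generate_iqm_table(
    pheno: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """30-column image-quality-metric table with a planted 4-factor structure.

    Metrics are linear combinations of four latent subject quality
    factors (loadings fixed by the seed) plus white noise scaled by
    ``config.noise_sd``.  Site effects shift the latent factor means
    (scaled by ``config.site_effect_sd``): between-site differences in
    image quality live in the same four dimensions the factors
    represent, so a 4-factor solution accounts for them and the metric
    table stays rank-4 in the noiseless limit.
    """
    if len(pheno) == 0:
        raise ValueError("phenotype table is empty")
    rng = _rng(config.seed, "iqm")
    n = len(pheno)
    loadings = rng.normal(size=(len(IQM_COLUMNS), 4))
    latent = rng.normal(size=(n, 4))
    noise = rng.normal(0.0, 1.0, size=(n, len(IQM_COLUMNS))) * config.noise_sd

    sites = sorted(pheno["site"].unique()) if "site" in pheno.columns else ["site1"]
    site_shift = {
        s: rng.normal(0.0, config.site_effect_sd, size=4) for s in sites
    }
    latent = latent + np.array(
        [site_shift[s] for s in pheno.get("site", pd.Series(["site1"] * n))]
    )
    values = latent @ loadings.T + noise
    table = pd.DataFrame(values, columns=list(IQM_COLUMNS))
    table.insert(0, "subject_id", pheno["subject_id"].to_numpy())
    return table


def write_volume_nifti(
    path: str | Path, volume: np.ndarray, affine: np.ndarray
) -> Path:
    """Save a painted 4D volume as NIfTI-1 (.nii or .nii.gz)."""
    import nibabel as nib

    path = Path(path)
    nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                    np.asarray(affine, dtype=float)).to_filename(str(path))
    return path


# ---------------------------------------------------------------------------
# effect-size calibration

def _between_strength_noise_sd(
    config: SimulationConfig, n_mc: int = 80
) -> float:
    """MC estimate of the subject-level SD of between-module strength
    with all planted slopes at zero (subjects at the mid age)."""
    roiset = RoiSet.default()
    partition = roiset.partition()
    base = replace(config, beta_age=0.0, beta_interaction=0.0,
                   n_per_group=max(config.n_per_group, n_mc))
    vals = np.empty(n_mc)
    for i in range(n_mc):
        row = {"subject_id": f"sub-{i:04d}", "group": "CMP",
               "age": base.age_mid, "site": "site1"}
        ts = generate_timeseries(row, roiset, base)
        cm = conn.subject_connectivity(ts)
        _, between = netm.module_strengths(cm.z, partition, cm.labels)
        vals[i] = between
    return float(vals.std(ddof=1))


def implied_interaction_beta(
    config: SimulationConfig, n_mc: int = 80
) -> float:
    """Standardized age × group regression coefficient implied by the config.

    Propagates the planted per-year between-subsystem slope through the
    Fisher transform (with white-noise attenuation of the observed
    correlation), sums over the 38 between-subsystem edges, and divides
    by the subject-level SD of between-module strength (effect variance
    analytic, residual SD estimated by simulation).  Group is taken as
    ±0.5-coded and age z-scored, matching the GLM convention.
    """
    lo, hi = config.age_range
    sd_age = (hi - lo) / np.sqrt(12.0)
    kappa = 1.0 / (1.0 + config.noise_sd**2)
    c_obs = kappa * config.between_module_r_base
    n_between = 38  # unordered pairs spanning two subsystems (default set)
    sens = n_between * kappa / (1.0 - c_obs**2)

    b_int = sens * config.beta_interaction * sd_age
    b_age = sens * (config.beta_age + config.beta_interaction / 2.0) * sd_age
    sd_noise = _between_strength_noise_sd(config, n_mc=n_mc)
    sd_y = np.sqrt(b_age**2 + 0.25 * b_int**2 + sd_noise**2)
    # the interaction regressor is z(age)·(±0.5); the reported coefficient
    # is per unit of that product, with the outcome z-scored
    return float(b_int / sd_y)


def calibrate_interaction(
    config: SimulationConfig, target_beta: float = 0.3, n_mc: int = 80
) -> SimulationConfig:
    """Solve for `beta_interaction` giving a target standardized β.

    Inverts the mapping used by `implied_interaction_beta` (fixed-point
    iteration on the outcome SD, which itself depends on the slope).
    Negative targets plant a faster decline in the ASC group.
    """
    lo, hi = config.age_range
    sd_age = (hi - lo) / np.sqrt(12.0)
    kappa = 1.0 / (1.0 + config.noise_sd**2)
    c_obs = kappa * config.between_module_r_base
    sens = 38 * kappa / (1.0 - c_obs**2)
    sd_noise = _between_strength_noise_sd(config, n_mc=n_mc)

    beta_i = config.beta_interaction if config.beta_interaction != 0 else -1e-3
    for _ in range(50):
        b_int = sens * beta_i * sd_age
        b_age = sens * (config.beta_age + beta_i / 2.0) * sd_age
        sd_y = np.sqrt(b_age**2 + 0.25 * b_int**2 + sd_noise**2)
        new = target_beta * sd_y / (sens * sd_age)
        if abs(new - beta_i) < 1e-12:
            beta_i = new
            break
        beta_i = new
    return replace(config, beta_interaction=float(beta_i))


# ---------------------------------------------------------------------------
# cohort convenience + disk output

def generate_cohort(
    config: SimulationConfig, roiset: RoiSet | None = None
) -> tuple[pd.DataFrame, list[conn.SubjectTimeSeries], pd.DataFrame]:
    """Phenotypes, per-subject time series and IQM table in one call."""
    roiset = roiset or RoiSet.default()
    pheno = generate_phenotypes(config)
    ts = [generate_timeseries(row, roiset, config) for _, row in pheno.iterrows()]
    iqm = generate_iqm_table(pheno, config)
    return pheno, ts, iqm


def write_cohort(
    out_dir: str | Path,
    config: SimulationConfig,
    roiset: RoiSet | None = None,
) -> Path:
    """Write phenotype CSV, IQM CSV, ROI TSV and per-subject TSV pairs."""
    roiset = roiset or RoiSet.default()
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    pheno, ts_list, iqm = generate_cohort(config, roiset)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    iqm.to_csv(out / "iqm.csv", index=False)
    roiset.to_tsv(out / "rois.tsv")
    for ts in ts_list:
        pd.DataFrame(ts.data, columns=ts.labels).to_csv(
            out / "timeseries" / f"{ts.subject_id}_timeseries.tsv",
            sep="\t", index=False,
        )
        ts.confounds.to_csv(
            out / "timeseries" / f"{ts.subject_id}_confounds.tsv",
            sep="\t", index=False,
        )
    return out
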