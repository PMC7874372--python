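"""End-to-end pipeline: simulate → connectivity → metrics → qc → analyze → report.

Each stage reads and writes plain-text tables under a single output
directory, so stages can be re-run individually and a full run is
reproducible byte-for-byte from its configuration.  Every stage writes a
JSON metadata sidecar recording its parameters, seeds and input hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .rois import RoiSet
from . import synthetic_data as synth
from . import connectivity as conn
from . import network_metrics as netm
from . import quality_control as qc_mod
from . import inference as inf

log = logging.getLogger(__name__)

STAGES = ("simulate", "connectivity", "metrics", "qc", "analyze", "report")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "dmn_run"
    stages: tuple[str, ...] = STAGES
    # simulation
    n_per_group: int = 30
    age_range: tuple[float, float] = (6.0, 18.0)
    T: int = 150
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
    # connectivity
    band: tuple[float, float] = conn.DEFAULT_BAND_HZ
    # metrics
    modularity_mode: str = "signed_asymmetric"
    # qc
    fd_max: float = qc_mod.FD_MAX_MM
    dvars_max: float = qc_mod.DVARS_MAX_PCT
    iq_low: float = qc_mod.IQ_LOW
    iq_high: float = qc_mod.IQ_HIGH
    # inference
    n_boot: int = 200
    include_quality_nuisance: bool = True
    run_edgewise: bool = True
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if not set(self.stages) <= set(STAGES):
            problems.append(f"unknown stages: {sorted(set(self.stages) - set(STAGES))}")
        if self.n_per_group < 2:
            problems.append("n_per_group must be >= 2")
        if self.T < 50:
            problems.append("T must be >= 50")
        if self.n_boot < 100:
            problems.append("n_boot must be >= 100")
        lo, hi = self.band
        if not 0 < lo < hi:
            problems.append(f"invalid band {self.band}")
        if hi >= 1.0 / (2.0 * self.TR):
            problems.append("band high must be below Nyquist")
        if self.modularity_mode not in netm.MODULARITY_MODES:
            problems.append(f"unknown modularity mode {self.modularity_mode!r}")
        if self.age_range[0] >= self.age_range[1]:
            problems.append(f"invalid age_range {self.age_range}")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))

    def sim_config(self) -> synth.SimulationConfig:
        return synth.SimulationConfig(
            n_per_group=self.n_per_group,
            age_range=tuple(self.age_range),
            T=self.T,
            TR=self.TR,
            within_module_r=self.within_module_r,
            between_module_r_base=self.between_module_r_base,
            beta_age=self.beta_age,
            beta_interaction=self.beta_interaction,
            noise_sd=self.noise_sd,
            n_sites=self.n_sites,
            site_effect_sd=self.site_effect_sd,
            motion_spike_prob=self.motion_spike_prob,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        for key in ("stages", "age_range", "band"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs, **({"extras": extras} if extras else {}))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["stages"] = list(self.stages)
        raw["age_range"] = list(self.age_range)
        raw["band"] = list(self.band)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_meta(stage_dir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    meta = {
        "stage": stage,
        "version": __version__,
        "parameters": params,
        "input_hashes": {p.name: _hash_file(p) for p in inputs if p.exists()},
    }
    (stage_dir / f"{stage}.meta.json").write_text(json.dumps(meta, indent=2, default=str))


def _load_subjects(out: Path, config: RunConfig) -> list[conn.SubjectTimeSeries]:
    ts_dir = out / "simulate" / "timeseries"
    pheno = pd.read_csv(out / "simulate" / "phenotypes.csv")
    subjects = []
    for sid in pheno["subject_id"]:
        subjects.append(
            conn.load_roi_timeseries_tsv(
                ts_dir / f"{sid}_timeseries.tsv",
                tr=config.TR,
                confounds_path=ts_dir / f"{sid}_confounds.tsv",
                subject_id=sid,
            )
        )
    return subjects


def stage_simulate(out: Path, config: RunConfig) -> None:
    sim_dir = out / "simulate"
    synth.write_cohort(sim_dir, config.sim_config())
    _write_meta(sim_dir, "simulate", asdict(config.sim_config()), [])


def stage_connectivity(out: Path, config: RunConfig) -> None:
    conn_dir = out / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    edges = []
    for ts in _load_subjects(out, config):
        cm = conn.subject_connectivity(ts, band=tuple(config.band))
        cm.to_frame().to_csv(conn_dir / f"{ts.subject_id}_connectivity.csv")
        e = cm.edge_table()
        e.insert(0, "subject_id", ts.subject_id)
        edges.append(e)
    pd.concat(edges, ignore_index=True).to_csv(conn_dir / "edges.csv", index=False)
    _write_meta(conn_dir, "connectivity",
                {"band": list(config.band), "TR": config.TR},
                [out / "simulate" / "phenotypes.csv"])


def _load_connectivity(out: Path) -> list[conn.ConnectivityMatrix]:
    pheno = pd.read_csv(out / "simulate" / "phenotypes.csv")
    mats = []
    for sid in pheno["subject_id"]:
        frame = pd.read_csv(out / "connectivity" / f"{sid}_connectivity.csv", index_col=0)
        mats.append(conn.ConnectivityMatrix(sid, frame.to_numpy(), list(frame.columns)))
    return mats


def stage_metrics(out: Path, config: RunConfig) -> None:
    met_dir = out / "metrics"
    met_dir.mkdir(parents=True, exist_ok=True)
    roiset = RoiSet.from_tsv(out / "simulate" / "rois.tsv")
    partition = roiset.partition()
    summaries = [
        netm.summarize_network(cm.subject_id, cm.z, partition, cm.labels,
                               mode=config.modularity_mode)
        for cm in _load_connectivity(out)
    ]
    netm.summaries_table(summaries).to_csv(met_dir / "summaries.csv", index=False)
    _write_meta(met_dir, "metrics", {"mode": config.modularity_mode},
                [out / "simulate" / "rois.tsv"])


def stage_qc(out: Path, config: RunConfig) -> None:
    qc_dir = out / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    pheno = pd.read_csv(out / "simulate" / "phenotypes.csv")
    subjects = _load_subjects(out, config)
    series = [qc_mod.qc_from_subject(s.subject_id, s.confounds, s.data)
              for s in subjects]
    qc_tab = qc_mod.qc_summary_table(series)
    qc_tab.to_csv(qc_dir / "qc_summary.csv", index=False)

    retained, excl = qc_mod.apply_exclusions(
        pheno, qc_tab, fd_max=config.fd_max, dvars_max=config.dvars_max,
        iq_low=config.iq_low, iq_high=config.iq_high,
    )
    retained.to_csv(qc_dir / "retained_phenotypes.csv", index=False)
    excl.to_csv(qc_dir / "exclusions.csv", index=False)
    qc_mod.movement_outliers(qc_tab).to_csv(qc_dir / "movement_outliers.csv", index=False)

    iqm = pd.read_csv(out / "simulate" / "iqm.csv")
    factors, explained = qc_mod.iqm_pca(iqm)
    factors.to_csv(qc_dir / "quality_factors.csv", index=False)

    leakage = {}
    if pheno["site"].nunique() >= 2 and pheno.groupby("site").size().min() >= 6:
        edges = pd.read_csv(out / "connectivity" / "edges.csv")
        wide = edges.pivot_table(index="subject_id", columns=["roi_i", "roi_j"],
                                 values="z", sort=False)
        wide = wide.loc[pheno["subject_id"]]
        site = pheno.set_index("subject_id").loc[wide.index, "site"]
        fac = factors.set_index("subject_id").loc[wide.index]
        for mode in ("raw", "quality_regressed", "site_regressed"):
            leakage[mode] = qc_mod.site_leakage_check(
                wide.to_numpy(), site.to_numpy(), mode=mode,
                seed=config.seed, quality=fac.to_numpy(),
            )
        leakage["chance"] = 1.0 / pheno["site"].nunique()
    report = {
        "explained_variance": [float(v) for v in explained],
        "leakage_balanced_accuracy": leakage,
        "descriptives": qc_mod.sample_descriptives(pheno, qc_tab),
    }
    (qc_dir / "leakage_report.json").write_text(json.dumps(report, indent=2, default=str))
    _write_meta(qc_dir, "qc",
                {"fd_max": config.fd_max, "dvars_max": config.dvars_max,
                 "iq_low": config.iq_low, "iq_high": config.iq_high},
                [out / "simulate" / "phenotypes.csv", out / "simulate" / "iqm.csv"])


def stage_analyze(out: Path, config: RunConfig) -> None:
    ana_dir = out / "analyze"
    ana_dir.mkdir(parents=True, exist_ok=True)
    pheno = pd.read_csv(out / "qc" / "retained_phenotypes.csv")
    summaries = pd.read_csv(out / "metrics" / "summaries.csv")
    summaries = summaries[summaries["subject_id"].isin(set(pheno["subject_id"]))]
    factors = pd.read_csv(out / "qc" / "quality_factors.csv")
    factors = factors[factors["subject_id"].isin(set(pheno["subject_id"]))]
    qc_tab = pd.read_csv(out / "qc" / "qc_summary.csv")
    qc_tab = qc_tab[qc_tab["subject_id"].isin(set(pheno["subject_id"]))]

    nuisance = ("fiq", "f1", "f2", "f3", "f4") if config.include_quality_nuisance \
        else ("fiq",)
    spec = inf.GlmSpec(nuisance=nuisance, n_boot=config.n_boot, seed=config.seed)

    quality = factors if config.include_quality_nuisance else None
    module_stats = inf.module_level_analysis(summaries, pheno, quality, spec)
    module_stats_noout = inf.module_level_analysis(
        summaries, pheno, quality, spec, exclude_outliers=True, qc=qc_tab
    )
    pd.concat([module_stats, module_stats_noout], ignore_index=True).to_csv(
        ana_dir / "module_stats.csv", index=False
    )

    if config.run_edgewise:
        mats = [m for m in _load_connectivity(out)
                if m.subject_id in set(pheno["subject_id"])]
        roiset = RoiSet.from_tsv(out / "simulate" / "rois.tsv")
        edge_stats = inf.edgewise_analysis(mats, pheno, quality, spec,
                                           partition=roiset.partition())
        edge_stats.to_csv(ana_dir / "edge_stats.csv", index=False)

    symptom_rows = []
    for score_col in ("srs_z", "ados_z"):
        scored = pheno.dropna(subset=[score_col])
        if len(scored) >= 10:
            scores = pheno.set_index("subject_id")[score_col]
            res = inf.symptom_association(
                scores, summaries, pheno, quality, spec
            )
            res.insert(0, "score", score_col)
            symptom_rows.append(res)
    if symptom_rows:
        pd.concat(symptom_rows, ignore_index=True).to_csv(
            ana_dir / "symptom_stats.csv", index=False
        )

    (ana_dir / "analysis_metadata.json").write_text(json.dumps({
        "version": __version__,
        "n_boot": config.n_boot,
        "seed": config.seed,
        "group_coding": {"CMP": -0.5, "ASC": 0.5},
        "null_scheme": spec.null_scheme,
        "fdr_family": "per coefficient across edges",
        "bonferroni_family": list(inf.STRENGTH_OUTCOMES),
        "nuisance": list(nuisance),
    }, indent=2))
    _write_meta(ana_dir, "analyze", {"n_boot": config.n_boot, "seed": config.seed},
                [out / "metrics" / "summaries.csv"])


def average_adjacency(
    mats: list[conn.ConnectivityMatrix], band_of: pd.Series
) -> dict[str, np.ndarray]:
    """Mean adjacency matrix per band label (band_of indexed by subject)."""
    out: dict[str, list[np.ndarray]] = {}
    for m in mats:
        band = band_of.get(m.subject_id)
        if band is None or (isinstance(band, float) and np.isnan(band)):
            continue
        out.setdefault(str(band), []).append(m.z)
    return {b: np.mean(stack, axis=0) for b, stack in out.items()}


def make_report(out: Path | str, config: RunConfig | None = None) -> Path:
    """Render average adjacency panels, effect matrices and scatter plots.

    Expects `analyze` (and upstream) outputs under `out`.  Missing
    inputs raise an error listing them.  Returns the report directory.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    needed = [out / "qc" / "retained_phenotypes.csv",
              out / "metrics" / "summaries.csv",
              out / "analyze" / "module_stats.csv"]
    missing = [str(p) for p in needed if not p.exists()]
    if missing:
        raise FileNotFoundError(f"make_report missing inputs: {missing}")

    rep_dir = out / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    pheno = pd.read_csv(out / "qc" / "retained_phenotypes.csv")
    summaries = pd.read_csv(out / "metrics" / "summaries.csv")
    mats = [m for m in _load_connectivity(out)
            if m.subject_id in set(pheno["subject_id"])]
    roiset = RoiSet.from_tsv(out / "simulate" / "rois.tsv")

    bands = inf.median_split(pheno)
    key = pheno["group"].astype(str) + "/" + bands.astype(str)
    band_of = pd.Series(key.to_numpy(), index=pheno["subject_id"].to_numpy())
    averages = average_adjacency(mats, band_of)

    labels = mats[0].labels
    # order nodes by subsystem for block-structured display
    part = roiset.partition()
    order = np.argsort(part.indices(labels), kind="stable")
    notes = []
    panel_keys = [f"{g}/{b}" for g in ("ASC", "CMP")
                  for b in ("younger", "older")]
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, k in zip(axes.ravel(), panel_keys):
        if k not in averages:
            ax.set_axis_off()
            ax.set_title(f"{k}: no subjects")
            notes.append(f"panel {k} omitted: no subjects in band")
            continue
        m = averages[k][np.ix_(order, order)]
        im = ax.imshow(m, cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_title(f"{k} (n={int((band_of == k).sum())})")
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels([labels[i] for i in order], rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels([labels[i] for i in order], fontsize=6)
        ci = part.indices(labels)[order]
        edges_at = np.flatnonzero(np.diff(ci)) + 0.5
        for e in edges_at:
            ax.axhline(e - 0.0, color="white", lw=1.5)
            ax.axvline(e - 0.0, color="white", lw=1.5)
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(rep_dir / "average_adjacency.png", dpi=120)
    plt.close(fig)

    # age-strength regressions per group
    tab = pheno.merge(summaries, on="subject_id")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, outcome in zip(axes, ("between", "Q")):
        for g, color in (("ASC", "tab:red"), ("CMP", "tab:gray")):
            sub = tab[tab["group"] == g]
            ax.scatter(sub["age"], sub[outcome], s=8, color=color, alpha=0.6, label=g)
            if len(sub) > 2:
                b = np.polyfit(sub["age"], sub[outcome], 1)
                xs = np.linspace(sub["age"].min(), sub["age"].max(), 20)
                ax.plot(xs, np.polyval(b, xs), color=color)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(outcome)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(rep_dir / "age_regressions.png", dpi=120)
    plt.close(fig)

    edge_stats_path = out / "analyze" / "edge_stats.csv"
    if edge_stats_path.exists():
        edge_stats = pd.read_csv(edge_stats_path)
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, coef in zip(axes, ("age", "age_x_group")):
            sub = edge_stats[edge_stats["coef"] == coef]
            mat = np.zeros((len(labels), len(labels)))
            idx = {l: i for i, l in enumerate(labels)}
            for _, r in sub.iterrows():
                i, j = idx[r["roi_i"]], idx[r["roi_j"]]
                mat[i, j] = mat[j, i] = r["beta_median"]
            m = mat[np.ix_(order, order)]
            im = ax.imshow(m, cmap="RdBu_r", vmin=-0.8, vmax=0.8)
            ax.set_title(f"standardized beta: {coef}")
            fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
        fig.savefig(rep_dir / "edge_effects.png", dpi=120)
        plt.close(fig)

    module_stats = pd.read_csv(out / "analyze" / "module_stats.csv")
    lines = ["# DMN subsystem run report", ""]
    lines += [f"- {n}" for n in notes]
    lines += ["", "## Module-level statistics", "",
              module_stats.to_string(index=False), ""]
    (rep_dir / "report.md").write_text("\n".join(lines))
    return rep_dir


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "connectivity": stage_connectivity,
    "metrics": stage_metrics,
    "qc": stage_qc,
    "analyze": stage_analyze,
}

_STAGE_INPUTS = {
    "simulate": [],
    "connectivity": ["simulate/phenotypes.csv"],
    "metrics": ["connectivity/edges.csv", "simulate/rois.tsv"],
    "qc": ["simulate/phenotypes.csv", "simulate/iqm.csv", "connectivity/edges.csv"],
    "analyze": ["metrics/summaries.csv", "qc/retained_phenotypes.csv",
                "qc/quality_factors.csv"],
    "report": ["analyze/module_stats.csv", "metrics/summaries.csv",
               "qc/retained_phenotypes.csv"],
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Stage inputs are validated up front: a requested stage whose inputs
    are neither produced by an earlier requested stage nor already on
    disk fails before anything runs.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    ordered = [s for s in STAGES if s in config.stages]
    produced = set()
    problems = []
    for stage in ordered:
        for rel in _STAGE_INPUTS[stage]:
            producer = rel.split("/")[0]
            if producer in produced:
                continue
            if not (out / rel).exists():
                problems.append(f"stage {stage!r} needs missing input {rel}")
        produced.add(stage)
    if problems:
        logging.getLogger().removeHandler(fh)
        raise ValueError("; ".join(problems))

    config.to_yaml(out / "run_config.yaml")
    report: dict = {"stages_run": [], "out_dir": str(out)}
    try:
        for stage in ordered:
            log.info("running stage %s", stage)
            try:
                if stage == "report":
                    make_report(out, config)
                else:
                    _STAGE_FUNCS[stage](out, config)
            except Exception as err:
                raise RuntimeError(f"stage {stage!r} failed: {err}") from err
            report["stages_run"].append(stage)
    finally:
        logging.getLogger().removeHandler(fh)
    return report
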