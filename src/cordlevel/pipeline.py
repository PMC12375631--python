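"""End-to-end orchestration: simulate -> fit -> profile -> stats -> report.

A single YAML-backed :class:`RunConfig` (schema-validated, unknown keys
rejected) drives all stages. Each stage records SHA-256 checksums of its
outputs in ``manifest.json``; re-running an identical configuration skips
stages whose recorded outputs are intact, so a deleted stats table is
recomputed from the existing profiles without re-simulating. All randomness
lives in the simulation stage and is fanned out from the master seed by
spawning one child seed sequence per subject (and per sub-stage within a
subject), so results do not depend on processing order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import core_io, dti, levels as levels_mod, phantom, stats as stats_mod
from .core_io import read_gradient_table, write_gradient_table, write_volume

log = logging.getLogger("cordlevel")

PROFILE_COLUMNS = ["subject_id", "region", "sublevel", "metric", "value", "n_voxels"]


class EffectModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tissue: str
    metric: str
    delta: float
    band: tuple[float, float] | None = None


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_hc: int = 46
    n_ms: int = 54
    grid_dims: tuple[int, int, int] = (24, 24, 40)
    voxel_size_mm: float = 0.5
    effects: list[EffectModel] = Field(
        default_factory=lambda: [EffectModel(tissue="WM", metric="FA", delta=-0.02),
                                 EffectModel(tissue="GM", metric="FA", delta=-0.04)])
    between_subject_sd: dict[str, float] = Field(
        default_factory=lambda: {"FA": 0.025, "MD": 3e-5})
    lesion_count_range: tuple[int, int] = (1, 4)
    lesion_radius_range_mm: tuple[float, float] = (1.0, 3.0)


class AcquisitionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_directions: int = 15
    b_value: float = 750.0
    n_b0: int = 1
    n_averages: int = 3
    s0: float = 1000.0
    snr: float | None = 20.0


class LevelsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_voxels: int = 1


class StatsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha_group: float = 0.05
    alpha_level: float = 0.01
    alpha_fdr: float = 0.05


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML sections mirror these)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    output_dir: str = "cordlevel_run"
    cohort: CohortSection = Field(default_factory=CohortSection)
    acquisition: AcquisitionSection = Field(default_factory=AcquisitionSection)
    levels: LevelsSection = Field(default_factory=LevelsSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def phantom_config(self) -> phantom.CohortConfig:
        c = self.cohort
        return phantom.CohortConfig(
            n_hc=c.n_hc, n_ms=c.n_ms, grid_dims=tuple(c.grid_dims),
            voxel_size_mm=c.voxel_size_mm,
            effects=tuple(phantom.EffectSpec(e.tissue, e.metric, e.delta,
                                             tuple(e.band) if e.band else None)
                          for e in c.effects),
            between_subject_sd=dict(c.between_subject_sd),
            lesion_count_range=tuple(c.lesion_count_range),
            lesion_radius_range_mm=tuple(c.lesion_radius_range_mm),
            seed=self.seed)

    def acquisition_spec(self) -> phantom.AcquisitionSpec:
        a = self.acquisition
        return phantom.AcquisitionSpec(
            n_directions=a.n_directions, b_value=a.b_value, n_b0=a.n_b0,
            n_averages=a.n_averages, s0=a.s0, snr=a.snr)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage output checksums keyed by the configuration hash."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.path = out_dir / "manifest.json"
        self.config_hash = config_hash
        self.data: dict = {"config_hash": config_hash, "stages": {}}
        if self.path.exists():
            try:
                stored = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                stored = {}
            if stored.get("config_hash") == config_hash:
                self.data = stored

    def stage_complete(self, stage: str) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        base = self.path.parent
        for rel, digest in entry["outputs"].items():
            f = base / rel
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def record(self, stage: str, outputs: list[Path], seconds: float,
               warnings: list[str] | None = None) -> None:
        base = self.path.parent
        self.data["stages"][stage] = {
            "outputs": {str(p.relative_to(base)): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
            "warnings": warnings or [],
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _subject_dir(out: Path, sid: str) -> Path:
    return out / "subjects" / sid


def run_cohort_in_memory(config: phantom.CohortConfig,
                         acq: phantom.AcquisitionSpec | None = None,
                         fit: bool = True, min_voxels: int = 1,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate, fit and profile a cohort subject-by-subject without disk I/O.

    Streams one subject at a time (volumes are discarded after profiling),
    so memory stays flat for large cohorts. Returns (profiles, records,
    truth_profiles). With ``fit=False`` the DWI/tensor-fit stages are
    skipped and ``profiles`` contains only mask-derived metrics (CSA,
    lesion load) plus the ground-truth diffusion entries in
    ``truth_profiles``.
    """
    acq = acq or phantom.AcquisitionSpec()
    plan = phantom.plan_cohort(config)
    profile_frames, truth_frames, band_means = [], [], []
    for i in range(len(plan)):
        s = phantom.build_subject(config, acq, plan.ids[i], plan.groups[i],
                                  plan.subject_seeds[i], float(plan.ages[i]),
                                  str(plan.sexes[i]), with_dwi=fit)
        band_means.append(phantom._truth_band_mean(
            s.truth_profile, "GM", "CSA", config.clinical.band))
        truth_frames.append(s.truth_profile)
        sub = levels_mod.discretize_levels(s.levels)
        if fit:
            field = dti.fit_tensor(s.dwi, s.regions.cord)
            scalars = dti.tensor_scalars(field)
        else:
            scalars = None
        profile_frames.append(levels_mod.build_profiles(
            plan.ids[i], scalars, s.regions, sub, min_voxels=min_voxels))
    records = phantom.clinical_records(config, plan, np.asarray(band_means))
    return (pd.concat(profile_frames, ignore_index=True), records,
            pd.concat(truth_frames, ignore_index=True))


def stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    cfg = config.phantom_config()
    acq = config.acquisition_spec()
    subjects, records = phantom.generate_cohort(cfg, acq, with_dwi=True)
    outputs = []
    for s in subjects:
        d = _subject_dir(out, s.record.id)
        d.mkdir(parents=True, exist_ok=True)
        write_volume(s.dwi, d / "dwi.nii.gz")
        write_gradient_table(s.dwi.gradients, d / "bvals", d / "bvecs")
        for name, vol in s.regions.items():
            write_volume(vol, d / f"mask_{name}.nii.gz")
        write_volume(s.levels, d / "levels.nii.gz")
        write_volume(s.truth_tensors.components, d / "truth_tensors.nii.gz",
                     grid=s.grid)
        s.truth_profile.to_csv(d / "truth_profile.csv", index=False)
        outputs += [d / "dwi.nii.gz", d / "truth_profile.csv"]
    records.to_csv(out / "subjects.csv", index=False)
    outputs.append(out / "subjects.csv")
    return outputs


def stage_fit(config: RunConfig, out: Path) -> list[Path]:
    records = core_io.read_subject_table(out / "subjects.csv")
    outputs = []
    for sid in records["id"]:
        d = _subject_dir(out, sid)
        gt = read_gradient_table(d / "bvals", d / "bvecs")
        cord = core_io.read_volume(d / "mask_cord.nii.gz", kind="binary")
        dwi = core_io.read_volume(d / "dwi.nii.gz", expected_grid=cord.grid,
                                  gradients=gt)
        field = dti.fit_tensor(dwi, cord)
        scalars = dti.tensor_scalars(field)
        for metric, arr in (("fa", scalars.fa), ("md", scalars.md),
                            ("ad", scalars.ad), ("rd", scalars.rd)):
            write_volume(np.nan_to_num(arr), d / f"{metric}.nii.gz",
                         grid=field.grid)
        write_volume(field.components, d / "tensors.nii.gz", grid=field.grid)
        write_volume(core_io.LabelVolume(field.grid,
                                         scalars.valid.astype(np.uint8)),
                     d / "fit_valid.nii.gz")
        report = {"n_clamped": field.n_clamped,
                  "n_excluded": int(field.excluded.sum()),
                  "n_fitted": int(field.mask.sum())}
        (d / "fit_report.json").write_text(json.dumps(report, sort_keys=True))
        outputs += [d / "fa.nii.gz", d / "fit_report.json"]
    return outputs


def stage_profile(config: RunConfig, out: Path) -> list[Path]:
    records = core_io.read_subject_table(out / "subjects.csv")
    frames = []
    for sid in records["id"]:
        d = _subject_dir(out, sid)
        grid = core_io.read_volume(d / "mask_cord.nii.gz", kind="binary").grid
        names = {"cord": "cord", "WM": "WM", "GM": "GM"}
        masks = {}
        for name in ("cord", "WM", "GM", *core_io.PATHWAY_NAMES,
                     *core_io.SUBREGION_NAMES):
            masks[name] = core_io.read_volume(d / f"mask_{name}.nii.gz",
                                              expected_grid=grid, kind="binary")
        lesion_path = d / "mask_lesion.nii.gz"
        lesion = (core_io.read_volume(lesion_path, expected_grid=grid,
                                      kind="binary")
                  if lesion_path.exists() else None)
        regions = core_io.RegionSet(
            grid, masks["cord"], masks["WM"], masks["GM"],
            {n: masks[n] for n in core_io.PATHWAY_NAMES},
            {n: masks[n] for n in core_io.SUBREGION_NAMES}, lesion=lesion)
        level_map = core_io.read_volume(d / "levels.nii.gz",
                                        expected_grid=grid, kind="level")
        sub = levels_mod.discretize_levels(level_map)
        valid = core_io.read_volume(d / "fit_valid.nii.gz",
                                    expected_grid=grid, kind="binary")
        maps = {}
        for metric in ("fa", "md", "ad", "rd"):
            maps[metric] = np.asarray(
                core_io.read_volume(d / f"{metric}.nii.gz",
                                    expected_grid=grid, kind="probability"
                                    if metric == "fa" else "auto").data,
                dtype=float)
        scalars = dti.ScalarMapSet(grid, maps["fa"], maps["md"], maps["ad"],
                                   maps["rd"], valid=valid.data.astype(bool))
        frames.append(levels_mod.build_profiles(
            sid, scalars, regions, sub, min_voxels=config.levels.min_voxels))
    profiles = pd.concat(frames, ignore_index=True)
    profiles.to_csv(out / "profiles.csv", index=False)
    return [out / "profiles.csv"]


def stage_stats(config: RunConfig, out: Path) -> list[Path]:
    profiles = pd.read_csv(out / "profiles.csv")
    records = core_io.read_subject_table(out / "subjects.csv")
    s = config.stats
    outputs = []
    tables = {
        "demographics.csv": stats_mod.demographics_table(records),
        "group_stats.csv": stats_mod.group_comparison_table(
            profiles, records, alpha=s.alpha_group),
        "effect_sizes.csv": stats_mod.effect_size_table(
            profiles, records, alpha=s.alpha_level),
        "level_contrasts.csv": stats_mod.level_contrast_table(
            profiles, records, alpha=s.alpha_level),
        "associations.csv": stats_mod.association_scan(
            profiles, records, alpha_fdr=s.alpha_fdr),
        "group_curves.csv": stats_mod.group_level_curves(profiles, records),
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.10g")
        outputs.append(out / name)
    return outputs


def stage_report(config: RunConfig, out: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = pd.read_csv(out / "group_curves.csv")
    effects = pd.read_csv(out / "effect_sizes.csv")
    outputs = []

    sel = curves[(curves.region == "cord")]
    metrics = [m for m in ("CSA", "FA", "MD", "AD", "RD")
               if m in set(sel.metric)]
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3),
                             squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        for group, color in (("HC", "tab:blue"), ("pwRRMS", "tab:red")):
            g = sel[(sel.metric == metric) & (sel.group == group)]
            xs = np.arange(len(g))
            ax.plot(xs, g["mean"], color=color, label=group)
            ax.fill_between(xs, g["mean"] - g.ci95, g["mean"] + g.ci95,
                            color=color, alpha=0.25)
            ax.set_xticks(xs[::5], g.sublevel.iloc[::5], rotation=45)
        ax.set_title(f"whole cord {metric}")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(out / "curves_whole_cord.png", dpi=110)
    plt.close(fig)
    outputs.append(out / "curves_whole_cord.png")

    sub = effects[effects.sublevel != "mean"]
    for scale, regs in (("pathways", core_io.PATHWAY_NAMES),
                        ("subregions", core_io.SUBREGION_NAMES)):
        mat_regions = [r for r in regs if r in set(sub.region)]
        if not mat_regions:
            continue
        metrics_here = sorted(set(sub.metric) - {"lesion_load"})
        fig, axes = plt.subplots(1, len(metrics_here),
                                 figsize=(4 * len(metrics_here), 3),
                                 squeeze=False)
        for ax, metric in zip(axes[0], metrics_here):
            mat = np.full((len(mat_regions), levels_mod.N_SUBLEVELS), np.nan)
            for i, r in enumerate(mat_regions):
                rows = sub[(sub.region == r) & (sub.metric == metric)]
                for _, row in rows.iterrows():
                    mat[i, levels_mod.SUBLEVELS.index(row.sublevel)] = row.d
            disp = stats_mod.normalize_for_display(mat)
            im = ax.imshow(disp, cmap="RdBu", vmin=-1, vmax=1, aspect="auto")
            ax.set_yticks(range(len(mat_regions)), mat_regions)
            ax.set_title(f"{scale} {metric} (Cohen's d, display-normalized)")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out / f"effect_sizes_{scale}.png", dpi=110)
        plt.close(fig)
        outputs.append(out / f"effect_sizes_{scale}.png")

    summary = summarize_run(out)
    (out / "summary.txt").write_text(summary)
    outputs.append(out / "summary.txt")
    return outputs


STAGES = [
    ("simulate", stage_simulate),
    ("fit", stage_fit),
    ("profile", stage_profile),
    ("stats", stage_stats),
    ("report", stage_report),
]


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Manifest:
    """Run (or resume) the pipeline; returns the updated manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, config.config_hash())
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True))
    for name, fn in STAGES:
        if stages is not None and name not in stages:
            continue
        if manifest.stage_complete(name):
            log.info("stage %s: outputs intact, skipping", name)
            continue
        log.info("stage %s: running", name)
        t0 = time.time()
        try:
            outputs = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        manifest.record(name, outputs, time.time() - t0)
    return manifest


def summarize_run(out_dir: str | Path) -> str:
    """Human-readable counts of significant cells at the three spatial
    scales (whole cord; WM/GM; pathways and subregions)."""
    out = Path(out_dir)
    for required in ("group_stats.csv", "level_contrasts.csv"):
        if not (out / required).exists():
            raise FileNotFoundError(f"missing results file: {out / required}")
    group = pd.read_csv(out / "group_stats.csv")
    contrasts = pd.read_csv(out / "level_contrasts.csv")
    assoc_path = out / "associations.csv"
    lines = ["cordlevel run summary", "====================="]
    scales = {
        "whole cord": ["cord"],
        "WM/GM": ["WM", "GM"],
        "pathways": list(core_io.PATHWAY_NAMES),
        "subregions": list(core_io.SUBREGION_NAMES),
    }
    for scale, regs in scales.items():
        g = group[group.region.isin(regs) & group.significant]
        lines.append(f"[{scale}] significant region means (Welch): "
                     + (", ".join(f"{r.region} {r.metric}"
                                  for r in g.itertuples()) or "none"))
        c = contrasts[contrasts.region.isin(regs) & contrasts.significant]
        if len(c):
            per = c.groupby(["region", "metric"]).size()
            lines.append(f"[{scale}] per-level contrasts: " + ", ".join(
                f"{r}/{m}: {n} sub-levels" for (r, m), n in per.items()))
        else:
            lines.append(f"[{scale}] per-level contrasts: none significant")
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path)
        sig = assoc[assoc.significant]
        lines.append("associations surviving FDR: " + (", ".join(
            f"{r.clinical}~{r.region}/{r.metric}@{r.sublevel} (B1={r.b1:.2f})"
            for r in sig.itertuples()) or "none"))
    return "\n".join(lines) + "\n"
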