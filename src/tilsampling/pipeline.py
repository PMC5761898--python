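"""End-to-end orchestration: config, per-stage seeds, and the full pipeline.

One master seed is expanded into independent per-stage seeds via
``numpy.random.SeedSequence([master_seed, crc32(stage_name)])`` so that any
stage can be rerun in isolation and still reproduce the full run.  A
pipeline run with the same config produces byte-identical output tables.

The demo pipeline realises the whole workflow on a synthetic cohort:
section tables -> variance components -> section resampling -> spatial
slides -> core grids -> core subsampling -> ROC.  Slide-level target
percents are the patients' simulated section values, so the spatial stage
inherits the cohort's between- and within-patient structure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cores import CoreGridConfig, cores_to_frame, generate_core_grid, score_cores
from .resample import (
    DEFAULT_CUTOFFS,
    block_pool,
    roc_over_cutoffs,
    roc_to_frame,
    subsample_cores,
)
from .sections import SCHEMES, patient_truth_and_cutoff, resample_section_classification
from .synthetic import (
    GroupSpec,
    SlideSpec,
    default_groups,
    generate_section_measurements,
    generate_slide,
    rectangle_roi,
)
from .variance import fixed_effects_anova, random_intercept_icc

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    seed: int = 0
    output_dir: str = "tilsampling-run"
    # cohort
    groups: list[GroupSpec] = field(default_factory=default_groups)
    # spatial slides
    slides_per_block: int = 2
    roi_width_mm: tuple[float, float] = (9.0, 12.0)  # sampled U(lo, hi) per slide
    cell_density_per_mm2: float = 600.0
    margin_enriched_fraction: float = 0.2
    margin_width_um: float = 200.0
    margin_enrichment: float = 3.0
    # stages
    section_ks: tuple[int, ...] = (1, 2)
    core_ks: tuple[int, ...] = (1, 2, 3, 4, 5)
    summary_stats: tuple[str, ...] = ("mean", "max")
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    n_reps: int = 1000
    min_cores: int = 15
    run_sections: bool = True
    run_cores: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        d["groups"] = [GroupSpec(**g) for g in d.get("groups", [])]
        for key in ("roi_width_mm", "section_ks", "core_ks", "summary_stats", "cutoffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["groups"] = [dataclasses.asdict(g) for g in self.groups]
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All output tables of one run plus reproducibility metadata."""

    config: RunConfig
    tables: dict[str, pd.DataFrame]
    metadata: dict

    def write(self, out_dir=None) -> Path:
        out = Path(out_dir or self.config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        (out / "metadata.yaml").write_text(
            yaml.safe_dump(self.metadata, sort_keys=True), encoding="utf-8"
        )
        return out


def run_pipeline(config: RunConfig | None = None) -> ReportBundle:
    """Execute every stage on a synthetic cohort; deterministic per config."""
    cfg = config or RunConfig()
    tables: dict[str, pd.DataFrame] = {}
    warnings: list[str] = []

    # --- cohort -----------------------------------------------------------
    measurements = generate_section_measurements(
        cfg.groups, seed=stage_seed(cfg.seed, "sections")
    )
    tables["section_measurements"] = measurements

    # --- variance components ---------------------------------------------
    anova = fixed_effects_anova(measurements)
    vc = random_intercept_icc(measurements)
    tables["anova"] = anova.to_frame()
    tables["variance_components"] = pd.DataFrame(
        {
            "sigma2_patient": [vc.sigma2_patient],
            "sigma2_residual": [vc.sigma2_residual],
            "icc": [vc.icc],
            "pct_var_patient_ss": [anova.pct_var_patient],
            "pct_var_section_ss": [anova.pct_var_section],
            "p_section": [anova.p_section],
        }
    )

    # --- section resampling ----------------------------------------------
    if cfg.run_sections:
        truth = patient_truth_and_cutoff(measurements)
        rows = []
        for scheme in SCHEMES:
            for k in cfg.section_ks:
                for stat in cfg.summary_stats:
                    s = resample_section_classification(
                        measurements,
                        k_sections=k,
                        summary_stat=stat,
                        scheme=scheme,
                        n_reps=cfg.n_reps,
                        seed=stage_seed(cfg.seed, f"sections-resample-{scheme}-{k}-{stat}"),
                    )
                    rows.append(
                        {
                            "scheme": s.scheme,
                            "k_sections": s.k_sections,
                            "summary_stat": s.summary_stat,
                            "cutoff": truth.cutoff,
                            "agreement_mean": s.agreement_mean,
                            "agreement_ci_lo": s.agreement_ci95[0],
                            "agreement_ci_hi": s.agreement_ci95[1],
                            "sensitivity_mean": s.sensitivity_mean,
                            "specificity_mean": s.specificity_mean,
                        }
                    )
        tables["section_agreement"] = pd.DataFrame(rows)
        tables["patient_truth"] = truth.truth.assign(cutoff=truth.cutoff)

    # --- spatial slides and cores ----------------------------------------
    if cfg.run_cores:
        core_rows, slide_units, block_units = _core_stage(cfg, measurements, warnings)
        tables["cores"] = pd.concat(core_rows, ignore_index=True)
        tables["core_subsampling"] = _subsample_stage(cfg, slide_units, block_units)
        roc_points = []
        for level, units in (("slide", slide_units), ("block", block_units)):
            usable = {
                u: v for u, v in units.items()
                if len(v) >= max(max(cfg.core_ks) + 1, cfg.min_cores)
            }
            if usable:
                roc_points += roc_over_cutoffs(
                    usable,
                    ks=cfg.core_ks,
                    summary_stats=cfg.summary_stats,
                    cutoffs=cfg.cutoffs,
                    truth_level=level,
                    n_reps=cfg.n_reps,
                    seed=stage_seed(cfg.seed, f"roc-{level}"),
                    min_cores=cfg.min_cores,
                )
            else:
                warnings.append(f"no {level} unit passed the >= {cfg.min_cores} core filter")
        tables["roc"] = roc_to_frame(roc_points)

    metadata = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_clipped_sections": int(measurements.attrs.get("n_clipped", 0)),
        "warnings": warnings,
    }
    return ReportBundle(config=cfg, tables=tables, metadata=metadata)


def _core_stage(cfg: RunConfig, measurements: pd.DataFrame, warnings: list[str]):
    """Generate slides per block, tile and score cores."""
    core_rows = []
    slide_units: dict[str, np.ndarray] = {}
    block_units: dict[str, list] = {}
    rng = np.random.default_rng(stage_seed(cfg.seed, "slides"))
    grid_cfg = CoreGridConfig(min_overlap=0.7, min_tumor_fraction=0.33)
    for pid, sub in measurements.groupby("patient_id", sort=True):
        sub = sub.sort_values("section")
        block_units[pid] = []
        margin = rng.random() < cfg.margin_enriched_fraction
        for s in range(cfg.slides_per_block):
            slide_id = f"{pid}-s{s + 1}"
            target = float(sub["percent_cd8"].iloc[s % len(sub)])
            w = rng.uniform(*cfg.roi_width_mm)
            h = rng.uniform(*cfg.roi_width_mm)
            spec = SlideSpec(
                roi_polygon=rectangle_roi(w, h),
                cell_density=cfg.cell_density_per_mm2,
                target_percent=target,
                pattern="margin_enriched" if margin else "uniform",
                margin_width=cfg.margin_width_um,
                margin_enrichment=cfg.margin_enrichment,
            )
            geometry, cells = generate_slide(
                spec, seed=stage_seed(cfg.seed, f"slide-{slide_id}")
            )
            grid = generate_core_grid(geometry, grid_cfg)
            scored = score_cores(grid, cells)
            if not scored:
                warnings.append(f"slide {slide_id}: no scoreable cores")
                continue
            core_rows.append(cores_to_frame(slide_id, scored))
            percents = np.array([c.percent_cd8 for c in scored])
            slide_units[slide_id] = percents
            block_units[pid].append(percents)
    pooled = {
        pid: block_pool(slides)[0] for pid, slides in block_units.items() if slides
    }
    return core_rows, slide_units, pooled


def _subsample_stage(cfg: RunConfig, slide_units, block_units) -> pd.DataFrame:
    rows = []
    for level, units in (("slide", slide_units), ("block", block_units)):
        for uid, percents in units.items():
            if len(percents) < max(max(cfg.core_ks) + 1, cfg.min_cores):
                continue
            for k in cfg.core_ks:
                for stat in cfg.summary_stats:
                    s = subsample_cores(
                        percents,
                        k=k,
                        summary_stat=stat,
                        n_reps=cfg.n_reps,
                        seed=stage_seed(cfg.seed, f"subsample-{level}-{uid}-{k}-{stat}"),
                        min_cores=cfg.min_cores,
                        slide_id=uid,
                    )
                    rows.append(
                        {
                            "truth_level": level,
                            "unit_id": uid,
                            "k": k,
                            "summary_stat": stat,
                            "n_cores": len(percents),
                            "within_1sd_rate": s.within_1sd_rate,
                            "oob_diff_mean": s.oob_diff_mean,
                            "oob_diff_sd": s.oob_diff_sd,
                        }
                    )
    return pd.DataFrame(rows)
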