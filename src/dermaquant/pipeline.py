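"""End-to-end study runs: synthesis/ingest → segmentation → statistics → outputs.

A run consumes either a study bundle on disk (images + absorbance CSVs +
functional CSVs, as written by :func:`dermaquant.synthetic_data.generate_study`)
or synthesizes the study in memory from a :class:`StudyDesign`, then emits the
analysis surfaces:

* ``tile_stats.csv`` — one row per 250×250 tile (N_G, N_PC, gap pixels),
* ``comparison_table.csv`` — VAS-vs-IMQ Mann–Whitney p-values per
  (strain, timepoint) for N_G and N_PC,
* ``boxplot_summary.csv`` + ``boxplots.png`` — five-number summaries of the
  60-tile sequences,
* ``auc_table.csv`` / ``auc_stats.csv`` — per-replicate trapezoid AUC of the
  permeation profiles and the group tests on them,
* ``functional_pct.csv`` — baseline-normalized percent-change courses
  (mean ± SEM per group),
* ``overlays/<arm>_overlay.png`` — yellow/blue gap-vs-cell renderings,
* ``run_manifest.json`` — every tunable, every derived seed, output row
  counts and any warnings; identical config + seed give identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import functional_params as fp
from . import gap_segmentation as seg
from . import permeation as perm
from . import sem_image as semi
from . import synthetic_data as synth
from .group_stats import boxplot_summary, condition_table

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """All tunables of one pipeline run (flags > config file > defaults)."""

    out_dir: str = "dermaquant_out"
    bundle_dir: str | None = None  # None -> synthesize in memory
    master_seed: int = 0
    tile_px: int = 250
    banner_rows: int | None = None  # None -> 250 for 1750-row rasters else 0
    frac: float = 0.40
    connectivity: int = 8
    min_area: int = 1
    threshold_scope: str = "tile"
    auc_window: tuple[float, float] = (0.0, 180.0)
    plateau_rel_tol: float = 0.05
    mw_method: str = "auto"
    alpha: float = 0.05
    log_level: str = "INFO"
    design: synth.StudyDesign = field(default_factory=synth.StudyDesign)

    def __post_init__(self) -> None:
        if self.connectivity != 8:
            raise ValueError("only 8-connected gap regions are supported")
        if not 0.0 < self.frac < 1.0:
            raise ValueError("frac must lie in (0, 1)")
        if self.threshold_scope not in ("tile", "image"):
            raise ValueError("threshold_scope must be 'tile' or 'image'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        design_raw = raw.pop("design", {})
        texture = synth.TextureParams(**design_raw.pop("texture", {}))
        permeation = synth.PermeationParams(**design_raw.pop("permeation", {}))
        design = synth.StudyDesign(
            texture=texture, permeation=permeation, **design_raw
        )
        if "auc_window" in raw:
            raw["auc_window"] = tuple(raw["auc_window"])
        return cls(design=design, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["auc_window"] = list(self.auc_window)
        return d


def _effective_banner_rows(cfg: RunConfig, height_px: int) -> int:
    if cfg.banner_rows is not None:
        return cfg.banner_rows
    return 250 if height_px == 1750 else 0


def _load_bundle_images(cfg: RunConfig) -> dict[str, semi.SEMImage]:
    bundle = Path(cfg.bundle_dir)
    images = {}
    for strain, treatment, timepoint in cfg.design.arms():
        label = f"{strain}_{treatment}_{timepoint}h"
        path = bundle / "images" / f"{label}.png"
        if not path.exists():
            raise FileNotFoundError(
                f"bundle is missing the image for arm {label} ({path})"
            )
        img = semi.load_grayscale(path)
        images[label] = img
    return images


def _synthesize_images(cfg: RunConfig) -> tuple[dict[str, semi.SEMImage], dict]:
    images, truth = {}, {}
    d = cfg.design
    for strain, treatment, timepoint in d.arms():
        label = f"{strain}_{treatment}_{timepoint}h"
        severity = 1.0 if treatment == "VAS" else d.gap_density_effect
        tex = synth.TextureParams(
            **{
                **dataclasses.asdict(d.texture),
                "n_cells": int(round(d.texture.n_cells * severity)),
                "detachment_fraction": 0.0 if treatment == "VAS" else 0.3,
                "rng_seed": synth.child_seed(d.master_seed, f"tex_{label}"),
            }
        )
        img, t = synth.generate_sem_texture(tex)
        images[label] = img
        truth[label] = {"n_gaps": t.n_gaps, "gap_px": int(t.gap_mask.sum())}
    return images, truth


def _segment_arm(
    cfg: RunConfig, label: str, img: semi.SEMImage, overlays_dir: Path
) -> pd.DataFrame:
    strain, treatment, tp = label.rsplit("_", 2)[0], label.split("_")[-2], label.split("_")[-1]
    timepoint = int(tp.rstrip("h"))
    banner = _effective_banner_rows(cfg, img.height_px)
    cropped = semi.crop_scan_area(
        semi.SEMImage(pixels=img.pixels, banner_rows=banner)
    )
    grid = semi.tile_image(cropped, tile_px=cfg.tile_px)
    stats = seg.segment_tiles(
        grid, frac=cfg.frac, threshold_scope=cfg.threshold_scope, min_area=cfg.min_area
    )
    # Fig-6-style overlay of the whole scan area, thresholded per run scope.
    full_mask = seg.binarize_gaps(cropped, frac=cfg.frac)
    iio.imwrite(overlays_dir / f"{label}_overlay.png", seg.render_overlay(full_mask))
    return pd.DataFrame(
        {
            "strain": strain, "treatment": treatment, "timepoint": timepoint,
            "tile_row": [s.tile_origin[0] for s in stats],
            "tile_col": [s.tile_origin[1] for s in stats],
            "n_g": [s.n_g for s in stats],
            "n_pc": [s.n_pc for s in stats],
            "gap_px": [s.gap_px for s in stats],
            "threshold_value": [s.threshold_value for s in stats],
        }
    )


def _boxplot_outputs(tile_stats: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    rows = []
    for (strain, treatment, timepoint), g in tile_stats.groupby(
        ["strain", "treatment", "timepoint"], sort=True
    ):
        for stat in ("n_g", "n_pc"):
            s = boxplot_summary(g[stat])
            rows.append(
                {
                    "strain": strain, "treatment": treatment, "timepoint": timepoint,
                    "statistic": stat, "min": s.min, "q1": s.q1, "median": s.median,
                    "q3": s.q3, "max": s.max, "n": s.n, "mean": s.mean, "sd": s.sd,
                }
            )
    summary = pd.DataFrame(rows)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strains = sorted(tile_stats["strain"].unique())
    fig, axes = plt.subplots(
        len(strains), 2, figsize=(10, 3 * len(strains)), squeeze=False
    )
    for i, strain in enumerate(strains):
        sub = tile_stats[tile_stats["strain"] == strain]
        conds = sorted(
            sub.groupby(["treatment", "timepoint"]).groups.keys(),
            key=lambda k: (k[0], k[1]),
        )
        for j, stat in enumerate(("n_pc", "n_g")):
            data = [
                sub[(sub["treatment"] == tr) & (sub["timepoint"] == tp)][stat]
                for tr, tp in conds
            ]
            axes[i][j].boxplot(data, tick_labels=[f"{tr} {tp}h" for tr, tp in conds])
            axes[i][j].set_title(f"{strain} {stat.upper()}")
    fig.tight_layout()
    fig.savefig(out_dir / "boxplots.png", dpi=100)
    plt.close(fig)
    return summary


def _permeation_outputs(cfg: RunConfig, out_dir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = cfg.design
    cal = perm.Calibration(
        slope=d.permeation.cal_slope, intercept=d.permeation.cal_intercept
    )
    rows = []
    for strain, treatment, timepoint in d.arms():
        label = f"{strain}_{treatment}_{timepoint}h"
        if cfg.bundle_dir is not None:
            df = pd.read_csv(Path(cfg.bundle_dir) / "permeation" / f"{label}.csv")
            reps = {
                int(r): g.sort_values("time_min")["absorbance"].to_numpy()
                for r, g in df.groupby("replicate")
            }
        else:
            reps = {}
            for rep in range(d.n_chip_replicates):
                pp = synth.PermeationParams(
                    **{
                        **dataclasses.asdict(d.permeation),
                        "severity_multiplier": (
                            d.permeation_effect if treatment == "IMQ" else 1.0
                        ),
                        "rng_seed": synth.child_seed(
                            d.master_seed, f"perm_{label}_{rep}"
                        ),
                    }
                )
                absorbance, _ = synth.generate_permeation_series(pp)
                reps[rep + 1] = absorbance
        for rep, absorbance in sorted(reps.items()):
            profile = perm.profile_from_fractions(
                absorbance, cal,
                flow_ul_min=d.permeation.flow_ul_min,
                interval_min=d.permeation.interval_min,
            )
            auc = perm.auc_trapezoid(profile, window=cfg.auc_window)
            plateau = perm.plateau_time(profile, rel_tol=cfg.plateau_rel_tol)
            rows.append(
                {
                    "strain": strain, "treatment": treatment, "timepoint": timepoint,
                    "replicate": rep, "auc": auc.auc,
                    "window_start_min": auc.window_min[0],
                    "window_end_min": auc.window_min[1],
                    "plateau_min": plateau if plateau is not None else np.nan,
                }
            )
    auc_table = pd.DataFrame(rows)
    stat_rows = []
    for strain, g in auc_table.groupby("strain", sort=True):
        result = perm.compare_auc(g)
        for key, tr in result["anova"].items():
            stat_rows.append(
                {
                    "strain": strain, "term": key, "statistic": tr.statistic_name,
                    "value": tr.statistic_value, "p_value": tr.p_value,
                }
            )
    return auc_table, pd.DataFrame(stat_rows)


def _functional_outputs(cfg: RunConfig) -> pd.DataFrame:
    d = cfg.design
    frames = []
    for parameter in fp.PARAMETERS:
        series = []
        for strain in d.strains:
            for treatment in d.treatments:
                if cfg.bundle_dir is not None:
                    path = (
                        Path(cfg.bundle_dir) / "functional"
                        / f"{strain}_{treatment}_{parameter}.csv"
                    )
                    raw = pd.read_csv(path)
                    for animal, g in raw.groupby("animal_id"):
                        g = g.sort_values("time_h")
                        series.append(
                            fp.FunctionalSeries(
                                parameter=parameter,
                                times_h=g["time_h"].to_numpy(),
                                values=g["value"].to_numpy(),
                                animal_id=str(animal), strain=strain,
                                treatment=treatment,
                            )
                        )
                else:
                    series.extend(
                        synth.generate_functional_series(
                            strain, treatment, parameter,
                            seed=synth.child_seed(
                                d.master_seed, f"fun_{strain}_{treatment}_{parameter}"
                            ),
                            n_animals=d.n_animals,
                            thickness_effect_pct=d.thickness_effect_pct,
                            tewl_effect=d.tewl_effect,
                            weight_effect_pct=d.weight_effect_pct,
                            noise_sd=d.functional_noise_sd,
                        )
                    )
        pct = [fp.percent_change(s) for s in series]
        frames.append(fp.group_course(pct, parameter))
    return pd.concat(frames, ignore_index=True)


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Output CSVs are written with a fixed float format so identical config and
    master seed reproduce them byte-for-byte.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    overlays = out_dir / "overlays"
    overlays.mkdir(exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "outputs": {}, "warnings": []}

    if config.bundle_dir is not None:
        images = _load_bundle_images(config)
        manifest["ground_truth"] = None
    else:
        images, truth = _synthesize_images(config)
        manifest["ground_truth"] = truth

    tile_frames = [
        _segment_arm(config, label, img, overlays) for label, img in sorted(images.items())
    ]
    tile_stats = pd.concat(tile_frames, ignore_index=True)
    tile_stats.to_csv(out_dir / "tile_stats.csv", index=False, float_format=_CSV_FLOAT)

    comparison = condition_table(tile_stats, alpha=config.alpha, method=config.mw_method)
    comparison.to_csv(
        out_dir / "comparison_table.csv", index=False, float_format=_CSV_FLOAT
    )

    summary = _boxplot_outputs(tile_stats, out_dir)
    summary.to_csv(
        out_dir / "boxplot_summary.csv", index=False, float_format=_CSV_FLOAT
    )

    auc_table, auc_stats = _permeation_outputs(config, out_dir)
    auc_table.to_csv(out_dir / "auc_table.csv", index=False, float_format=_CSV_FLOAT)
    auc_stats.to_csv(out_dir / "auc_stats.csv", index=False, float_format=_CSV_FLOAT)

    functional = _functional_outputs(config)
    functional.to_csv(
        out_dir / "functional_pct.csv", index=False, float_format=_CSV_FLOAT
    )

    manifest["outputs"] = {
        "tile_stats_rows": int(len(tile_stats)),
        "comparison_rows": int(len(comparison)),
        "boxplot_rows": int(len(summary)),
        "auc_rows": int(len(auc_table)),
        "functional_rows": int(len(functional)),
        "n_conditions": len(config.design.arms()),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    logger.info("run complete: %s", manifest["outputs"])
    return manifest
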