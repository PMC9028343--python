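"""Synthetic study inputs with known ground truth.

The original micrographs, fraction absorbances and in-vivo series are not
publicly deposited, so the pipeline is exercised on generated data that
emulates their structure:

* **SEM textures** — a nearest-seed (Voronoi) corneocyte mosaic on the pixel
  grid; pixels within a half-width of a mosaic boundary are painted at the
  dark gap level, a configurable fraction of cells additionally sheds a
  displaced bright "plaque" copy whose dark rim adds gap boundary (the
  psoriasis-severity knob), Gaussian noise is added after the ground-truth
  gap mask is captured, and the bottom rows are stamped with a flat mid-gray
  instrument banner.
* **Permeation series** — fraction concentrations sampled from the
  saturating uptake curve C(t) = c_ss (1 − exp(−(t − t_lag)/τ)) for
  t > t_lag, converted to absorbances through a declared linear calibration,
  with Gaussian absorbance noise floored at 0; the true AUC over any window
  follows from the closed-form integral.
* **Functional series** — IMQ arms follow monotone mean trajectories
  (thickness, perfusion and TEWL rising, body weight falling), VAS arms stay
  flat, with lognormal animal-level noise.

Every generator is deterministic given its seed; per-arm child seeds are
derived from the master seed and the arm label so arms are independent yet
reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from scipy.spatial import cKDTree

from .functional_params import FunctionalSeries
from .sem_image import SEMImage

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureParams:
    """Corneocyte-texture generator settings (reference raster 1750×2560)."""

    height_px: int = 1750
    width_px: int = 2560
    banner_rows: int = 250
    n_cells: int = 150
    gap_width_px: float = 2.0
    gap_intensity_mean: float = 30.0
    cell_intensity_mean: float = 200.0
    plaque_intensity_mean: float = 245.0
    banner_intensity: float = 120.0
    noise_sd: float = 8.0
    detachment_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height_px, self.width_px, self.n_cells) < 1:
            raise ValueError("pixel counts and n_cells must be >= 1")
        if not 0.0 <= self.detachment_fraction <= 1.0:
            raise ValueError("detachment_fraction must lie in [0, 1]")
        if not self.gap_intensity_mean < self.cell_intensity_mean:
            raise ValueError("gap intensity must be below cell intensity")
        if not 0 <= self.banner_rows < self.height_px:
            raise ValueError("banner_rows must lie in [0, height_px)")


@dataclass(frozen=True)
class PermeationParams:
    """Saturating uptake-curve settings for one diffusion-cell run."""

    c_ss: float = 12.0  # plateau fraction concentration, µg/mL
    tau_min: float = 45.0
    t_lag_min: float = 0.0
    noise_sd: float = 0.01  # absorbance units
    interval_min: float = 30.0
    flow_ul_min: float = 4.0
    n_fractions: int = 10  # 5 h of 30-min fractions
    severity_multiplier: float = 1.0
    cal_slope: float = 20.0  # declared calibration: µg/mL per AU
    cal_intercept: float = 0.0
    applied_dose_ug: float = 20000.0  # 1000 µL of 2% caffeine cream
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.c_ss <= 0 or self.tau_min <= 0:
            raise ValueError("c_ss and tau must be positive")
        if self.t_lag_min < 0:
            raise ValueError("t_lag must be non-negative")
        if self.severity_multiplier <= 0:
            raise ValueError("severity_multiplier must be positive")


@dataclass(frozen=True)
class StudyDesign:
    """Fully crossed strain × treatment × timepoint layout with effect sizes."""

    strains: tuple[str, ...] = ("WT", "TRPA1KO", "TRPV1KO")
    treatments: tuple[str, ...] = ("VAS", "IMQ")
    timepoints_h: tuple[int, ...] = (24, 96)
    n_animals: int = 5
    n_chip_replicates: int = 3
    gap_density_effect: float = 2.5  # IMQ multiplier on expected gap density
    permeation_effect: float = 2.5  # IMQ multiplier on c_ss
    thickness_effect_pct: float = 100.0  # IMQ thickness increase at 96 h
    tewl_effect: float = 3.0  # IMQ TEWL fold change at 96 h
    weight_effect_pct: float = -10.0  # IMQ body-weight change at 96 h
    functional_noise_sd: float = 0.05  # lognormal sigma of animal noise
    texture: TextureParams = field(default_factory=TextureParams)
    permeation: PermeationParams = field(default_factory=PermeationParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for eff in (self.gap_density_effect, self.permeation_effect, self.tewl_effect):
            if eff <= 0:
                raise ValueError("effect multipliers must be positive")

    def arms(self) -> list[tuple[str, str, int]]:
        return [
            (s, tr, tp)
            for s in self.strains
            for tr in self.treatments
            for tp in self.timepoints_h
        ]


def child_seed(master_seed: int, label: str) -> int:
    """Deterministic per-arm seed: hash of (master seed, label), < 2^31."""
    return (master_seed * 2654435761 + zlib.crc32(label.encode())) % (2**31)


# ---------------------------------------------------------------------------
# SEM texture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TextureTruth:
    """Planted ground truth captured before noise was added."""

    gap_mask: np.ndarray  # bool, full raster; False everywhere in the banner
    n_gaps: int  # 8-connected components of gap_mask


def generate_sem_texture(params: TextureParams) -> tuple[SEMImage, TextureTruth]:
    """Generate one corneocyte-like texture and its planted gap topology."""
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.height_px, params.width_px
    seeds = np.column_stack(
        [rng.uniform(0, h, params.n_cells), rng.uniform(0, w, params.n_cells)]
    )
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    _, nearest = cKDTree(seeds).query(pts, k=1)
    labels = nearest.reshape(h, w)

    # Boundary pixels: label differs from the east or south neighbour.
    boundary = np.zeros((h, w), dtype=bool)
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if boundary.any():
        dist = _ndi.distance_transform_edt(~boundary)
        band = dist <= params.gap_width_px
    else:
        band = np.zeros((h, w), dtype=bool)
    if band.all():
        raise ValueError("gap band covers the entire image; widen cells or shrink band")

    base = np.full((h, w), params.cell_intensity_mean, dtype=float)
    gap_mask = band.copy()

    # Detached plaques: displaced bright copies of whole cells with dark rims.
    n_plaques = int(round(params.detachment_fraction * params.n_cells))
    if n_plaques:
        chosen = rng.choice(params.n_cells, size=n_plaques, replace=False)
        plaque_all = np.zeros((h, w), dtype=bool)
        rim_all = np.zeros((h, w), dtype=bool)
        for cell_idx in chosen:
            cell = labels == cell_idx
            dr_off = int(rng.integers(5, 16)) * int(rng.choice([-1, 1]))
            dc_off = int(rng.integers(5, 16)) * int(rng.choice([-1, 1]))
            shifted = np.zeros_like(cell)
            src = cell[
                max(0, -dr_off) : h - max(0, dr_off),
                max(0, -dc_off) : w - max(0, dc_off),
            ]
            shifted[
                max(0, dr_off) : h - max(0, -dr_off),
                max(0, dc_off) : w - max(0, -dc_off),
            ] = src
            rim = _ndi.binary_dilation(shifted, iterations=2) & ~shifted
            plaque_all |= shifted
            rim_all |= rim
        rim_all &= ~plaque_all
        # plaques are painted first and the gap network last, so boundary
        # gaps stay visible through overlying plaques (cracked-plaque look);
        # detachment therefore only ever adds gap pixels (rims)
        gap_mask = gap_mask | rim_all
        base[plaque_all] = params.plaque_intensity_mean

    base[gap_mask] = params.gap_intensity_mean
    if params.banner_rows:
        scan_h = h - params.banner_rows
        gap_mask[scan_h:, :] = False
        base[scan_h:, :] = params.banner_intensity

    if params.noise_sd > 0:
        base = base + rng.normal(0.0, params.noise_sd, size=base.shape)
    pixels = np.clip(np.rint(base), 0, 255).astype(np.uint8)

    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity
    _, n_gaps = _ndi.label(gap_mask, structure=structure)
    img = SEMImage(
        pixels=pixels, banner_rows=params.banner_rows, magnification_label="300x"
    )
    return img, TextureTruth(gap_mask=gap_mask, n_gaps=int(n_gaps))


# ---------------------------------------------------------------------------
# Permeation series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermeationTruth:
    times_min: np.ndarray
    conc_curve: np.ndarray  # noise-free fraction concentrations, µg/mL
    cal_slope: float
    cal_intercept: float

    def true_auc(self, window: tuple[float, float], params: PermeationParams) -> float:
        """Closed-form ∫C dt over ``window`` of the generating curve."""
        c = params.c_ss * params.severity_multiplier
        tau, lag = params.tau_min, params.t_lag_min

        def primitive(t: float) -> float:
            if t <= lag:
                return 0.0
            u = t - lag
            return c * (u - tau * (1.0 - np.exp(-u / tau)))

        return primitive(window[1]) - primitive(window[0])


def uptake_curve(t, params: PermeationParams) -> np.ndarray:
    """Noise-free concentration C(t) of the saturating uptake model."""
    t = np.asarray(t, dtype=float)
    c = params.c_ss * params.severity_multiplier
    u = np.maximum(t - params.t_lag_min, 0.0)
    return c * (1.0 - np.exp(-u / params.tau_min))


def generate_permeation_series(
    params: PermeationParams,
) -> tuple[np.ndarray, PermeationTruth]:
    """Fraction absorbances for one run plus the generating ground truth."""
    rng = np.random.default_rng(params.rng_seed)
    times = params.interval_min * np.arange(1, params.n_fractions + 1)
    conc = uptake_curve(times, params)
    absorbance = (conc - params.cal_intercept) / params.cal_slope
    if params.noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, params.noise_sd, size=times.shape)
    absorbance = np.maximum(absorbance, 0.0)
    truth = PermeationTruth(
        times_min=times, conc_curve=conc,
        cal_slope=params.cal_slope, cal_intercept=params.cal_intercept,
    )
    return absorbance, truth


# ---------------------------------------------------------------------------
# Functional series
# ---------------------------------------------------------------------------

#: Baseline values per parameter (units as named).
FUNCTIONAL_BASELINES = {
    "thickness_mm": 0.7,
    "perfusion_AU": 100.0,
    "weight_g": 22.0,
    "tewl_g_m2_h": 8.0,
}


def generate_functional_series(
    strain: str,
    treatment: str,
    parameter: str,
    seed: int,
    n_animals: int = 5,
    times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0),
    thickness_effect_pct: float = 100.0,
    tewl_effect: float = 3.0,
    weight_effect_pct: float = -10.0,
    perfusion_effect: float = 1.6,
    noise_sd: float = 0.05,
) -> list[FunctionalSeries]:
    """One cohort of site-averaged series for a (strain, treatment) arm.

    IMQ arms ramp linearly in the mean from baseline at 0 h to the stated
    96 h effect; VAS arms stay flat.  Animal-level lognormal noise with
    sigma ``noise_sd`` multiplies every measurement.
    """
    if parameter not in FUNCTIONAL_BASELINES:
        raise ValueError(f"unknown parameter {parameter!r}")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    ramp = t / 96.0
    baseline = FUNCTIONAL_BASELINES[parameter]
    if treatment == "IMQ":
        if parameter == "thickness_mm":
            mean = baseline * (1.0 + thickness_effect_pct / 100.0 * ramp)
        elif parameter == "tewl_g_m2_h":
            mean = baseline * (1.0 + (tewl_effect - 1.0) * ramp)
        elif parameter == "weight_g":
            mean = baseline * (1.0 + weight_effect_pct / 100.0 * ramp)
        else:
            mean = baseline * (1.0 + (perfusion_effect - 1.0) * ramp)
    else:
        mean = np.full_like(t, baseline)
    cohort = []
    for i in range(n_animals):
        if noise_sd > 0:
            noise = rng.lognormal(mean=0.0, sigma=noise_sd, size=t.shape)
        else:
            noise = np.ones_like(t)
        cohort.append(
            FunctionalSeries(
                parameter=parameter, times_h=t, values=mean * noise,
                animal_id=f"{strain}_{treatment}_{i + 1}",
                strain=strain, treatment=treatment,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Tile-statistic generator (for statistical calibration at scale)
# ---------------------------------------------------------------------------


def generate_tile_stat_table(
    design: StudyDesign,
    n_tiles: int = 60,
    tile_px: int = 250,
    base_gap_rate: float = 40.0,
    mean_gap_area_px: float = 120.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-tile N_G / N_PC draws matching the study layout, without images.

    Gap counts per tile are Poisson with rate ``base_gap_rate`` (scaled by
    ``gap_density_effect`` in IMQ arms); gap pixel totals are Gamma-
    distributed around ``mean_gap_area_px`` per gap.  This generator feeds
    the type-I-error and power calibration of the comparison table, where
    hundreds of replicate studies are needed and full image synthesis would
    be disproportionate; the statistical pipeline downstream is identical.
    """
    if rng is None:
        rng = np.random.default_rng(design.master_seed)
    total_px = tile_px * tile_px
    rows = []
    for strain, treatment, timepoint in design.arms():
        rate = base_gap_rate * (
            design.gap_density_effect if treatment == "IMQ" else 1.0
        )
        n_g = rng.poisson(rate, size=n_tiles)
        gap_px = np.zeros(n_tiles, dtype=int)
        pos = n_g > 0
        if pos.any():
            areas = rng.gamma(
                shape=2.0, scale=mean_gap_area_px / 2.0, size=int(pos.sum())
            )
            gap_px[pos] = np.maximum(
                n_g[pos], np.rint(n_g[pos] * areas).astype(int)
            )
        gap_px = np.minimum(gap_px, total_px)
        for i in range(n_tiles):
            rows.append(
                {
                    "strain": strain, "treatment": treatment, "timepoint": timepoint,
                    "tile_row": (i // 10) * tile_px, "tile_col": (i % 10) * tile_px,
                    "n_g": int(n_g[i]), "n_pc": int(total_px - gap_px[i]),
                    "gap_px": int(gap_px[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


def generate_study(design: StudyDesign, out_dir: str | Path, force: bool = False) -> Path:
    """Write the full factorial study bundle to ``out_dir``.

    Per (strain, treatment, timepoint) arm: one texture PNG, one absorbance
    CSV holding the chip replicates, and per-parameter functional CSVs per
    (strain, treatment); plus ``ground_truth.json`` with the planted values.
    Child seeds are derived from ``design.master_seed`` and the arm label.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "permeation").mkdir(exist_ok=True)
    (out / "functional").mkdir(exist_ok=True)

    truth: dict = {"arms": {}, "master_seed": design.master_seed}
    for strain, treatment, timepoint in design.arms():
        label = f"{strain}_{treatment}_{timepoint}h"
        severity = 1.0 if treatment == "VAS" else design.gap_density_effect
        # more, smaller cells plus plaque shedding raise planted gap density
        tex = TextureParams(
            **{
                **asdict(design.texture),
                "n_cells": int(round(design.texture.n_cells * severity)),
                "detachment_fraction": 0.0 if treatment == "VAS" else 0.3,
                "rng_seed": child_seed(design.master_seed, f"tex_{label}"),
            }
        )
        img, tex_truth = generate_sem_texture(tex)
        iio.imwrite(out / "images" / f"{label}.png", img.pixels)

        per_runs = []
        for rep in range(design.n_chip_replicates):
            pp = PermeationParams(
                **{
                    **asdict(design.permeation),
                    "severity_multiplier": (
                        design.permeation_effect if treatment == "IMQ" else 1.0
                    ),
                    "rng_seed": child_seed(design.master_seed, f"perm_{label}_{rep}"),
                }
            )
            absorbance, p_truth = generate_permeation_series(pp)
            per_runs.append(
                pd.DataFrame(
                    {
                        "replicate": rep + 1,
                        "time_min": p_truth.times_min,
                        "absorbance": absorbance,
                    }
                )
            )
        pd.concat(per_runs).to_csv(
            out / "permeation" / f"{label}.csv", index=False, float_format="%.10g"
        )
        truth["arms"][label] = {
            "n_gaps": tex_truth.n_gaps,
            "gap_px": int(tex_truth.gap_mask.sum()),
            "texture_seed": tex.rng_seed,
        }

    for strain in design.strains:
        for treatment in design.treatments:
            for parameter in FUNCTIONAL_BASELINES:
                cohort = generate_functional_series(
                    strain, treatment, parameter,
                    seed=child_seed(
                        design.master_seed, f"fun_{strain}_{treatment}_{parameter}"
                    ),
                    n_animals=design.n_animals,
                    thickness_effect_pct=design.thickness_effect_pct,
                    tewl_effect=design.tewl_effect,
                    weight_effect_pct=design.weight_effect_pct,
                    noise_sd=design.functional_noise_sd,
                )
                rows = [
                    {
                        "animal_id": s.animal_id, "strain": s.strain,
                        "treatment": s.treatment, "time_h": t, "value": v,
                    }
                    for s in cohort
                    for t, v in zip(s.times_h, s.values)
                ]
                pd.DataFrame(rows).to_csv(
                    out / "functional" / f"{strain}_{treatment}_{parameter}.csv",
                    index=False, float_format="%.10g",
                )

    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return out
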