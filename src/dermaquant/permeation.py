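"""Flow-through diffusion-cell permeation profiles, AUC and plateau detection.

The skin-on-a-chip receptor compartment is perfused at a constant rate
(4 µL/min in the reference setup) and the effluent is collected in 30-min
fractions, so each vial holds ``flow × interval`` µL.  Fraction absorbances
measured at 273 nm are converted to concentrations through a linear standard
curve, attributed to the fraction's end time (the vial aggregates the whole
interval; a midpoint convention is available), and integrated by the
composite trapezoidal rule to the AUC endpoint.  Units are fixed: µg/mL,
min, µL, cm²; AUC is reported in µg·min/mL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group_stats import TestResult, student_t, two_way_anova_bonferroni

logger = logging.getLogger(__name__)

#: Default integration window (min): the reference analysis uses the first 3 h.
DEFAULT_AUC_WINDOW = (0.0, 180.0)

#: Default diffusion surface (cm²) of the chip's skin aperture.
DEFAULT_AREA_CM2 = 0.5


@dataclass(frozen=True)
class Calibration:
    """Linear absorbance→concentration standard curve at a fixed wavelength."""

    slope: float  # µg/mL per absorbance unit
    intercept: float  # µg/mL
    wavelength_nm: float = 273.0
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, absorbance) -> np.ndarray:
        return self.slope * np.asarray(absorbance, dtype=float) + self.intercept


@dataclass(frozen=True)
class ConcentrationProfile:
    """Fraction-wise concentration-time profile of the receptor effluent."""

    times_min: np.ndarray  # strictly increasing fraction end-times
    conc: np.ndarray  # µg/mL per fraction, >= 0
    flow_ul_min: float = 4.0
    interval_min: float = 30.0
    area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.size == 0 or t.shape != c.shape:
            raise ValueError("times and concentrations must be matching 1-D arrays")
        if not (np.diff(t) > 0).all() or t[0] <= 0:
            raise ValueError("fraction end-times must be positive and strictly increasing")
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.flow_ul_min <= 0 or self.interval_min <= 0:
            raise ValueError("flow and interval must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "conc", c)

    @property
    def fraction_volume_ul(self) -> float:
        return self.flow_ul_min * self.interval_min

    def cumulative_amount_ug(self) -> float:
        """Total drug collected: Σ conc_i × fraction volume (µg)."""
        return float(self.conc.sum() * self.fraction_volume_ul * 1e-3)


@dataclass(frozen=True)
class AUCResult:
    auc: float  # µg·min/mL
    window_min: tuple[float, float]
    method: str = "trapezoid"
    per_area: bool = field(default=False)


def calibrate_absorbance(standards) -> Calibration:
    """Fit concentration on absorbance by ordinary least squares.

    ``standards`` is a sequence of ``(concentration, absorbance)`` pairs
    (µg/mL, AU); at least two distinct absorbances are required.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (concentration, absorbance) standards")
    conc, absb = pts[:, 0], pts[:, 1]
    if np.ptp(absb) == 0:
        raise ValueError("degenerate standard curve: all absorbances identical")
    a_mean, c_mean = absb.mean(), conc.mean()
    sxx = float(((absb - a_mean) ** 2).sum())
    sxy = float(((absb - a_mean) * (conc - c_mean)).sum())
    slope = sxy / sxx
    intercept = float(c_mean - slope * a_mean)
    resid = conc - (slope * absb + intercept)
    sst = float(((conc - c_mean) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - float((resid**2).sum()) / sst
    return Calibration(slope=slope, intercept=intercept, r_squared=max(0.0, min(1.0, r2)))


def profile_from_fractions(
    absorbances,
    cal: Calibration,
    flow_ul_min: float = 4.0,
    interval_min: float = 30.0,
    area_cm2: float = DEFAULT_AREA_CM2,
    time_convention: str = "end",
) -> ConcentrationProfile:
    """Convert ordered fraction absorbances into a concentration-time profile.

    Concentrations below zero after calibration (blank noise) are floored at
    0 with a logged warning.  ``time_convention`` places each fraction at its
    interval's ``"end"`` (default) or ``"midpoint"``.
    """
    a = np.asarray(absorbances, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("absorbances must be a non-empty 1-D sequence")
    if flow_ul_min <= 0 or interval_min <= 0:
        raise ValueError("flow and interval must be positive")
    conc = cal.concentration(a)
    n_neg = int((conc < 0).sum())
    if n_neg:
        logger.warning("floored %d negative calibrated concentrations at 0", n_neg)
        conc = np.maximum(conc, 0.0)
    k = np.arange(1, a.size + 1, dtype=float)
    times = interval_min * k
    if time_convention == "midpoint":
        times = times - interval_min / 2.0
    elif time_convention != "end":
        raise ValueError(f"unknown time convention {time_convention!r}")
    return ConcentrationProfile(
        times_min=times, conc=conc, flow_ul_min=flow_ul_min,
        interval_min=interval_min, area_cm2=area_cm2,
    )


def auc_trapezoid(
    profile: ConcentrationProfile,
    window: tuple[float, float] = DEFAULT_AUC_WINDOW,
    per_area: bool = False,
) -> AUCResult:
    """Composite trapezoidal AUC over ``window`` (µg·min/mL).

    A (0, 0) anchor is prepended — the receptor starts drug-free — and the
    profile is linearly interpolated at the window edges.  ``per_area``
    divides by the diffusion surface (µg·min/mL/cm²).
    """
    t0, t1 = float(window[0]), float(window[1])
    if not t0 < t1:
        raise ValueError(f"empty or reversed AUC window {window}")
    t = np.concatenate([[0.0], profile.times_min])
    c = np.concatenate([[0.0], profile.conc])
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(
            f"window {window} exceeds profile span [{t[0]}, {t[-1]}] min"
        )
    edges = [t0, t1]
    inner = t[(t > t0) & (t < t1)]
    grid = np.unique(np.concatenate([edges, inner]))
    vals = np.interp(grid, t, c)
    auc = float(np.trapezoid(vals, grid))
    if per_area:
        auc /= profile.area_cm2
    return AUCResult(auc=auc, window_min=(t0, t1), per_area=per_area)


def plateau_time(profile: ConcentrationProfile, rel_tol: float = 0.05) -> float | None:
    """Earliest fraction time after which the profile stops rising.

    Returns the earliest fraction end-time ``t*`` such that every successive
    step strictly after ``t*`` changes by at most ``rel_tol`` of the profile
    maximum (|ΔC| / max(C) ≤ rel_tol); ``None`` if no such time exists.  A
    constant profile plateaus at its first fraction.  The rule is invariant
    to uniform scaling of the concentration axis.
    """
    if profile.conc.size < 3:
        raise ValueError("plateau detection requires at least 3 fractions")
    c = profile.conc
    cmax = float(c.max())
    if cmax == 0.0:
        return float(profile.times_min[0])
    rel_steps = np.abs(np.diff(c)) / cmax  # step i is times[i] -> times[i+1]
    ok = rel_steps <= rel_tol
    # earliest index i such that all steps starting at i or later are ok
    violating = np.nonzero(~ok)[0]
    if violating.size == 0:
        return float(profile.times_min[0])
    first_ok = violating[-1] + 1
    if first_ok >= rel_steps.size:
        return None
    return float(profile.times_min[first_ok])


def compare_auc(groups: pd.DataFrame, response: str = "auc") -> dict:
    """Group comparison of AUC endpoints.

    ``groups`` carries one row per profile with columns ``treatment``,
    ``timepoint`` and the response.  With both factors at ≥2 levels this
    delegates to the two-way ANOVA with Bonferroni post-hoc; a plain
    two-group layout (one factor varying) uses Student's t.  Returns a dict
    with keys ``"anova"``/``"posthoc"`` or ``"t"``.
    """
    if response not in groups.columns:
        raise ValueError(f"missing response column {response!r}")
    n_treat = groups["treatment"].nunique() if "treatment" in groups else 1
    n_time = groups["timepoint"].nunique() if "timepoint" in groups else 1
    if n_treat >= 2 and n_time >= 2:
        anova, posthoc = two_way_anova_bonferroni(
            groups, response, "treatment", "timepoint"
        )
        return {"anova": anova, "posthoc": posthoc}
    factor = "treatment" if n_treat >= 2 else "timepoint"
    if groups[factor].nunique() != 2:
        raise ValueError("two-group comparison requires exactly 2 levels")
    lv1, lv2 = sorted(groups[factor].unique())
    res: TestResult = student_t(
        groups.loc[groups[factor] == lv1, response],
        groups.loc[groups[factor] == lv2, response],
    )
    return {"t": res, "levels": (lv1, lv2)}
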