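"""Longitudinal in-vivo readouts: site averaging and percent-change series.

Double-fold skin thickness (mm, averaged over two sites), blood perfusion
(instrument AU from the speckle-contrast ROI mean), body weight (g) and
transepidermal water loss (TEWL, g/m²/h, averaged over three sites) are
reduced to site-averaged series per animal, normalized to the 0 h baseline
as percent change, and summarized per (strain, treatment) group as
mean ± SEM.  Missing intermediate timepoints are carried as gaps, never
interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PARAMETERS = ("thickness_mm", "perfusion_AU", "weight_g", "tewl_g_m2_h")

#: Number of measurement sites per parameter in the reference protocol.
EXPECTED_SITES = {"thickness_mm": 2, "tewl_g_m2_h": 3, "perfusion_AU": 1, "weight_g": 1}


@dataclass(frozen=True)
class FunctionalSeries:
    """Site-averaged raw values of one parameter for one animal."""

    parameter: str
    times_h: np.ndarray
    values: np.ndarray
    animal_id: str
    strain: str
    treatment: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("times and values must be matching 1-D arrays")
        if 0.0 not in t:
            raise ValueError("series must include the 0 h baseline")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PercentSeries:
    """Percent change of a series relative to its 0 h baseline."""

    parameter: str
    times_h: np.ndarray
    pct_change: np.ndarray
    animal_id: str
    strain: str
    treatment: str


def site_average(replicate_measurements, expected_sites: int | None = None) -> float:
    """Arithmetic mean over measurement sites; warns on unexpected counts."""
    vals = np.asarray(replicate_measurements, dtype=float)
    if vals.size == 0:
        raise ValueError("site_average requires at least one measurement")
    if expected_sites is not None and vals.size != expected_sites:
        logger.warning(
            "expected %d site measurements, got %d", expected_sites, vals.size
        )
    return float(vals.mean())


def percent_change(series: FunctionalSeries) -> PercentSeries:
    """100 × (v_t − v_0) / v_0 against the 0 h baseline; exactly 0 at t = 0."""
    (i0,) = np.nonzero(series.times_h == 0.0)
    v0 = float(series.values[i0[0]])
    if v0 <= 0:
        raise ValueError("baseline value at 0 h must be positive")
    pct = 100.0 * (series.values - v0) / v0
    pct[i0[0]] = 0.0
    return PercentSeries(
        parameter=series.parameter, times_h=series.times_h, pct_change=pct,
        animal_id=series.animal_id, strain=series.strain, treatment=series.treatment,
    )


def group_course(
    series: list[PercentSeries] | list[FunctionalSeries],
    parameter: str,
    value_attr: str = "pct_change",
) -> pd.DataFrame:
    """Per-timepoint mean ± SEM by (strain, treatment).

    SEM is sample sd (n−1) divided by √n, where n counts animals contributing
    a value at that timepoint; single-animal groups report SEM 0 with a
    warning.
    """
    rows = []
    for s in series:
        if s.parameter != parameter:
            continue
        vals = getattr(s, value_attr, None)
        if vals is None:
            vals = s.values  # type: ignore[union-attr]
        for t, v in zip(s.times_h, vals):
            rows.append(
                {
                    "strain": s.strain, "treatment": s.treatment,
                    "time_h": float(t), "value": float(v), "animal_id": s.animal_id,
                }
            )
    if not rows:
        raise ValueError(f"no series found for parameter {parameter!r}")
    df = pd.DataFrame(rows)
    out = []
    for (strain, treatment, t), g in df.groupby(
        ["strain", "treatment", "time_h"], sort=True
    ):
        n = len(g)
        if n == 1:
            logger.warning(
                "single animal in group (%s, %s) at %g h; SEM reported as 0",
                strain, treatment, t,
            )
            sem = 0.0
        else:
            sem = float(g["value"].std(ddof=1) / np.sqrt(n))
        out.append(
            {
                "parameter": parameter, "strain": strain, "treatment": treatment,
                "time_h": t, "mean": float(g["value"].mean()), "sem": sem, "n": n,
            }
        )
    return pd.DataFrame(out)
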