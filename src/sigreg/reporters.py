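"""Promoter-reporter activities and dilution-corrected growth curves.

Two small quantifications that accompany the transcriptome work: luciferase
(lux) reporter luminescence normalised to culture density (OD730), and
batch-culture growth where dense cultures are diluted and the dilution must
be folded back into the optical-density record before rates are fitted.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd


def promoter_activity(luminescence: float, od730: float) -> float:
    """Luminescence per OD730 unit; od730 must be positive."""
    if not od730 > 0:
        raise ValueError(f"od730 must be > 0, got {od730}")
    if luminescence < 0:
        raise ValueError("luminescence cannot be negative")
    return luminescence / od730


def fold_induction(
    activity_stress: float,
    activity_standard: float,
    background: float = 0.0,
) -> float:
    """Ratio of stress to standard promoter activity.

    An empty-vector/background activity may be subtracted from both before
    division; it defaults to 0 because the control strain's background
    luminescence is negligible.
    """
    denom = activity_standard - background
    if not denom > 0:
        raise ValueError("standard activity (after background subtraction) must be > 0")
    return (activity_stress - background) / denom


def corrected_growth_curve(
    time_days: Sequence[float],
    od730_measured: Sequence[float],
    dilution_factor: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Fold dilutions back into a growth record.

    ``dilution_factor[t]`` is the dilution applied immediately before the
    measurement at ``time_days[t]`` (1 = none).  The corrected OD at t is
    the measured OD times the product of all dilution factors applied at or
    before t, i.e. the density the undiluted culture would have reached.
    """
    t = np.asarray(time_days, dtype=float)
    od = np.asarray(od730_measured, dtype=float)
    if dilution_factor is None:
        dil = np.ones_like(od)
    else:
        dil = np.asarray(dilution_factor, dtype=float)
    if t.shape != od.shape or od.shape != dil.shape:
        raise ValueError("time, OD and dilution arrays must have equal length")
    if (np.diff(t) <= 0).any():
        raise ValueError("time points must be strictly increasing")
    if (od <= 0).any():
        raise ValueError("measured OD730 must be positive")
    if (dil < 1).any():
        raise ValueError("dilution factors must be >= 1")
    return od * np.cumprod(dil)


def growth_rate(
    time_days: Sequence[float],
    corrected_od: Sequence[float],
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Exponential growth rate (day^-1) over a time window.

    Ordinary least-squares slope of ln(corrected OD) against time; requires
    at least three positive points inside the window.  A culture doubling
    daily yields ln 2 per day.
    """
    t = np.asarray(time_days, dtype=float)
    od = np.asarray(corrected_od, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, od = t[keep], od[keep]
    if t.size < 3:
        raise ValueError("growth-rate fit needs at least 3 points in the window")
    if (od <= 0).any():
        raise ValueError("corrected OD must be positive for a log-linear fit")
    slope, _intercept = np.polyfit(t, np.log(od), 1)
    return float(slope)


# --- tidy-table conveniences ----------------------------------------------

def activities_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add an ``activity`` column (luminescence / od730) to a tidy table with
    columns strain, condition, luminescence, od730."""
    out = measurements.copy()
    out["activity"] = [
        promoter_activity(l, o)
        for l, o in zip(out["luminescence"], out["od730"])
    ]
    return out


def corrected_curves_table(growth: pd.DataFrame) -> pd.DataFrame:
    """Add a ``corrected_od`` column per strain to a tidy table with columns
    strain, time_days, od730, dilution_factor (sorted by time within strain)."""
    parts = []
    for strain, sub in growth.groupby("strain", sort=False):
        sub = sub.sort_values("time_days").copy()
        sub["corrected_od"] = corrected_growth_curve(
            sub["time_days"], sub["od730"], sub["dilution_factor"]
        )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
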