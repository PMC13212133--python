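"""Nonparametric rest-activity rhythm metrics from 24-hour activity profiles.

M10 is the mean acceleration over the most active 10-hour window of the
hour-of-day profile, L5 the mean over the least active 5-hour window, and
relative amplitude RA = (M10 - L5) / (M10 + L5) summarises the day/night
contrast of the rest-activity cycle: RA near 1 means a strong rhythm, RA
near 0 a flattened one. Windows are searched circularly (they may wrap
across midnight). Participants more than 2 sample standard deviations
below the cohort mean RA form the "low RA" (disrupted-rhythm) group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RAMetrics",
    "RAGrouping",
    "compute_m10_l5",
    "relative_amplitude",
    "classify_low_ra",
    "profile_metrics",
    "metrics_table",
]

HOURS = 24
M10_WINDOW = 10
L5_WINDOW = 5


class InvalidProfileError(ValueError):
    """Activity profile is not 24 finite nonnegative hourly values."""


class UndefinedRAError(ValueError):
    """RA undefined: the profile is identically zero (M10 + L5 = 0)."""


@dataclass(frozen=True)
class RAMetrics:
    m10: float
    l5: float
    m10_start_hour: int
    l5_start_hour: int
    ra: float | None = None


@dataclass(frozen=True)
class RAGrouping:
    """Low/high RA split at cohort mean minus 2 sample SDs."""

    threshold: float
    labels: np.ndarray  # True where low RA
    mean_ra: float
    sd_ra: float


def _validate(hourly) -> np.ndarray:
    arr = np.asarray(hourly, dtype=float)
    if arr.shape != (HOURS,):
        raise InvalidProfileError(f"expected {HOURS} hourly values, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidProfileError("profile contains missing or non-finite values")
    if np.any(arr < 0):
        raise InvalidProfileError("acceleration values must be nonnegative")
    return arr


def _window_means(arr: np.ndarray, width: int) -> np.ndarray:
    """Means of all 24 circularly wrapped windows of the given width."""
    ext = np.concatenate([arr, arr[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width])[:HOURS] / width


def compute_m10_l5(hourly) -> RAMetrics:
    """Locate the most active 10-h and least active 5-h circular windows.

    Ties are broken by the smallest start hour. ``ra`` is left unset.
    """
    arr = _validate(hourly)
    w10 = _window_means(arr, M10_WINDOW)
    w5 = _window_means(arr, L5_WINDOW)
    # np.argmax/argmin return the first (smallest) index on ties
    i10 = int(np.argmax(np.round(w10, 12)))
    i5 = int(np.argmin(np.round(w5, 12)))
    return RAMetrics(m10=float(w10[i10]), l5=float(w5[i5]),
                     m10_start_hour=i10, l5_start_hour=i5)


def relative_amplitude(m10: float, l5: float) -> float:
    """RA = (M10 - L5) / (M10 + L5), in [0, 1]."""
    if m10 < 0 or l5 < 0:
        raise ValueError("window means must be nonnegative")
    if m10 < l5:
        raise ValueError(f"m10 ({m10}) must be >= l5 ({l5})")
    if m10 + l5 == 0:
        raise UndefinedRAError("all-zero activity: RA undefined")
    return (m10 - l5) / (m10 + l5)


def profile_metrics(hourly) -> RAMetrics:
    """M10/L5 search plus RA in one call."""
    m = compute_m10_l5(hourly)
    return RAMetrics(m10=m.m10, l5=m.l5, m10_start_hour=m.m10_start_hour,
                     l5_start_hour=m.l5_start_hour,
                     ra=relative_amplitude(m.m10, m.l5))


def classify_low_ra(ra_values) -> RAGrouping:
    """Label participants low RA when ra < mean - 2 * sample SD (strict)."""
    ra = np.asarray(ra_values, dtype=float)
    if ra.size < 2:
        raise ValueError("need at least 2 RA values to form a grouping")
    if not np.all(np.isfinite(ra)):
        raise ValueError("missing RA values")
    mean = float(np.mean(ra))
    sd = float(np.std(ra, ddof=1))
    threshold = mean - 2.0 * sd
    return RAGrouping(threshold=threshold, labels=ra < threshold,
                      mean_ra=mean, sd_ra=sd)


def matrix_metrics(arr: np.ndarray):
    """Vectorised circular window search over a (n, 24) profile matrix.

    Returns (m10, l5, m10_start, l5_start, ra) arrays; equivalent to
    calling :func:`profile_metrics` row by row.
    """
    if arr.ndim != 2 or arr.shape[1] != HOURS:
        raise InvalidProfileError(f"expected an (n, {HOURS}) matrix")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidProfileError("profiles contain missing or negative values")

    def windows(width):
        ext = np.concatenate([arr, arr[:, : width - 1]], axis=1)
        csum = np.concatenate([np.zeros((arr.shape[0], 1)),
                               np.cumsum(ext, axis=1)], axis=1)
        return (csum[:, width:] - csum[:, :-width])[:, :HOURS] / width

    w10, w5 = windows(M10_WINDOW), windows(L5_WINDOW)
    i10 = np.argmax(np.round(w10, 12), axis=1)
    i5 = np.argmin(np.round(w5, 12), axis=1)
    rows = np.arange(arr.shape[0])
    m10, l5 = w10[rows, i10], w5[rows, i5]
    denom = m10 + l5
    if np.any(denom == 0):
        raise UndefinedRAError("all-zero profile: RA undefined")
    return m10, l5, i10, i5, (m10 - l5) / denom


def metrics_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-participant metrics for a wide profile table.

    Parameters
    ----------
    profiles
        Columns ``participant_id`` and ``hour_0`` .. ``hour_23``.

    Returns
    -------
    DataFrame with participant_id, m10, l5, m10_start, l5_start, ra and
    ra_group ("low"/"high" from the 2-SD rule over this table).
    """
    hour_cols = [f"hour_{h}" for h in range(HOURS)]
    missing = [c for c in ["participant_id", *hour_cols] if c not in profiles.columns]
    if missing:
        raise InvalidProfileError(f"profile table missing columns: {missing}")
    arr = profiles[hour_cols].to_numpy(dtype=float)
    m10, l5, i10, i5, ra = matrix_metrics(arr)
    out = pd.DataFrame({"participant_id": profiles["participant_id"].to_numpy(),
                        "m10": m10, "l5": l5, "m10_start": i10,
                        "l5_start": i5, "ra": ra})
    grouping = classify_low_ra(out["ra"].to_numpy())
    out["ra_group"] = np.where(grouping.labels, "low", "high")
    return out
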