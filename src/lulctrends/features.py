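"""Per-pixel, per-year temporal statistics from 16-day composite series.

For each band (EVI, red, NIR, MIR) and each of six calendar windows
(12-month year, two 6-month halves, three 4-month thirds) the mean, sample
standard deviation, minimum, maximum and range are computed over reliable
composites only (reliability flag 3 removed first). A window with fewer
than three reliable composites is null. Feature tier drives the tiered
classifier routing: ``full`` (all windows valid), ``annual_only`` (only the
12-month window among those required), ``none`` (12-month window invalid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .scene import BAND_ORDER, N_COMPOSITES, UNRELIABLE

MIN_RELIABLE = 3
STAT_ORDER: tuple[str, ...] = ("mean", "sd", "min", "max", "range")

# Composite k (0-based) nominally starts on day-of-year 1 + 16k; its month
# (non-leap calendar) determines window membership.
_MONTH_END_DOY = np.cumsum([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
COMPOSITE_MONTH = np.searchsorted(_MONTH_END_DOY, 1 + 16 * np.arange(N_COMPOSITES), side="left") + 1

# Window -> calendar months covered. Order fixed: annual first.
WINDOW_MONTHS: dict[str, tuple[int, ...]] = {
    "Y": tuple(range(1, 13)),
    "H1": tuple(range(1, 7)),
    "H2": tuple(range(7, 13)),
    "T1": tuple(range(1, 5)),
    "T2": tuple(range(5, 9)),
    "T3": tuple(range(9, 13)),
}
WINDOW_ORDER: tuple[str, ...] = tuple(WINDOW_MONTHS)
WINDOW_COMPOSITES: dict[str, np.ndarray] = {
    w: np.flatnonzero(np.isin(COMPOSITE_MONTH, months))
    for w, months in WINDOW_MONTHS.items()
}

# Column layout: band-major, then window, then statistic -> 4*6*5 = 120.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{band}_{window}_{stat}"
    for band in BAND_ORDER
    for window in WINDOW_ORDER
    for stat in STAT_ORDER
)
N_FEATURES = len(FEATURE_NAMES)
# Columns belonging to the 12-month window only (the secondary model's input).
ANNUAL_FEATURE_IDX: np.ndarray = np.array(
    [i for i, n in enumerate(FEATURE_NAMES) if n.split("_")[1] == "Y"]
)


class Tier(IntEnum):
    NONE = 0
    ANNUAL_ONLY = 1
    FULL = 2


@dataclass(frozen=True)
class FeatureVector:
    """120 temporal statistics for one pixel-year, with validity and tier."""

    values: np.ndarray                  # (120,) float, NaN where window invalid
    window_valid: dict[str, bool]
    tier: Tier

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def window_statistics(
    values: np.ndarray, reliability_flags: np.ndarray, *,
    min_reliable: int = MIN_RELIABLE,
) -> dict[str, float] | None:
    """Five statistics over reliable composites of one window, or None.

    ``values`` and ``reliability_flags`` are aligned, one entry per composite
    in the window. Composites flagged 3 are removed; if fewer than
    ``min_reliable`` remain the window is null. sd uses the n-1 denominator.
    """
    values = np.asarray(values, dtype=float)
    reliability_flags = np.asarray(reliability_flags)
    if values.shape != reliability_flags.shape:
        raise ValueError(
            f"values {values.shape} and flags {reliability_flags.shape} differ in length"
        )
    good = values[reliability_flags != UNRELIABLE]
    if good.size < min_reliable:
        return None
    lo, hi = float(good.min()), float(good.max())
    return {
        "mean": float(good.mean()),
        "sd": float(good.std(ddof=1)),
        "min": lo,
        "max": hi,
        "range": hi - lo,
    }


def compute_feature_matrix(
    band_values: np.ndarray, reliability: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized features for many pixels in one year.

    Parameters
    ----------
    band_values : (23, 4, n) array of composite band values.
    reliability : (23, n) array of reliability flags.

    Returns
    -------
    (n, 120) float array with NaN in invalid windows, and an (n,) Tier array.
    """
    if band_values.shape[0] != N_COMPOSITES:
        raise ValueError(f"expected {N_COMPOSITES} composites, got {band_values.shape[0]}")
    if band_values.shape[1] != len(BAND_ORDER):
        raise ValueError(f"expected {len(BAND_ORDER)} bands, got {band_values.shape[1]}")
    n = band_values.shape[2]
    reliable = reliability != UNRELIABLE          # (23, n)
    masked = np.where(reliable[:, None, :], band_values.astype(float), np.nan)

    out = np.full((n, N_FEATURES), np.nan)
    valid_by_window = np.empty((len(WINDOW_ORDER), n), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        for wi, w in enumerate(WINDOW_ORDER):
            idx = WINDOW_COMPOSITES[w]
            count = reliable[idx].sum(axis=0)
            valid = count >= MIN_RELIABLE
            valid_by_window[wi] = valid
            sub = masked[idx]                     # (k, 4, n)
            mean = np.nanmean(sub, axis=0)
            sd = np.nanstd(sub, axis=0, ddof=1)
            mn = np.nanmin(sub, axis=0)
            mx = np.nanmax(sub, axis=0)
            stats = np.stack([mean, sd, mn, mx, mx - mn])   # (5, 4, n)
            stats[:, :, ~valid] = np.nan
            for bi in range(len(BAND_ORDER)):
                col0 = bi * len(WINDOW_ORDER) * len(STAT_ORDER) + wi * len(STAT_ORDER)
                out[:, col0:col0 + len(STAT_ORDER)] = stats[:, bi].T

    annual_valid = valid_by_window[WINDOW_ORDER.index("Y")]
    all_valid = valid_by_window.all(axis=0)
    tiers = np.where(all_valid, Tier.FULL,
                     np.where(annual_valid, Tier.ANNUAL_ONLY, Tier.NONE)).astype(np.int8)
    return out, tiers


def build_feature_vector(
    band_values: np.ndarray, reliability_flags: np.ndarray
) -> FeatureVector:
    """Features for a single pixel-year series.

    ``band_values`` is (23, 4) in band order EVI, red, NIR, MIR;
    ``reliability_flags`` is (23,).
    """
    band_values = np.asarray(band_values, dtype=float)
    reliability_flags = np.asarray(reliability_flags)
    if band_values.ndim != 2 or band_values.shape != (N_COMPOSITES, len(BAND_ORDER)):
        raise ValueError(
            f"expected band values of shape {(N_COMPOSITES, len(BAND_ORDER))}, "
            f"got {band_values.shape}"
        )
    if reliability_flags.shape != (N_COMPOSITES,):
        raise ValueError(f"expected {N_COMPOSITES} reliability flags")
    mat, tiers = compute_feature_matrix(
        band_values[:, :, None], reliability_flags[:, None]
    )
    reliable = reliability_flags != UNRELIABLE
    window_valid = {
        w: int(reliable[WINDOW_COMPOSITES[w]].sum()) >= MIN_RELIABLE
        for w in WINDOW_ORDER
    }
    return FeatureVector(values=mat[0], window_valid=window_valid, tier=Tier(int(tiers[0])))


def cube_year_features(cube, year_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Features for every pixel of one year of a CompositeCube.

    Returns an (n_pixels, 120) matrix (row-major pixel order) and tiers.
    """
    yb = cube.bands[year_index]                  # (23, 4, R, C)
    yr = cube.reliability[year_index]            # (23, R, C)
    n = yb.shape[2] * yb.shape[3]
    return compute_feature_matrix(yb.reshape(N_COMPOSITES, len(BAND_ORDER), n),
                                  yr.reshape(N_COMPOSITES, n))
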