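"""Multi-scale aggregation of municipality trend fits.

Rolls municipality net changes up to ecoregion, biome and country scales,
computes gain/loss partitions, hotspot tables with national shares, percent
changes and the gainer/loser municipality-size comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classes import TREND_CLASSES
from .trends import ALPHA

logger = logging.getLogger(__name__)

SCALES = ("country", "biome", "ecoregion", "municipality")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (printed style)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def net_change(area_first: float, area_last: float) -> float:
    """Net change: final-year area minus first-year area."""
    return area_last - area_first


def assign_unit(municipality_overlap_areas: dict[int, float]) -> int:
    """Unit with the greatest areal overlap; ties go to the lowest unit id."""
    if not municipality_overlap_areas:
        raise ValueError("no overlap areas supplied")
    if any(v < 0 for v in municipality_overlap_areas.values()):
        raise ValueError("overlap areas must be nonnegative")
    if all(v == 0 for v in municipality_overlap_areas.values()):
        raise ValueError("all overlap areas are zero")
    best = max(sorted(municipality_overlap_areas), key=municipality_overlap_areas.get)
    return best


def rollup(
    trend_fits: pd.DataFrame,
    unit_assignment: dict[int, int] | pd.Series | None,
    scale: str = "country",
) -> pd.DataFrame:
    """Sum fitted endpoint areas and nets per unit at the requested scale.

    All municipalities are included, not only significant ones. For
    ``scale="country"`` the assignment may be None (single unit 0);
    ``scale="municipality"`` is the identity rollup.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    df = trend_fits[trend_fits["estimable"]].copy()
    if scale == "country":
        df["unit"] = 0
    elif scale == "municipality":
        df["unit"] = df["municipality"]
    else:
        mapping = dict(unit_assignment) if unit_assignment is not None else {}
        missing = sorted(set(df["municipality"]) - set(mapping))
        if missing:
            raise ValueError(f"municipalities without a {scale} assignment: {missing}")
        df["unit"] = df["municipality"].map(mapping)

    rows = []
    for (unit, cls), grp in df.groupby(["unit", "cover_class"], sort=True):
        nets = grp["net_change"]
        rows.append({
            "scale": scale,
            "unit": unit,
            "cover_class": cls,
            "area_first_km2": float(grp["fitted_first"].sum()),
            "area_last_km2": float(grp["fitted_last"].sum()),
            "net_change_km2": float(nets.sum()),
            "total_gain_km2": float(nets[nets > 0].sum()),
            "total_loss_km2": float(-nets[nets < 0].sum()),
            "n_gaining": int((nets > 0).sum()),
            "n_losing": int((nets < 0).sum()),
            "n_municipalities": int(grp["municipality"].nunique()),
        })
    return pd.DataFrame.from_records(rows)


@dataclass(frozen=True)
class GainLossPartition:
    """Counts and summed areas of gaining vs losing municipalities."""

    cover_class: str
    n_total: int
    n_gain: int
    n_loss: int
    n_no_change: int
    gain_km2: float              # sum of positive nets
    loss_km2: float              # sum of |negative nets|
    pct_gain: int                # integer-rounded count percentages
    pct_loss: int
    significant_only: bool

    @property
    def net_km2(self) -> float:
        return self.gain_km2 - self.loss_km2


def gain_loss_partition(
    trend_fits: pd.DataFrame,
    cover_class: str,
    significant_only: bool = False,
    alpha: float = ALPHA,
) -> GainLossPartition:
    """Partition municipalities into gainers and losers for one class.

    Percentages are counts over all estimable municipalities of the class,
    rounded half-away-from-zero to integers. ``significant_only`` restricts
    the gain/loss counts and sums (but not the denominator) to fits with
    p <= alpha.
    """
    df = trend_fits[(trend_fits["cover_class"] == cover_class)
                    & trend_fits["estimable"]]
    n_total = len(df)
    sel = df[df["p_value"] <= alpha] if significant_only else df
    nets = sel["net_change"]
    n_gain = int((nets > 0).sum())
    n_loss = int((nets < 0).sum())
    return GainLossPartition(
        cover_class=cover_class,
        n_total=n_total,
        n_gain=n_gain,
        n_loss=n_loss,
        n_no_change=n_total - n_gain - n_loss,
        gain_km2=float(nets[nets > 0].sum()),
        loss_km2=float(-nets[nets < 0].sum()),
        pct_gain=round_half_away(100.0 * n_gain / n_total) if n_total else 0,
        pct_loss=round_half_away(100.0 * n_loss / n_total) if n_total else 0,
        significant_only=significant_only,
    )


@dataclass(frozen=True)
class HotspotTable:
    """Top-k municipalities by |net change| in one direction."""

    direction: str               # "gain" | "loss"
    cover_class: str
    table: pd.DataFrame          # municipality, net_change, r, p_value, pct_change
    national_total_km2: float    # summed |net| over ALL municipalities in direction
    share_pct: int               # integer-rounded top-k share of the national total


def percent_change(fitted_first: float, change: float) -> float | None:
    """Net change as a percentage of the first-year fitted baseline.

    A nonpositive baseline is undefined and reported as None.
    """
    if fitted_first <= 0:
        return None
    return 100.0 * change / fitted_first


def hotspots(
    trend_fits: pd.DataFrame,
    cover_class: str,
    k: int = 10,
    direction: str = "gain",
    significant_only: bool = False,
    alpha: float = ALPHA,
) -> HotspotTable:
    """Rank municipalities by |net change| (ties by municipality id) and
    report the top-k share of the national total in that direction.

    With ``significant_only`` both the ranking pool and the national total
    are restricted to significant fits.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    df = trend_fits[(trend_fits["cover_class"] == cover_class)
                    & trend_fits["estimable"]]
    if significant_only:
        df = df[df["p_value"] <= alpha]
    pool = df[df["net_change"] > 0] if direction == "gain" else df[df["net_change"] < 0]
    national = float(pool["net_change"].abs().sum())
    ranked = pool.assign(_mag=pool["net_change"].abs()).sort_values(
        ["_mag", "municipality"], ascending=[False, True]).drop(columns="_mag")
    if len(ranked) < k:
        logger.info("only %d municipalities in %s direction; table truncated from k=%d",
                    len(ranked), direction, k)
    top = ranked.head(k).copy()
    top["pct_change"] = [
        percent_change(f, c) for f, c in zip(top["fitted_first"], top["net_change"])
    ]
    top_sum = float(top["net_change"].abs().sum())
    share = round_half_away(100.0 * top_sum / national) if national > 0 else 0
    cols = ["municipality", "net_change", "r", "p_value", "fitted_first", "pct_change"]
    return HotspotTable(
        direction=direction,
        cover_class=cover_class,
        table=top[cols].reset_index(drop=True),
        national_total_km2=national,
        share_pct=share,
    )


@dataclass(frozen=True)
class SizeComparison:
    """Rank-sum comparison of gainer vs loser municipality sizes."""

    n_gainers: int
    n_losers: int
    mean_gainer_km2: float
    mean_loser_km2: float
    u_statistic: float
    z_statistic: float           # normal deviate (tie-corrected, no continuity)
    p_value: float
    method: str                  # "exact" | "asymptotic"


def compare_sizes(
    gainer_areas: np.ndarray, loser_areas: np.ndarray, exact_max_n: int = 12
) -> SizeComparison:
    """Two-sided rank-sum test on municipality areas of significant gainers
    vs losers.

    Exact enumeration when the combined sample is small (<= ``exact_max_n``)
    and tie-free; the tie-corrected normal approximation otherwise. Both the
    U statistic and the normal deviate z are reported.
    """
    x = np.asarray(gainer_areas, dtype=float)
    y = np.asarray(loser_areas, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)

    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (u1 - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0

    return SizeComparison(
        n_gainers=n1,
        n_losers=n2,
        mean_gainer_km2=float(x.mean()),
        mean_loser_km2=float(y.mean()),
        u_statistic=u1,
        z_statistic=z,
        p_value=float(res.pvalue),
        method=method,
    )


def change_report(
    trend_fits: pd.DataFrame,
    biome_of_municipality: dict[int, int] | None = None,
    ecoregion_of_municipality: dict[int, int] | None = None,
    k: int = 10,
    alpha: float = ALPHA,
) -> str:
    """Plain-text multi-scale summary of the change analysis."""
    lines = ["Land-cover change summary", "=" * 32]
    country = rollup(trend_fits, None, "country")
    lines.append("\nCountry scale (fitted endpoint areas, km^2):")
    for _, row in country.iterrows():
        lines.append(
            f"  {row['cover_class']:>18s}: {row['area_first_km2']:12.1f} -> "
            f"{row['area_last_km2']:12.1f}  net {row['net_change_km2']:+10.1f}"
        )
    for scale, mapping in (("biome", biome_of_municipality),
                           ("ecoregion", ecoregion_of_municipality)):
        if mapping is None:
            continue
        lines.append(f"\n{scale.capitalize()} scale net change (km^2):")
        for _, row in rollup(trend_fits, mapping, scale).iterrows():
            lines.append(f"  {scale} {row['unit']:>3} {row['cover_class']:>18s}: "
                         f"{row['net_change_km2']:+10.1f}")
    lines.append("\nMunicipality gain/loss partitions:")
    for cls in TREND_CLASSES:
        if not (trend_fits["cover_class"] == cls).any():
            continue
        p = gain_loss_partition(trend_fits, cls)
        lines.append(
            f"  {cls:>18s}: {p.pct_gain}% ({p.n_gain}) gained {p.gain_km2:.1f} km^2, "
            f"{p.pct_loss}% ({p.n_loss}) lost {p.loss_km2:.1f} km^2, "
            f"net {p.net_km2:+.1f} km^2"
        )
    if (trend_fits["cover_class"] == "woody").any():
        for direction in ("gain", "loss"):
            h = hotspots(trend_fits, "woody", k=k, direction=direction, alpha=alpha)
            if len(h.table):
                lines.append(f"\nTop {len(h.table)} woody {direction} municipalities "
                             f"({h.share_pct}% of national {direction}):")
                for _, r in h.table.iterrows():
                    pc = "n/a" if r["pct_change"] is None else f"{r['pct_change']:+.0f}%"
                    lines.append(f"  mun {int(r['municipality']):>4} "
                                 f"net {r['net_change']:+9.1f} km^2  R {r['r']:+.2f}  "
                                 f"p {r['p_value']:.3f}  change {pc}")
    return "\n".join(lines)
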