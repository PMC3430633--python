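"""Per-municipality class areas and year-trend regressions.

Annual five-class maps are summarized to per-municipality class areas
(km^2); municipality-years with more than 1% No-Data area are dropped;
each municipality x class series is fit by ordinary least squares against
year, with Pearson R, a two-sided p-value from the exact t-transform of R,
and net change taken from the fitted values at the endpoint years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classes import CLASS5_CODE, NODATA, TREND_CLASSES
from .classifier import AnnualMapStack
from .scene import LandscapePartition

FIRST_YEAR = 2001
LAST_YEAR = 2010
MIN_YEARS = 3
NODATA_THRESHOLD = 0.01
ALPHA = 0.05


@dataclass(frozen=True)
class AreaTable:
    """Per municipality x class x year areas plus No-Data bookkeeping."""

    areas: pd.DataFrame          # columns: municipality, cover_class, year, area_km2
    municipality_km2: pd.Series  # total mapped area per municipality
    nodata_fraction: pd.DataFrame  # columns: municipality, year, nodata_fraction
    cell_size_m: float


def municipality_class_areas(
    map_stack: AnnualMapStack,
    partition: LandscapePartition,
    cell_size_m: float | None = None,
    cover_classes: tuple[str, ...] = tuple(CLASS5_CODE),
) -> AreaTable:
    """Pixel counts x cell area per municipality, class and year."""
    if map_stack.codes.shape[1:] != (partition.rows, partition.cols):
        raise ValueError("map stack and partition grids differ")
    cell_size_m = partition.cell_size_m if cell_size_m is None else cell_size_m
    cell_km2 = (cell_size_m / 1000.0) ** 2

    mun_flat = partition.municipality_of.ravel()
    mun_ids = partition.municipality_ids
    recs = []
    for m in mun_ids:
        sel = mun_flat == m
        for yi, year in enumerate(map_stack.years):
            codes = map_stack.codes[yi].ravel()[sel]
            for cls in cover_classes:
                recs.append({
                    "municipality": int(m),
                    "cover_class": cls,
                    "year": int(year),
                    "area_km2": float((codes == CLASS5_CODE[cls]).sum() * cell_km2),
                })
    totals = pd.Series(
        {int(m): float((mun_flat == m).sum() * cell_km2) for m in mun_ids},
        name="municipality_km2",
    )
    return AreaTable(
        areas=pd.DataFrame.from_records(recs),
        municipality_km2=totals,
        nodata_fraction=map_stack.nodata_fraction.copy(),
        cell_size_m=cell_size_m,
    )


def filter_years(
    area_table: AreaTable, nodata_threshold: float = NODATA_THRESHOLD
) -> tuple[AreaTable, pd.DataFrame]:
    """Drop municipality-years whose No-Data fraction exceeds the threshold.

    The rule is strictly "more than": a fraction exactly at the threshold is
    retained. Returns the filtered table plus a frame of dropped
    municipality-years. Municipalities left with fewer than MIN_YEARS usable
    years are later flagged unestimable by ``fit_trend``.
    """
    nd = area_table.nodata_fraction
    bad = nd[nd["nodata_fraction"] > nodata_threshold][["municipality", "year"]]
    if bad.empty:
        return area_table, bad
    merged = area_table.areas.merge(bad.assign(_drop=True),
                                    on=["municipality", "year"], how="left")
    kept = merged[merged["_drop"].isna()].drop(columns="_drop").reset_index(drop=True)
    return AreaTable(
        areas=kept,
        municipality_km2=area_table.municipality_km2,
        nodata_fraction=nd,
        cell_size_m=area_table.cell_size_m,
    ), bad.reset_index(drop=True)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of one municipality x class area series against year."""

    municipality: int
    cover_class: str
    slope: float                 # km^2 / yr
    intercept: float             # km^2 at FIRST_YEAR
    r: float
    p_value: float
    n_years: int
    fitted_first: float          # fitted area at FIRST_YEAR (km^2)
    fitted_last: float           # fitted area at LAST_YEAR (km^2)
    raw_change: float            # last observed minus first observed (diagnostic)
    estimable: bool = True

    @property
    def net_change(self) -> float:
        return self.fitted_last - self.fitted_first

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.estimable and self.p_value <= alpha


def fit_trend(
    areas: np.ndarray,
    years: np.ndarray,
    municipality: int = 0,
    cover_class: str = "",
) -> TrendFit:
    """OLS of area on year index with Pearson R and its exact-t p-value.

    Fitted endpoints are evaluated at FIRST_YEAR and LAST_YEAR regardless of
    dropped interior years. Zero variance in area is the no-change
    convention: slope 0, R 0, p 1. Fewer than MIN_YEARS points is
    unestimable.
    """
    areas = np.asarray(areas, dtype=float)
    years = np.asarray(years, dtype=int)
    if areas.shape != years.shape:
        raise ValueError("areas and years differ in length")
    n = areas.size
    if n < MIN_YEARS:
        return TrendFit(municipality, cover_class, np.nan, np.nan, np.nan, np.nan,
                        n, np.nan, np.nan, np.nan, estimable=False)
    x = (years - FIRST_YEAR).astype(float)
    order = np.argsort(years)
    first_obs, last_obs = areas[order[0]], areas[order[-1]]
    if np.ptp(areas) == 0.0:
        a = float(areas[0])
        return TrendFit(municipality, cover_class, 0.0, a, 0.0, 1.0, n,
                        a, a, float(last_obs - first_obs))
    res = stats.linregress(x, areas)
    f_first = res.intercept  # x = 0 at FIRST_YEAR
    f_last = res.intercept + res.slope * (LAST_YEAR - FIRST_YEAR)
    return TrendFit(
        municipality=municipality,
        cover_class=cover_class,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_years=n,
        fitted_first=float(f_first),
        fitted_last=float(f_last),
        raw_change=float(last_obs - first_obs),
    )


def fit_all_trends(
    area_table: AreaTable, cover_classes: tuple[str, ...] = TREND_CLASSES
) -> list[TrendFit]:
    """One TrendFit per municipality x analysed class."""
    fits = []
    df = area_table.areas
    for (m, cls), grp in df[df["cover_class"].isin(cover_classes)].groupby(
            ["municipality", "cover_class"], sort=True):
        fits.append(fit_trend(grp["area_km2"].to_numpy(), grp["year"].to_numpy(),
                              municipality=int(m), cover_class=str(cls)))
    return fits


def classify_municipality(fit: TrendFit, alpha: float = ALPHA) -> str:
    """gain / loss / no_change / unestimable label for one fit.

    The significant variants additionally require p <= alpha (inclusive).
    """
    if not fit.estimable:
        return "unestimable"
    if fit.net_change > 0:
        return "significant_gain" if fit.p_value <= alpha else "gain"
    if fit.net_change < 0:
        return "significant_loss" if fit.p_value <= alpha else "loss"
    return "no_change"


def fits_to_frame(fits: list[TrendFit], alpha: float = ALPHA) -> pd.DataFrame:
    """Tabulate TrendFits for the aggregation stage."""
    return pd.DataFrame.from_records([
        {
            "municipality": f.municipality,
            "cover_class": f.cover_class,
            "slope": f.slope,
            "intercept": f.intercept,
            "r": f.r,
            "p_value": f.p_value,
            "n_years": f.n_years,
            "fitted_first": f.fitted_first,
            "fitted_last": f.fitted_last,
            "net_change": f.net_change if f.estimable else np.nan,
            "raw_change": f.raw_change,
            "estimable": f.estimable,
            "significant": f.significant(alpha),
        }
        for f in fits
    ])
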