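"""Synthetic landscape, cover-trajectory, composite-cube and reference-sample
generation.

Everything downstream of raw imagery is exercised against scenes produced
here: a nearest-seed municipality tessellation, per-municipality cover
trajectories with prescribed linear trends, 16-day composite cubes with
class-specific seasonal signatures plus reliability gaps, and paired
interpreter percent-cover samples with a minimum-spacing constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import CATEGORY_ORDER, CLASS8_CODE, CLASS8_ORDER, CODE_CLASS8

DEFAULT_CELL_SIZE_M = 231.7
N_COMPOSITES = 23
BAND_ORDER: tuple[str, ...] = ("EVI", "red", "NIR", "MIR")
RELIABLE = 0
UNRELIABLE = 3
FIRST_YEAR = 2001

# Canonical percent-cover composition of a pure footprint of each class,
# chosen so the class-assignment rules recover the class exactly.
CANONICAL_COMPOSITION: dict[str, dict[str, float]] = {
    "woody": {"woody": 90.0, "herb": 10.0},
    "herb": {"herb": 90.0, "woody": 10.0},
    "ag": {"ag": 85.0, "herb": 15.0},
    "plant": {"plant": 85.0, "herb": 15.0},
    "built": {"built": 85.0, "bare": 15.0},
    "bare": {"bare": 85.0, "herb": 15.0},
    "water": {"water": 95.0, "herb": 5.0},
    "mixed_woody": {"woody": 50.0, "herb": 30.0, "ag": 20.0},
}


@dataclass(frozen=True)
class LandscapePartition:
    """A grid partitioned into municipalities nested in biomes/ecoregions."""

    rows: int
    cols: int
    cell_size_m: float
    municipality_of: np.ndarray          # (rows, cols) int municipality ids
    biome_of_municipality: dict[int, int]
    ecoregion_of_municipality: dict[int, int]

    @property
    def municipality_ids(self) -> np.ndarray:
        return np.unique(self.municipality_of)

    @property
    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.municipality_of, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def municipality_pixels(self, mun_id: int) -> np.ndarray:
        """Flat pixel indices belonging to a municipality."""
        return np.flatnonzero(self.municipality_of.ravel() == mun_id)


@dataclass(frozen=True)
class CoverTrendSpec:
    """Initial composition and prescribed linear trends for one municipality.

    ``proportions`` give initial class fractions (must sum to 1);
    ``slopes_px_per_year`` give prescribed trends in pixels per year and
    should sum to ~0 — any residual is absorbed by the largest initial class.
    """

    proportions: dict[str, float]
    slopes_px_per_year: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for cls in list(self.proportions) + list(self.slopes_px_per_year):
            if cls not in CLASS8_ORDER:
                raise ValueError(f"unknown cover class {cls!r}")


@dataclass(frozen=True)
class TrueCoverSeries:
    """Per-pixel, per-year true class labels (eight-category codes)."""

    labels: np.ndarray                    # (n_years, rows, cols) int8 codes
    years: tuple[int, ...]
    clipped: tuple[tuple[int, str, int], ...] = ()   # (mun, class, year) where a slope hit zero

    @property
    def n_years(self) -> int:
        return len(self.years)

    def class_counts(self, partition: LandscapePartition, mun_id: int) -> dict[str, np.ndarray]:
        """Realized per-year pixel counts per class for one municipality."""
        mask = partition.municipality_of == mun_id
        out = {}
        for name, code in CLASS8_CODE.items():
            out[name] = (self.labels[:, mask] == code).sum(axis=1)
        return out


@dataclass(frozen=True)
class PhenologySpec:
    """Seasonal band signatures, observation noise and cloud probability.

    ``curves`` maps each class name to a (4, 23) array of per-composite band
    means in ``BAND_ORDER``; ``noise_scale`` is the s.d. of additive Gaussian
    observation noise; ``cloud_prob`` is the per-composite probability of an
    unreliable (value 3) flag.
    """

    curves: dict[str, np.ndarray]
    noise_scale: float = 0.02
    cloud_prob: float = 0.05

    def __post_init__(self) -> None:
        for name, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (len(BAND_ORDER), N_COMPOSITES):
                raise ValueError(
                    f"curve for {name!r} has shape {c.shape}, expected "
                    f"{(len(BAND_ORDER), N_COMPOSITES)}"
                )
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")


@dataclass(frozen=True)
class CompositeCube:
    """Per-pixel 16-day composite band values and reliability flags."""

    bands: np.ndarray        # (n_years, 23, 4, rows, cols) float32
    reliability: np.ndarray  # (n_years, 23, rows, cols) int8 {0, 3}
    years: tuple[int, ...]

    @property
    def rows(self) -> int:
        return self.bands.shape[3]

    @property
    def cols(self) -> int:
        return self.bands.shape[4]


def default_phenology(noise_scale: float = 0.02, cloud_prob: float = 0.05) -> PhenologySpec:
    """Distinct, physically plausible seasonal signatures for all 8 classes."""
    t = 2.0 * np.pi * np.arange(N_COMPOSITES) / N_COMPOSITES
    s1, s2 = np.sin(t), np.sin(2.0 * t)

    def curve(evi, red, nir, mir):
        return np.vstack([evi, red, nir, mir])

    flat = np.ones(N_COMPOSITES)
    curves = {
        "woody": curve(0.75 + 0.03 * s1, 0.05 * flat, 0.35 * flat, 0.12 * flat),
        "mixed_woody": curve(0.60 + 0.08 * s1, 0.07 * flat, 0.32 * flat, 0.16 * flat),
        "plant": curve(0.65 + 0.05 * s1, 0.06 * flat, 0.40 * flat, 0.10 * flat),
        "herb": curve(0.45 + 0.15 * s1, 0.10 * flat, 0.28 * flat, 0.22 * flat),
        "ag": curve(0.40 + 0.22 * s2, 0.12 + 0.03 * s2, 0.26 * flat, 0.27 * flat),
        "built": curve(0.18 * flat, 0.18 * flat, 0.22 * flat, 0.30 * flat),
        "bare": curve(0.10 * flat, 0.26 * flat, 0.30 * flat, 0.36 * flat),
        "water": curve(0.02 * flat, 0.04 * flat, 0.03 * flat, 0.02 * flat),
    }
    return PhenologySpec(curves=curves, noise_scale=noise_scale, cloud_prob=cloud_prob)


def _split_by_rank(order: np.ndarray, n_groups: int) -> np.ndarray:
    """Assign items (given in rank order) to n_groups near-equal groups."""
    n = order.size
    groups = np.zeros(n, dtype=int)
    bounds = np.linspace(0, n, n_groups + 1).round().astype(int)
    for g in range(n_groups):
        groups[order[bounds[g]:bounds[g + 1]]] = g
    return groups


def generate_landscape(
    rows: int,
    cols: int,
    n_municipalities: int,
    n_biomes: int = 1,
    n_ecoregions: int = 1,
    seed: int = 0,
    cell_size_m: float = DEFAULT_CELL_SIZE_M,
) -> LandscapePartition:
    """Nearest-seed tessellation into municipalities, grouped into biomes and
    ecoregions by centroid rank so every unit is non-empty.

    Ties in seed distance go to the lowest municipality id. Deterministic for
    a fixed seed.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if n_municipalities < 1 or n_biomes < 1 or n_ecoregions < 1:
        raise ValueError("unit counts must be >= 1")
    if n_municipalities > rows * cols:
        raise ValueError(
            f"cannot place {n_municipalities} municipalities on a "
            f"{rows}x{cols} grid"
        )
    if n_biomes > n_municipalities or n_ecoregions > n_municipalities:
        raise ValueError("cannot have more biomes/ecoregions than municipalities")

    rng = np.random.default_rng(seed)
    seeds = rng.choice(rows * cols, size=n_municipalities, replace=False)
    sr, sc = np.divmod(seeds, cols)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # squared distance to every seed; argmin returns the first (lowest id) tie
    d2 = (rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2
    mun = np.argmin(d2, axis=2).astype(np.int32)

    # group municipalities into biomes/ecoregions by centroid rank along two
    # different axes so the groupings are spatially coherent but distinct
    cent_r = np.array([rr[mun == m].mean() for m in range(n_municipalities)])
    cent_c = np.array([cc[mun == m].mean() for m in range(n_municipalities)])
    biome_groups = _split_by_rank(np.argsort(cent_c + 1e-9 * cent_r, kind="stable"), n_biomes)
    eco_groups = _split_by_rank(np.argsort(cent_r + 1e-9 * cent_c, kind="stable"), n_ecoregions)

    return LandscapePartition(
        rows=rows,
        cols=cols,
        cell_size_m=cell_size_m,
        municipality_of=mun,
        biome_of_municipality={m: int(biome_groups[m]) for m in range(n_municipalities)},
        ecoregion_of_municipality={m: int(eco_groups[m]) for m in range(n_municipalities)},
    )


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` matching `ideal` within <1 each."""
    ideal = np.maximum(ideal, 0.0)
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = ideal - np.floor(ideal)
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(ideal - np.floor(ideal), kind="stable")
        take = -short
        for i in order:
            if take == 0:
                break
            if base[i] > 0:
                base[i] -= 1
                take -= 1
    return base


def generate_trajectories(
    partition: LandscapePartition,
    trend_spec: dict[int, CoverTrendSpec] | CoverTrendSpec,
    years: int = 10,
    seed: int = 0,
    first_year: int = FIRST_YEAR,
) -> TrueCoverSeries:
    """Per-municipality label maps whose realized class areas track the
    prescribed linear trajectories (within discretization error).

    Cover-change pixels are flipped at municipality-random locations.
    Slopes that would drive a class area negative are clipped at zero and
    reported in ``TrueCoverSeries.clipped``.
    """
    rng = np.random.default_rng(seed)
    mun_ids = partition.municipality_ids
    if isinstance(trend_spec, CoverTrendSpec):
        trend_spec = {int(m): trend_spec for m in mun_ids}
    missing = [int(m) for m in mun_ids if int(m) not in trend_spec]
    if missing:
        raise ValueError(f"no trend spec for municipalities {missing}")

    labels = np.zeros((years, partition.rows, partition.cols), dtype=np.int8)
    flat = labels.reshape(years, -1)
    clipped: list[tuple[int, str, int]] = []

    for m in mun_ids:
        spec = trend_spec[int(m)]
        pix = partition.municipality_pixels(int(m))
        n = pix.size
        class_names = [c for c in CLASS8_ORDER if spec.proportions.get(c, 0.0) > 0
                       or spec.slopes_px_per_year.get(c, 0.0) != 0.0]
        props = np.array([spec.proportions.get(c, 0.0) for c in class_names])
        slopes = np.array([spec.slopes_px_per_year.get(c, 0.0) for c in class_names])
        ideal0 = props * n

        # year-0 assignment at random locations
        counts0 = _largest_remainder(ideal0, n)
        perm = rng.permutation(pix)
        codes = np.repeat([CLASS8_CODE[c] for c in class_names], counts0)
        flat[0, perm] = codes

        prev = flat[0, pix].copy()
        for t in range(1, years):
            ideal = ideal0 + slopes * t
            for i, c in enumerate(class_names):
                if ideal[i] < 0:
                    clipped.append((int(m), c, first_year + t))
            counts = _largest_remainder(ideal, n)
            cur = prev.copy()
            have = {CLASS8_CODE[c]: (cur == CLASS8_CODE[c]).nonzero()[0]
                    for c in class_names}
            donors: list[int] = []
            for i, c in enumerate(class_names):
                code = CLASS8_CODE[c]
                excess = have[code].size - counts[i]
                if excess > 0:
                    give = rng.choice(have[code], size=excess, replace=False)
                    donors.extend(give.tolist())
            donors_arr = rng.permutation(np.array(donors, dtype=int))
            pos = 0
            for i, c in enumerate(class_names):
                code = CLASS8_CODE[c]
                deficit = counts[i] - have[code].size
                if deficit > 0:
                    take = donors_arr[pos:pos + deficit]
                    cur[take] = code
                    pos += deficit
            flat[t, pix] = cur
            prev = cur

    return TrueCoverSeries(
        labels=labels,
        years=tuple(first_year + t for t in range(years)),
        clipped=tuple(clipped),
    )


def simulate_composites(
    true_cover: TrueCoverSeries,
    phenology_spec: PhenologySpec,
    seed: int = 0,
) -> CompositeCube:
    """Render 23 composites/year x 4 bands from class signatures, with
    additive Gaussian noise and Bernoulli cloud (reliability 3) flags.
    """
    present = np.unique(true_cover.labels)
    for code in present:
        name = CODE_CLASS8.get(int(code))
        if name is None or name not in phenology_spec.curves:
            raise ValueError(
                f"phenology spec missing class {name or int(code)!r} present in scene"
            )
    rng = np.random.default_rng(seed)
    n_years, rows, cols = true_cover.labels.shape

    # lookup: code -> (4, 23) curve; codes start at 1
    max_code = int(present.max())
    lut = np.zeros((max_code + 1, len(BAND_ORDER), N_COMPOSITES), dtype=np.float32)
    for code in present:
        lut[int(code)] = phenology_spec.curves[CODE_CLASS8[int(code)]]

    # bands[y, k, b, r, c]
    bands = lut[true_cover.labels]                       # (Y, R, C, 4, 23)
    bands = np.moveaxis(bands, (3, 4), (2, 1)).copy()    # (Y, 23, 4, R, C)
    if phenology_spec.noise_scale > 0:
        bands += rng.normal(0.0, phenology_spec.noise_scale, size=bands.shape).astype(np.float32)
    # clamp to physically plausible ranges: EVI in [-0.2, 1], reflectance in [0, 1]
    np.clip(bands[:, :, 0], -0.2, 1.0, out=bands[:, :, 0])
    np.clip(bands[:, :, 1:], 0.0, 1.0, out=bands[:, :, 1:])

    if phenology_spec.cloud_prob >= 1.0:
        rel = np.full((n_years, N_COMPOSITES, rows, cols), UNRELIABLE, dtype=np.int8)
    elif phenology_spec.cloud_prob <= 0.0:
        rel = np.full((n_years, N_COMPOSITES, rows, cols), RELIABLE, dtype=np.int8)
    else:
        cloudy = rng.random((n_years, N_COMPOSITES, rows, cols)) < phenology_spec.cloud_prob
        rel = np.where(cloudy, UNRELIABLE, RELIABLE).astype(np.int8)

    return CompositeCube(bands=bands.astype(np.float32), reliability=rel,
                         years=true_cover.years)


@dataclass(frozen=True)
class SampleRecord:
    """A reference footprint with two interpreters' percent-cover estimates."""

    sample_id: int
    row: int
    col: int
    year: int
    true_class8: str
    interp_a: dict[str, float]
    interp_b: dict[str, float]
    year_a: int
    year_b: int

    @property
    def true_composition(self) -> dict[str, float]:
        return dict(CANONICAL_COMPOSITION[self.true_class8])


def _perturb(comp: dict[str, float], noise: float, rng: np.random.Generator) -> dict[str, float]:
    if noise <= 0:
        return {c: comp.get(c, 0.0) for c in CATEGORY_ORDER}
    vals = np.array([comp.get(c, 0.0) for c in CATEGORY_ORDER])
    jitter = rng.normal(0.0, noise, size=vals.size)
    vals = np.maximum(vals + np.where(vals > 0, jitter, 0.0), 0.0)
    vals = vals / vals.sum() * 100.0
    return dict(zip(CATEGORY_ORDER, vals.tolist()))


def simulate_reference_samples(
    true_cover: TrueCoverSeries,
    partition: LandscapePartition,
    n_samples: int,
    min_spacing_m: float = 1000.0,
    interpreter_noise: float = 2.0,
    disagreement_rate: float = 0.05,
    seed: int = 0,
    stratified_fraction: float = 0.5,
    max_attempts_per_sample: int = 200,
) -> list[SampleRecord]:
    """Place reference footprints no closer than ``min_spacing_m`` apart and
    attach two interpreters' percent-cover vectors.

    Half of the samples (``stratified_fraction``) are stratified by cover
    class, the rest placed at random. At ``disagreement_rate``, interpreter B
    reports a different majority cover, forcing expert resolution downstream.
    """
    if n_samples == 0:
        return []
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = partition.rows, partition.cols
    cell = partition.cell_size_m
    min_d2 = (min_spacing_m / cell) ** 2

    n_strat = int(round(stratified_fraction * n_samples))
    placed_rc: list[tuple[int, int]] = []
    records: list[SampleRecord] = []

    # pixels per class in year 0 for the stratified draw
    year0 = true_cover.labels[0]
    class_pixels = {
        name: np.argwhere(year0 == code)
        for name, code in CLASS8_CODE.items()
        if (year0 == code).any()
    }
    strata = sorted(class_pixels)

    def far_enough(r: int, c: int) -> bool:
        return all((r - pr) ** 2 + (c - pc) ** 2 >= min_d2 for pr, pc in placed_rc)

    attempts_budget = max_attempts_per_sample * n_samples
    attempts = 0
    for i in range(n_samples):
        stratified = i < n_strat and strata
        while True:
            attempts += 1
            if attempts > attempts_budget:
                raise RuntimeError(
                    f"could not place {n_samples} samples at spacing "
                    f">= {min_spacing_m} m after {attempts - 1} attempts"
                )
            if stratified:
                cls = strata[i % len(strata)]
                px = class_pixels[cls]
                r, c = px[rng.integers(px.shape[0])]
            else:
                r = rng.integers(rows)
                c = rng.integers(cols)
            if far_enough(int(r), int(c)):
                break
        r, c = int(r), int(c)
        placed_rc.append((r, c))
        year_idx = int(rng.integers(true_cover.n_years))
        year = true_cover.years[year_idx]
        true_cls = CODE_CLASS8[int(true_cover.labels[year_idx, r, c])]
        truth = CANONICAL_COMPOSITION[true_cls]

        interp_a = _perturb(truth, interpreter_noise, rng)
        if rng.random() < disagreement_rate:
            # a disagreement must differ in majority cover, not just class
            true_major = max(CATEGORY_ORDER, key=lambda cat: truth.get(cat, 0.0))
            other = [
                c8 for c8, comp in CANONICAL_COMPOSITION.items()
                if max(CATEGORY_ORDER, key=lambda cat: comp.get(cat, 0.0)) != true_major
            ]
            wrong = other[int(rng.integers(len(other)))]
            interp_b = _perturb(CANONICAL_COMPOSITION[wrong], interpreter_noise, rng)
        else:
            interp_b = _perturb(truth, interpreter_noise, rng)

        records.append(SampleRecord(
            sample_id=i, row=r, col=c, year=int(year), true_class8=true_cls,
            interp_a=interp_a, interp_b=interp_b,
            year_a=int(year), year_b=int(year),
        ))
    return records
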