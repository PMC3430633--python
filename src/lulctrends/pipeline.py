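"""End-to-end wiring: scene -> consensus samples -> features -> per-biome
classifiers -> annual maps -> areas -> trends.

Used by the CLI and by full-pipeline tests; each stage remains individually
callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import (
    AccuracyReport,
    AnnualMapStack,
    ClassifierPair,
    RFConfig,
    build_annual_maps,
    oob_accuracy,
    train_biome_classifier,
)
from .features import N_COMPOSITES, Tier, compute_feature_matrix
from .samples import ConsensusSample, SampleInterpretation, consensus
from .scene import (
    BAND_ORDER,
    CompositeCube,
    LandscapePartition,
    SampleRecord,
)
from .trends import AreaTable, filter_years, fit_all_trends, fits_to_frame, municipality_class_areas


def label_samples(records: list[SampleRecord]) -> list[ConsensusSample]:
    """Consensus-label simulated sample pairs; the true composition acts as
    the expert resolution when interpreters disagree."""
    out = []
    for rec in records:
        a = SampleInterpretation(rec.sample_id, "A", rec.interp_a, rec.year_a)
        b = SampleInterpretation(rec.sample_id, "B", rec.interp_b, rec.year_b)
        expert = SampleInterpretation(rec.sample_id, "expert",
                                      rec.true_composition, rec.year)
        cs = consensus(a, b, expert_resolution=expert)
        if cs is not None:
            out.append(cs)
    return out


def pair_interpretations(
    interps: list[SampleInterpretation],
) -> list[tuple[SampleInterpretation, SampleInterpretation]]:
    """Group a flat interpretation list (e.g. from CSV) into per-sample pairs."""
    by_id: dict[int, list[SampleInterpretation]] = {}
    for it in interps:
        by_id.setdefault(it.sample_id, []).append(it)
    pairs = []
    for sid in sorted(by_id):
        group = by_id[sid]
        if len(group) != 2:
            raise ValueError(f"sample {sid} has {len(group)} interpretations, expected 2")
        pairs.append((group[0], group[1]))
    return pairs


def sample_features(
    cube: CompositeCube,
    records: list[SampleRecord],
    labeled: list[ConsensusSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature matrix for labeled samples, extracted at each sample's pixel
    for its image year.

    Returns (sample_ids, X, tiers, y_class8) for assigned samples only.
    """
    rec_by_id = {r.sample_id: r for r in records}
    year_index = {y: i for i, y in enumerate(cube.years)}
    ids, series_vals, series_rel, ys = [], [], [], []
    for cs in labeled:
        if cs.class8 is None:
            continue
        rec = rec_by_id[cs.sample_id]
        yi = year_index[cs.year]
        series_vals.append(cube.bands[yi, :, :, rec.row, rec.col])
        series_rel.append(cube.reliability[yi, :, rec.row, rec.col])
        ids.append(cs.sample_id)
        ys.append(cs.class8)
    if not ids:
        return (np.empty(0, dtype=int), np.empty((0, 0)), np.empty(0, dtype=np.int8),
                np.empty(0, dtype=object))
    vals = np.stack(series_vals, axis=-1)          # (23, 4, n)
    rel = np.stack(series_rel, axis=-1)            # (23, n)
    X, tiers = compute_feature_matrix(vals, rel)
    return np.asarray(ids), X, tiers, np.asarray(ys, dtype=object)


def train_all_biomes(
    partition: LandscapePartition,
    records: list[SampleRecord],
    sample_ids: np.ndarray,
    X: np.ndarray,
    tiers: np.ndarray,
    y: np.ndarray,
    config: RFConfig | None = None,
    seed: int = 0,
    outlier_threshold: float = 10.0,
) -> tuple[dict[int, ClassifierPair], list[AccuracyReport]]:
    """Train one ClassifierPair per biome from tier=full samples located in
    that biome, and compute its OOB accuracy report."""
    rec_by_id = {r.sample_id: r for r in records}
    biome_of = np.array([
        partition.biome_of_municipality[
            int(partition.municipality_of[rec_by_id[int(s)].row, rec_by_id[int(s)].col])
        ]
        for s in sample_ids
    ])
    usable = tiers == Tier.FULL
    pairs: dict[int, ClassifierPair] = {}
    reports: list[AccuracyReport] = []
    for b in sorted(set(biome_of.tolist())):
        sel = usable & (biome_of == b)
        if sel.sum() == 0:
            raise ValueError(f"no usable training samples in biome {b}")
        pair = train_biome_classifier(
            sample_ids[sel], X[sel], y[sel], biome_id=int(b),
            config=config, seed=seed, outlier_threshold=outlier_threshold,
        )
        pairs[int(b)] = pair
        kept = np.isin(sample_ids[sel], pair.training_sample_ids)
        reports.append(oob_accuracy(pair, y[sel][kept]))
    return pairs, reports


@dataclass
class PipelineResult:
    maps: AnnualMapStack
    area_table: AreaTable
    dropped_years: pd.DataFrame
    trend_fits: pd.DataFrame
    classifiers: dict[int, ClassifierPair]
    accuracy_reports: list[AccuracyReport]


def run_pipeline(
    partition: LandscapePartition,
    cube: CompositeCube,
    records: list[SampleRecord],
    config: RFConfig | None = None,
    seed: int = 0,
    nodata_threshold: float = 0.01,
    alpha: float = 0.05,
) -> PipelineResult:
    """Full chain from cube + samples to trend fits."""
    labeled = label_samples(records)
    ids, X, tiers, y = sample_features(cube, records, labeled)
    classifiers, reports = train_all_biomes(
        partition, records, ids, X, tiers, y, config=config, seed=seed)
    maps = build_annual_maps(cube, partition, classifiers)
    table = municipality_class_areas(maps, partition)
    filtered, dropped = filter_years(table, nodata_threshold)
    fits = fits_to_frame(fit_all_trends(filtered), alpha=alpha)
    return PipelineResult(
        maps=maps,
        area_table=filtered,
        dropped_years=dropped,
        trend_fits=fits,
        classifiers=classifiers,
        accuracy_reports=reports,
    )
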