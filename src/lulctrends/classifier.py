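"""Per-biome tiered ensemble classification with proximity-outlier removal,
out-of-bag accuracy assessment, and annual map construction.

Each biome gets a pair of random-forest models: an initial model on all 120
temporal features and a secondary model on the 20 annual-window features,
both trained on the same post-outlier-filter sample set. Pixel-years route
to a model by feature tier; tier ``none`` becomes No Data. Eight-class
predictions are grouped to the five-class scheme post hoc, both for maps
and for the out-of-bag confusion matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .classes import (
    CLASS5_CODE,
    CLASS5_ORDER,
    CLASS8_CODE,
    GROUP_TO_FIVE,
    NODATA,
    group_to_five,
)
from .features import ANNUAL_FEATURE_IDX, N_FEATURES, Tier, cube_year_features
from .scene import CompositeCube, LandscapePartition

logger = logging.getLogger(__name__)

MAX_NODATA_YEARS = 4   # pixels with >= this many No-Data years are voided


@dataclass(frozen=True)
class RFConfig:
    """Ensemble configuration (defaults match the published run)."""

    n_trees: int = 1999
    min_node_size: int = 5
    max_features: str | int = "sqrt"     # floor(sqrt(p)) candidates per split

    def make(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_node_size,
            max_features=self.max_features,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )


@dataclass
class ClassifierPair:
    """Initial (all-feature) and secondary (annual-only) models for a biome."""

    biome_id: int
    initial: RandomForestClassifier
    secondary: RandomForestClassifier
    training_sample_ids: np.ndarray
    config: RFConfig
    seed: int
    outlier_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_training_samples(self) -> int:
        return self.training_sample_ids.size

    def oob_predictions(self) -> np.ndarray:
        """OOB class predictions (8-scheme names) for every training sample.

        Vote ties resolve to the first class in the model's sorted class
        order; samples never out of bag (vanishingly rare at 1999 trees)
        fall back to the in-bag prediction.
        """
        proba = self.initial.oob_decision_function_
        never_oob = np.isnan(proba).any(axis=1) | (proba.sum(axis=1) == 0)
        pred = self.initial.classes_[np.argmax(np.nan_to_num(proba), axis=1)]
        if never_oob.any():
            logger.warning("%d samples never OOB; using in-bag predictions",
                           int(never_oob.sum()))
        return pred


def proximity_matrix(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees in which each pair of samples lands in the same leaf."""
    leaves = model.apply(np.asarray(X))
    n, n_trees = leaves.shape
    prox = np.zeros((n, n), dtype=np.float64)
    for t in range(n_trees):
        col = leaves[:, t]
        prox += col[:, None] == col[None, :]
    prox /= n_trees
    return prox


def outlier_scores(labels: np.ndarray, proximity: np.ndarray) -> np.ndarray:
    """Class-wise standardized proximity outlier scores.

    Per sample i of class c: raw = n_c / sum_{j in c} prox(i, j)^2, then
    standardized within class by the class median and the mean absolute
    deviation from the median. Classes with fewer than 2 samples get score
    0 (undefined; such samples are always retained).
    """
    labels = np.asarray(labels)
    n = labels.size
    if proximity.shape != (n, n):
        raise ValueError("proximity matrix does not match sample count")
    scores = np.zeros(n, dtype=float)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            logger.info("class %r has <2 samples; outlier score undefined, retained", cls)
            continue
        sub = proximity[np.ix_(idx, idx)]
        raw = idx.size / np.maximum((sub ** 2).sum(axis=1), 1e-300)
        med = np.median(raw)
        mad = np.mean(np.abs(raw - med))
        if mad == 0:
            continue
        scores[idx] = (raw - med) / mad
    return scores


def remove_outliers(
    labels: np.ndarray, proximity: np.ndarray, threshold: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Keep-mask and scores after dropping samples with score > threshold."""
    scores = outlier_scores(labels, proximity)
    keep = scores <= threshold
    return keep, scores


def train_biome_classifier(
    sample_ids: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    biome_id: int = 0,
    config: RFConfig | None = None,
    seed: int = 0,
    outlier_threshold: float = 10.0,
) -> ClassifierPair:
    """Fit the per-biome model pair with proximity-outlier filtering.

    An initial forest is fit on all samples to obtain proximities; samples
    with outlier metric greater than ``outlier_threshold`` are dropped; the
    final initial (120-feature) and secondary (annual-feature) forests are
    then fit on the filtered set. Deterministic given ``seed``.
    """
    config = config or RFConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sample_ids = np.asarray(sample_ids)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    if np.unique(y).size < 2:
        raise ValueError(f"biome {biome_id}: need >=2 classes, got {np.unique(y)!r}")
    if np.isnan(X).any():
        raise ValueError("training features must be tier=full (no nulls)")

    prelim = config.make(seed).fit(X, y)
    prox = proximity_matrix(prelim, X)
    keep, scores = remove_outliers(y, prox, outlier_threshold)
    if np.unique(y[keep]).size < 2:
        raise ValueError(f"biome {biome_id}: outlier filter left <2 classes")

    Xk, yk = X[keep], y[keep]
    initial = config.make(seed).fit(Xk, yk)
    secondary = config.make(seed).fit(Xk[:, ANNUAL_FEATURE_IDX], yk)
    return ClassifierPair(
        biome_id=biome_id,
        initial=initial,
        secondary=secondary,
        training_sample_ids=sample_ids[keep],
        config=config,
        seed=seed,
        outlier_scores=scores,
    )


def classify_pixel_year(feature_vector, classifier_pair: ClassifierPair) -> str | None:
    """Route one pixel-year to a model by feature tier.

    Returns the 8-scheme class name, or None for No Data (tier ``none``).
    """
    if feature_vector.tier == Tier.NONE:
        return None
    vals = feature_vector.values[None, :]
    if feature_vector.tier == Tier.FULL:
        return str(classifier_pair.initial.predict(vals)[0])
    return str(classifier_pair.secondary.predict(vals[:, ANNUAL_FEATURE_IDX])[0])


def classify_batch(
    features: np.ndarray, tiers: np.ndarray, classifier_pair: ClassifierPair
) -> tuple[np.ndarray, dict[str, int]]:
    """Classify many pixel-years at once.

    Returns 8-scheme integer codes (0 = No Data) and a routing counter
    {"full": ..., "annual_only": ..., "none": ...}.
    """
    tiers = np.asarray(tiers)
    out = np.zeros(tiers.size, dtype=np.int8)
    full = tiers == Tier.FULL
    annual = tiers == Tier.ANNUAL_ONLY
    code_of = np.vectorize(CLASS8_CODE.get, otypes=[np.int8])
    if full.any():
        out[full] = code_of(classifier_pair.initial.predict(features[full]))
    if annual.any():
        out[annual] = code_of(
            classifier_pair.secondary.predict(features[annual][:, ANNUAL_FEATURE_IDX])
        )
    counts = {
        "full": int(full.sum()),
        "annual_only": int(annual.sum()),
        "none": int((tiers == Tier.NONE).sum()),
    }
    return out, counts


@dataclass(frozen=True)
class AnnualMapStack:
    """Per-pixel, per-year five-class map codes (0 = No Data)."""

    codes: np.ndarray                  # (n_years, rows, cols) int8, 0..5
    years: tuple[int, ...]
    nodata_fraction: pd.DataFrame      # columns: municipality, year, nodata_fraction
    route_counts: dict[str, int] = field(default_factory=dict)


# 8-class code -> 5-class code lookup (index 0 stays No Data)
_GROUP_LUT = np.zeros(len(CLASS8_CODE) + 1, dtype=np.int8)
for _name, _code in CLASS8_CODE.items():
    _GROUP_LUT[_code] = CLASS5_CODE[GROUP_TO_FIVE[_name]]


def build_annual_maps(
    cube: CompositeCube,
    partition: LandscapePartition,
    classifiers: dict[int, ClassifierPair],
) -> AnnualMapStack:
    """Classify every pixel-year by its biome's model pair and apply the
    No-Data rules.

    Eight-class labels are grouped to five classes; pixels with
    >= MAX_NODATA_YEARS No-Data years over the series are voided in all
    years; per-municipality annual No-Data fractions are recorded.
    """
    if (cube.rows, cube.cols) != (partition.rows, partition.cols):
        raise ValueError("cube and partition grids differ")
    mun_flat = partition.municipality_of.ravel()
    biome_of_pixel = np.vectorize(partition.biome_of_municipality.get)(mun_flat)
    for b in np.unique(biome_of_pixel):
        if int(b) not in classifiers:
            raise ValueError(f"no trained classifier for biome {int(b)}")

    n_years = len(cube.years)
    n_pix = cube.rows * cube.cols
    codes8 = np.zeros((n_years, n_pix), dtype=np.int8)
    route_totals = {"full": 0, "annual_only": 0, "none": 0}
    for yi in range(n_years):
        feats, tiers = cube_year_features(cube, yi)
        for b in np.unique(biome_of_pixel):
            sel = biome_of_pixel == b
            labels, counts = classify_batch(feats[sel], tiers[sel], classifiers[int(b)])
            codes8[yi, sel] = labels
            for k, v in counts.items():
                route_totals[k] += v

    codes5 = _GROUP_LUT[codes8]
    void = (codes5 == NODATA).sum(axis=0) >= MAX_NODATA_YEARS
    codes5[:, void] = NODATA

    recs = []
    for m in partition.municipality_ids:
        sel = mun_flat == m
        denom = int(sel.sum())
        for yi, year in enumerate(cube.years):
            recs.append({
                "municipality": int(m),
                "year": int(year),
                "nodata_fraction": float((codes5[yi, sel] == NODATA).sum() / denom),
            })
    return AnnualMapStack(
        codes=codes5.reshape(n_years, cube.rows, cube.cols),
        years=cube.years,
        nodata_fraction=pd.DataFrame.from_records(recs),
        route_counts=route_totals,
    )


@dataclass(frozen=True)
class AccuracyReport:
    """Five-class OOB confusion matrix and derived accuracies for one biome."""

    biome_id: int
    matrix: np.ndarray                 # (5, 5), rows = reference, cols = predicted
    classes: tuple[str, ...]
    n_samples: int
    overall: float                     # %
    producers: dict[str, float]        # % per class (NaN if class absent)
    users: dict[str, float]

    @classmethod
    def from_matrix(cls, biome_id: int, matrix: np.ndarray,
                    classes: tuple[str, ...] = CLASS5_ORDER) -> "AccuracyReport":
        m = np.asarray(matrix, dtype=float)
        total = m.sum()
        diag = np.diag(m)
        with np.errstate(divide="ignore", invalid="ignore"):
            prod = 100.0 * diag / m.sum(axis=1)
            user = 100.0 * diag / m.sum(axis=0)
        return cls(
            biome_id=biome_id,
            matrix=m,
            classes=tuple(classes),
            n_samples=int(total),
            overall=100.0 * float(diag.sum()) / float(total),
            producers=dict(zip(classes, prod.tolist())),
            users=dict(zip(classes, user.tolist())),
        )


def oob_accuracy(classifier_pair: ClassifierPair, reference_class8: np.ndarray) -> AccuracyReport:
    """OOB accuracy for one biome, in the five-class scheme.

    Both the OOB predictions and the reference labels are grouped to five
    classes before the matrix is built.
    """
    ref = np.asarray(reference_class8)
    pred = classifier_pair.oob_predictions()
    if ref.size != pred.size:
        raise ValueError("reference labels do not match training sample count")
    idx = {c: i for i, c in enumerate(CLASS5_ORDER)}
    m = np.zeros((len(CLASS5_ORDER), len(CLASS5_ORDER)), dtype=float)
    for r, p in zip(ref, pred):
        m[idx[group_to_five(str(r))], idx[group_to_five(str(p))]] += 1
    return AccuracyReport.from_matrix(classifier_pair.biome_id, m)


@dataclass(frozen=True)
class AccuracySummary:
    """Cross-biome unweighted summary of overall and per-class accuracies."""

    n_biomes: int
    mean_overall: float
    sd_overall: float                  # sample sd (n-1)
    producers_mean: dict[str, float]
    users_mean: dict[str, float]


def summarize_accuracy(reports: list[AccuracyReport]) -> AccuracySummary:
    """Unweighted mean / sample sd of overall accuracy across biomes, and
    unweighted per-class means of producer's and user's accuracies."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to summarize")
    overalls = np.array([r.overall for r in reports], dtype=float)
    classes = reports[0].classes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        prod = {
            c: float(np.nanmean([r.producers.get(c, np.nan) for r in reports]))
            for c in classes
        }
        user = {
            c: float(np.nanmean([r.users.get(c, np.nan) for r in reports]))
            for c in classes
        }
    return AccuracySummary(
        n_biomes=len(reports),
        mean_overall=float(overalls.mean()),
        sd_overall=float(overalls.std(ddof=1)),
        producers_mean=prod,
        users_mean=user,
    )
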