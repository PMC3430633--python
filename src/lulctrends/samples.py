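"""Consensus labeling of paired interpreter percent-cover estimates.

Two interpreters estimate percent cover of seven categories for each
reference footprint. If they agree on the majority cover and image year,
their estimates are averaged; otherwise an expert resolution is adopted.
Final percents are assigned to an eight-category class by the >=80% rule
with a mixed-woody fallback, then grouped to the five-class map scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classes import CATEGORY_ORDER, group_to_five

SUM_TOLERANCE = 0.5  # interpretation rounding slack on the 100% total


@dataclass(frozen=True)
class SampleInterpretation:
    """One interpreter's percent-cover estimates for one footprint."""

    sample_id: int
    interpreter: str
    percents: dict[str, float]
    year: int

    def __post_init__(self) -> None:
        unknown = set(self.percents) - set(CATEGORY_ORDER)
        if unknown:
            raise ValueError(f"unknown cover categories {sorted(unknown)}")
        vals = [self.percents.get(c, 0.0) for c in CATEGORY_ORDER]
        if any(v < 0 for v in vals):
            raise ValueError("percent covers must be nonnegative")
        total = sum(vals)
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise ValueError(f"percent covers sum to {total}, expected 100 +/- {SUM_TOLERANCE}")


@dataclass(frozen=True)
class ConsensusSample:
    """Final percents, image year and class label for one footprint."""

    sample_id: int
    percents: dict[str, float]
    year: int
    class8: str | None
    provenance: str              # "averaged" | "expert"

    @property
    def class5(self) -> str | None:
        return group_to_five(self.class8) if self.class8 is not None else None


def majority_cover(percents: dict[str, float]) -> tuple[str, ...]:
    """Categories sharing the maximum percent, in the fixed category order.

    A tie between interpreters counts as agreement only when both tie over
    the identical category set.
    """
    top = max(percents.get(c, 0.0) for c in CATEGORY_ORDER)
    return tuple(c for c in CATEGORY_ORDER if percents.get(c, 0.0) == top)


def assign_class(final_percents: dict[str, float]) -> str | None:
    """Assign the eight-category class for a percent-cover vector.

    Any single category >=80% wins (checked first, in fixed category order);
    otherwise 20-80% woody with each of bare, herb, ag below 80% is
    mixed_woody; anything else is unassigned (None). Total function.
    """
    for c in CATEGORY_ORDER:
        if final_percents.get(c, 0.0) >= 80.0:
            return c
    woody = final_percents.get("woody", 0.0)
    if (20.0 <= woody <= 80.0
            and final_percents.get("bare", 0.0) < 80.0
            and final_percents.get("herb", 0.0) < 80.0
            and final_percents.get("ag", 0.0) < 80.0):
        return "mixed_woody"
    return None


def consensus(
    interpretation_a: SampleInterpretation,
    interpretation_b: SampleInterpretation,
    expert_resolution: SampleInterpretation | None = None,
) -> ConsensusSample | None:
    """Merge two interpretations of the same footprint.

    Agreement on majority cover and image year averages the percents
    element-wise; any disagreement adopts the supplied expert resolution
    verbatim. Returns None (unresolved, to be excluded) when interpreters
    disagree and no expert resolution is supplied.
    """
    if interpretation_a.sample_id != interpretation_b.sample_id:
        raise ValueError(
            f"sample ids differ: {interpretation_a.sample_id} vs "
            f"{interpretation_b.sample_id}"
        )
    agree = (
        majority_cover(interpretation_a.percents) == majority_cover(interpretation_b.percents)
        and interpretation_a.year == interpretation_b.year
    )
    if agree:
        merged = {
            c: (interpretation_a.percents.get(c, 0.0) + interpretation_b.percents.get(c, 0.0)) / 2.0
            for c in CATEGORY_ORDER
        }
        return ConsensusSample(
            sample_id=interpretation_a.sample_id,
            percents=merged,
            year=interpretation_a.year,
            class8=assign_class(merged),
            provenance="averaged",
        )
    if expert_resolution is None:
        return None
    if expert_resolution.sample_id != interpretation_a.sample_id:
        raise ValueError("expert resolution refers to a different sample")
    final = {c: expert_resolution.percents.get(c, 0.0) for c in CATEGORY_ORDER}
    return ConsensusSample(
        sample_id=interpretation_a.sample_id,
        percents=final,
        year=expert_resolution.year,
        class8=assign_class(final),
        provenance="expert",
    )
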