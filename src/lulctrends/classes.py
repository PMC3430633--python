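"""Cover-class schemes shared across the pipeline.

Two nested schemes are used: an eight-category scheme for interpretation
and classifier training, and a five-class scheme for the final maps and
all change analyses.
"""

from __future__ import annotations

# Percent-cover categories interpreted on a reference footprint, in the
# fixed order used for majority-cover tie-breaking.
CATEGORY_ORDER: tuple[str, ...] = (
    "woody", "herb", "ag", "plant", "built", "bare", "water",
)

# Eight-category training scheme: the seven interpreted categories plus the
# mixed-woody rule class.
CLASS8_ORDER: tuple[str, ...] = (
    "ag", "bare", "built", "herb", "mixed_woody", "plant", "woody", "water",
)

# Final five-class map scheme.
CLASS5_ORDER: tuple[str, ...] = (
    "woody", "mixed_woody_plant", "ag_herb", "bare_built", "water",
)

# Integer codes used in map rasters. 0 is reserved for No Data.
NODATA = 0
CLASS5_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASS5_ORDER)}
CODE_CLASS5: dict[int, str] = {v: k for k, v in CLASS5_CODE.items()}

CLASS8_CODE: dict[str, int] = {name: i + 1 for i, name in enumerate(CLASS8_ORDER)}
CODE_CLASS8: dict[int, str] = {v: k for k, v in CLASS8_CODE.items()}

# Post-classification grouping of the eight categories into five classes.
GROUP_TO_FIVE: dict[str, str] = {
    "woody": "woody",
    "mixed_woody": "mixed_woody_plant",
    "plant": "mixed_woody_plant",
    "ag": "ag_herb",
    "herb": "ag_herb",
    "built": "bare_built",
    "bare": "bare_built",
    "water": "water",
}

# The three vegetation classes whose areas are trend-analysed.
TREND_CLASSES: tuple[str, ...] = ("woody", "mixed_woody_plant", "ag_herb")


def group_to_five(class8: str) -> str:
    """Map an eight-scheme class to its five-class group.

    Raises ``ValueError`` for unknown or unassigned input: grouping applies
    to labeled samples only.
    """
    try:
        return GROUP_TO_FIVE[class8]
    except KeyError:
        raise ValueError(f"cannot group unassigned/unknown class {class8!r}") from None
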