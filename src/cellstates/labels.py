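"""The six cell-state categories used throughout the package.

Five are biological states readable from phase-contrast morphology; the
sixth, ``DISCARDED``, marks multiplets (two or more touching cells in one
crop). Debris is never a category — it is filtered out during cropping.
"""

from __future__ import annotations

from enum import Enum


class CellStateLabel(str, Enum):
    MITOSIS = "mitosis"
    APOPTOSIS = "apoptosis"
    INTERPHASE = "interphase"
    NECROSIS = "necrosis"
    SENESCENCE = "senescence"
    DISCARDED = "discarded"

    def __str__(self) -> str:  # plain value in tables and filenames
        return self.value


#: Stable label <-> class-index mapping used by the classifier and reports.
LABEL_ORDER: tuple[CellStateLabel, ...] = (
    CellStateLabel.MITOSIS,
    CellStateLabel.APOPTOSIS,
    CellStateLabel.INTERPHASE,
    CellStateLabel.NECROSIS,
    CellStateLabel.SENESCENCE,
    CellStateLabel.DISCARDED,
)

LABEL_TO_INDEX: dict[CellStateLabel, int] = {l: i for i, l in enumerate(LABEL_ORDER)}

#: The five biological classes scored by per-class sensitivity.
BIOLOGICAL_LABELS: tuple[CellStateLabel, ...] = LABEL_ORDER[:5]


def as_label(value) -> CellStateLabel:
    """Coerce a string or label to a CellStateLabel, with a clear error."""
    if isinstance(value, CellStateLabel):
        return value
    try:
        return CellStateLabel(str(value).lower())
    except ValueError:
        valid = ", ".join(l.value for l in LABEL_ORDER)
        raise ValueError(f"unknown cell-state label {value!r}; expected one of: {valid}")
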