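"""Rule-based morphometric quantifications.

Dendritic spines are classified from measured geometry (length, head
width, neck width, in micrometers) by three rules applied in fixed
precedence; immuno-EM particle localization is summarized as
percentages of total particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MUSHROOM = "mushroom"
STUBBY = "stubby"
THIN_FILOPODIA = "thin_filopodia"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SpineMeasurement:
    """One spine's geometry; an absent head width encodes an indistinct
    head."""

    length_um: float
    head_width_um: float | None = None
    neck_width_um: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("length_um", self.length_um),
                        ("head_width_um", self.head_width_um),
                        ("neck_width_um", self.neck_width_um)):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


def classify_spine(m: SpineMeasurement) -> str:
    """Spine class by fixed-precedence rules.

    1. mushroom — distinct head wider than 0.5 um, or wider than twice
       the neck;
    2. stubby — short protrusion (length <= 0.5 um) with an indistinct
       head;
    3. thin/filopodia — long protrusion (length > 0.5 um) with a head
       narrower than 0.5 um or no distinct head.

    Mushroom takes priority when rules overlap (its rule is head-based
    regardless of length).  Measurements matching no rule — e.g. a
    0.5 um-long spine with a head exactly 0.5 um wide — are flagged
    ``unclassified`` rather than silently assigned.
    """
    head, neck = m.head_width_um, m.neck_width_um
    if head is not None and (
        head > 0.5 or (neck is not None and head > 2.0 * neck)
    ):
        return MUSHROOM
    if m.length_um <= 0.5 and head is None:
        return STUBBY
    if m.length_um > 0.5 and (head is None or head < 0.5):
        return THIN_FILOPODIA
    return UNCLASSIFIED


def classify_spines(table: pd.DataFrame) -> pd.Series:
    """Vectorized wrapper over a table with columns ``length_um``,
    ``head_width_um``, ``neck_width_um`` (NaN = absent)."""
    def row_class(row) -> str:
        return classify_spine(SpineMeasurement(
            length_um=float(row["length_um"]),
            head_width_um=None if pd.isna(row.get("head_width_um"))
            else float(row["head_width_um"]),
            neck_width_um=None if pd.isna(row.get("neck_width_um"))
            else float(row["neck_width_um"]),
        ))
    return table.apply(row_class, axis=1).rename("spine_class")


def particle_proportions(cleft: int, intra_spine: int) -> dict[str, float]:
    """Percentages of synaptic-cleft vs intra-spine particles.

    Returns integer-rounded percentages for reporting plus the raw
    fractions (which sum to 1 exactly).
    """
    if cleft < 0 or intra_spine < 0:
        raise ValueError("counts must be nonnegative")
    total = cleft + intra_spine
    if total == 0:
        raise ValueError("total particle count must be positive")
    frac_cleft = cleft / total
    frac_intra = intra_spine / total
    return {
        "pct_cleft": round(100.0 * frac_cleft),
        "pct_intra": round(100.0 * frac_intra),
        "frac_cleft": frac_cleft,
        "frac_intra": frac_intra,
    }
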