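"""Space-allowance models: allometric formulas and the EU transport minimum.

Two yardsticks are compared against the measured covered areas:

* **Allometric formulas** ``a = k · W^0.66`` relating live weight W (kg) to
  covered area a (m²), with the coefficient depending on posture class:
  0.019 for standing and sternal lying, 0.025 for semilateral lying and
  0.047 for fully recumbent lying.
* **The legal loading-density minimum** for road transport of ~100 kg pigs:
  at most 235 kg live weight per m² of floor, i.e. a minimum area of
  W / 235 m² per animal, optionally increased by up to 20%.

``comparison_table`` evaluates both at each posture group's mean live
weight and reports signed deviations: ``allometric − measured`` (how far the
formula over-predicts the static space) and ``legal − measured`` (the free
space remaining beyond the animal's body outline; negative means the legal
minimum is smaller than the body itself).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .postures import (
    POSTURE_CODES,
    STANDING_CODES,
    InvalidPostureError,
    StudyGroupSummary,
    posture_class,
)
from .rounding import round_half_up

__all__ = [
    "ALLOMETRIC_EXPONENT",
    "DEFAULT_DENSITY_KG_PER_M2",
    "AllometricModel",
    "LegalRequirement",
    "ComparisonRow",
    "StandingSummary",
    "allometric_area",
    "coefficient_for_posture",
    "legal_min_area",
    "comparison_table",
    "standing_deviation_summary",
    "write_comparison",
    "plot_comparison",
]

ALLOMETRIC_EXPONENT = 0.66

#: EU road-transport loading density for finishing pigs (kg live weight/m²).
DEFAULT_DENSITY_KG_PER_M2 = 235.0

# Posture → space-allowance coefficient k (m²·kg^-0.66): the standing
# formula also covers sternal lying with legs folded beneath the body.
_COEFFICIENTS = {**{c: 0.019 for c in STANDING_CODES},
                 "LBC": 0.019, "LSL": 0.025, "LL": 0.047}


@dataclass(frozen=True)
class AllometricModel:
    """Power-law space allowance a = k · W^0.66."""

    k: float
    exponent: float = ALLOMETRIC_EXPONENT

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("coefficient k must be positive")


@dataclass(frozen=True)
class LegalRequirement:
    """Loading-density floor-space rule: area ≥ (W / density)·(1 + surcharge)."""

    density_kg_per_m2: float = DEFAULT_DENSITY_KG_PER_M2
    surcharge: float = 0.0

    def __post_init__(self) -> None:
        if self.density_kg_per_m2 <= 0:
            raise ValueError("density must be positive")
        if not 0.0 <= self.surcharge <= 0.20:
            raise ValueError("surcharge must lie in [0, 0.20]")


@dataclass(frozen=True)
class ComparisonRow:
    """Per-posture comparison of measured vs modelled floor areas (m²)."""

    posture: str
    weight_mean_kg: float
    measured_area: float
    allometric_area: float
    allometric_deviation: float  # allometric − measured, signed
    legal_min_area: float
    free_space: float  # legal − measured, signed
    sufficient: bool  # free_space ≥ 0


@dataclass(frozen=True)
class StandingSummary:
    """Summary of allometric deviations over the ten standing postures."""

    mean: float
    sd: float
    min: float
    max: float
    argmin: str
    argmax: str


def allometric_area(weight_kg: float, model: AllometricModel) -> float:
    """Covered area (m²) predicted by the allometric formula at ``weight_kg``."""
    if weight_kg < 0:
        raise ValueError("weight must be non-negative")
    return model.k * weight_kg**model.exponent


def coefficient_for_posture(code: str) -> AllometricModel:
    """The recommended allometric model for a posture code."""
    try:
        return AllometricModel(k=_COEFFICIENTS[code])
    except KeyError:
        raise InvalidPostureError(f"unknown posture code: {code!r}") from None


def legal_min_area(
    weight_kg: float, requirement: LegalRequirement = LegalRequirement()
) -> float:
    """Minimum legal floor area (m²) for one animal of ``weight_kg``."""
    if weight_kg < 0:
        raise ValueError("weight must be non-negative")
    return (weight_kg / requirement.density_kg_per_m2) * (1.0 + requirement.surcharge)


def comparison_table(
    study_tables: Sequence[StudyGroupSummary],
    requirement: LegalRequirement = LegalRequirement(),
) -> list[ComparisonRow]:
    """One comparison row per posture, from the group mean weights and areas.

    Inputs are the published group means exactly as printed; deviations are
    carried unrounded (round only with :func:`round_half_up` when printing).
    """
    by_code = {r.posture: r for r in study_tables}
    missing = [c for c in POSTURE_CODES if c not in by_code]
    if missing:
        raise ValueError(f"missing posture rows: {missing}")
    rows = []
    for code in POSTURE_CODES:
        rec = by_code[code]
        a_allo = allometric_area(rec.weight_mean, coefficient_for_posture(code))
        a_legal = legal_min_area(rec.weight_mean, requirement)
        free = a_legal - rec.area_mean
        rows.append(
            ComparisonRow(
                posture=code,
                weight_mean_kg=rec.weight_mean,
                measured_area=rec.area_mean,
                allometric_area=a_allo,
                allometric_deviation=a_allo - rec.area_mean,
                legal_min_area=a_legal,
                free_space=free,
                sufficient=free >= 0,
            )
        )
    return rows


def standing_deviation_summary(rows: Sequence[ComparisonRow]) -> StandingSummary:
    """Mean/SD/min/max of allometric deviations over standing postures."""
    devs = {r.posture: r.allometric_deviation
            for r in rows if posture_class(r.posture) == "standing"}
    if len(devs) != len(STANDING_CODES):
        raise ValueError("need all ten standing rows")
    vals = list(devs.values())
    n = len(vals)
    mean = sum(vals) / n
    sd = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
    argmin = min(devs, key=devs.get)
    argmax = max(devs, key=devs.get)
    return StandingSummary(mean=mean, sd=sd, min=devs[argmin], max=devs[argmax],
                           argmin=argmin, argmax=argmax)


def write_comparison(
    rows: Sequence[ComparisonRow], path: str | Path
) -> None:
    """Write the comparison table (plus standing summary) to CSV, 3 dp half-up."""
    summary = standing_deviation_summary(rows)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["posture", "weight_mean_kg", "measured_area_m2",
             "allometric_area_m2", "allometric_deviation_m2",
             "legal_min_area_m2", "free_space_m2", "sufficient"]
        )
        for r in rows:
            writer.writerow(
                [r.posture, f"{r.weight_mean_kg:.2f}", f"{r.measured_area:.3f}",
                 f"{round_half_up(r.allometric_area, 3):.3f}",
                 f"{round_half_up(r.allometric_deviation, 3):.3f}",
                 f"{round_half_up(r.legal_min_area, 3):.3f}",
                 f"{round_half_up(r.free_space, 3):.3f}",
                 str(r.sufficient).lower()]
            )
        writer.writerow(
            ["standing_summary", "", "", "",
             f"mean={round_half_up(summary.mean, 3):.3f}"
             f";sd={round_half_up(summary.sd, 3):.3f}"
             f";min={round_half_up(summary.min, 3):.3f}({summary.argmin})"
             f";max={round_half_up(summary.max, 3):.3f}({summary.argmax})",
             "", "", ""]
        )


def plot_comparison(rows: Sequence[ComparisonRow], path: str | Path) -> None:
    """Grouped bar chart of measured vs allometric vs legal areas per posture."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    x = np.arange(len(rows))
    width = 0.28
    fig, ax = plt.subplots(figsize=(10, 4.5))
    ax.bar(x - width, [r.measured_area for r in rows], width,
           label="measured", color="#3b6ea5")
    ax.bar(x, [r.allometric_area for r in rows], width,
           label="allometric k·W^0.66", color="#c4722e")
    ax.bar(x + width, [r.legal_min_area for r in rows], width,
           label="legal minimum (235 kg/m²)", color="#5a915a")
    ax.set_xticks(x, [r.posture for r in rows])
    ax.set_ylabel("floor area (m²)")
    ax.set_xlabel("body posture")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
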