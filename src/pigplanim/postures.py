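"""Posture taxonomy and the study's summary tables.

Thirteen top-view body postures of finishing pigs are distinguished: ten
standing postures (codes A, AS, B, BS, C, CS, D, DS, E, ES — varying head
height and sideways body curvature) and three lying postures (LBC: sternal
recumbency, LSL: semilateral recumbency, LL: full lateral recumbency).

The per-posture study summaries (image counts, gender split, live-weight and
covered-area statistics) and the weight-area Spearman coefficients are
shipped as packaged CSV fixtures and loaded into typed records with their
internal consistency checked on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "POSTURE_CODES",
    "STANDING_CODES",
    "LYING_CODES",
    "PostureRecord",
    "StudyGroupSummary",
    "CorrelationRecord",
    "InvalidPostureError",
    "TableParseError",
    "posture_class",
    "reference_height_for",
    "posture_catalog",
    "load_study_tables",
    "save_study_tables",
    "load_correlations",
    "packaged_study_tables",
    "packaged_correlations",
    "overall_weight_summary",
]

#: Reference-surface mounting heights (cm above the floor) used when
#: calibrating images of standing and lying animals.
STANDING_REFERENCE_HEIGHT_CM = 69.00
LYING_REFERENCE_HEIGHT_CM = 29.00

STANDING_CODES = ("A", "AS", "B", "BS", "C", "CS", "D", "DS", "E", "ES")
LYING_CODES = ("LBC", "LSL", "LL")
POSTURE_CODES = STANDING_CODES + LYING_CODES

_DESCRIPTIONS = {
    "A": "Standing up straight, nose touching the ground",
    "AS": "Standing curved sideways, nose touching the ground",
    "B": "Standing up straight, head lowered to the ground",
    "BS": "Standing curved sideways, head lowered to the ground",
    "C": "Standing up straight, head raised below the dorsal line",
    "CS": "Standing curved sideways, head raised below the dorsal line",
    "D": "Standing up straight, head raised at the level of dorsal line",
    "DS": "Standing curved sideways, head raised at the level of dorsal line",
    "E": "Standing up straight, head raised above the dorsal line",
    "ES": "Standing curved sideways, head raised above the dorsal line",
    "LBC": "Lying in sternal (belly chest) recumbency",
    "LSL": "Lying in semilateral (lateral chest) recumbency",
    "LL": "Lying in lateral (full) recumbency",
}


class InvalidPostureError(ValueError):
    """Raised for a posture code outside the 13-code taxonomy."""


class TableParseError(ValueError):
    """Raised when a study-table CSV violates the catalog invariants."""


@dataclass(frozen=True)
class PostureRecord:
    """One posture code with its class and calibration reference height."""

    code: str
    description: str
    posture_class: str  # "standing" | "lying"
    reference_height_cm: float


@dataclass(frozen=True)
class StudyGroupSummary:
    """Per-posture summary of the study cohort: counts, weights, areas."""

    posture: str
    n_images: int
    n_female: int
    n_male_neutered: int
    weight_mean: float
    weight_sd: float
    weight_min: float
    weight_max: float
    area_mean: float
    area_sd: float
    area_min: float
    area_max: float


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman rho between live weight and covered area within a posture."""

    posture: str
    rho: float


def posture_class(code: str) -> str:
    """Return ``"standing"`` or ``"lying"`` for a posture code."""
    if code in STANDING_CODES:
        return "standing"
    if code in LYING_CODES:
        return "lying"
    raise InvalidPostureError(f"unknown posture code: {code!r}")


def reference_height_for(code: str) -> float:
    """Reference-board mounting height (cm) matched to a posture's class.

    69.00 cm for standing postures (mean standing back height of the study
    animals), 29.00 cm for lying postures.
    """
    cls = posture_class(code)
    return STANDING_REFERENCE_HEIGHT_CM if cls == "standing" else LYING_REFERENCE_HEIGHT_CM


def posture_catalog() -> list[PostureRecord]:
    """The full 13-record catalog, in table order A … LL."""
    return [
        PostureRecord(c, _DESCRIPTIONS[c], posture_class(c), reference_height_for(c))
        for c in POSTURE_CODES
    ]


_NUMERIC_FIELDS = (
    "weight_mean",
    "weight_sd",
    "weight_min",
    "weight_max",
    "area_mean",
    "area_sd",
    "area_min",
    "area_max",
)

#: Total number of analysed pictures across all 13 posture groups.
TOTAL_IMAGES = 1583


def _parse_row(row: Mapping[str, str], line_no: int) -> StudyGroupSummary:
    code = row["posture"].strip()
    if code not in POSTURE_CODES:
        raise TableParseError(f"row {line_no}: unknown posture {code!r}")
    try:
        counts = {
            k: int(row[k]) for k in ("n_images", "n_female", "n_male_neutered")
        }
        nums = {k: float(row[k]) for k in _NUMERIC_FIELDS}
    except (KeyError, ValueError) as exc:
        raise TableParseError(f"row {line_no} ({code}): bad cell: {exc}") from exc
    rec = StudyGroupSummary(posture=code, **counts, **nums)
    if rec.n_images != rec.n_female + rec.n_male_neutered:
        raise TableParseError(
            f"row {line_no} ({code}): n_images {rec.n_images} != "
            f"female {rec.n_female} + male {rec.n_male_neutered}"
        )
    if not (rec.weight_min <= rec.weight_mean <= rec.weight_max):
        raise TableParseError(f"row {line_no} ({code}): weight ordering violated")
    if not (rec.area_min <= rec.area_mean <= rec.area_max):
        raise TableParseError(f"row {line_no} ({code}): area ordering violated")
    return rec


def load_study_tables(path: str | Path) -> list[StudyGroupSummary]:
    """Read the per-posture summary table from CSV.

    Expects one row per posture (13 rows) plus an optional ``Total`` row,
    which carries only the pooled image count and weight summary and is
    validated but not returned. All invariants — gender sums, min/mean/max
    ordering, the 1,583-image total, no duplicate or missing postures — are
    enforced; violations raise :class:`TableParseError` naming the row.
    """
    records: dict[str, StudyGroupSummary] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for line_no, row in enumerate(reader, start=2):
            code = (row.get("posture") or "").strip()
            if code.lower() == "total":
                continue
            if code in records:
                raise TableParseError(f"row {line_no}: duplicate posture {code!r}")
            records[code] = _parse_row(row, line_no)
    missing = [c for c in POSTURE_CODES if c not in records]
    if missing:
        raise TableParseError(f"missing posture rows: {missing}")
    total = sum(r.n_images for r in records.values())
    if total != TOTAL_IMAGES:
        raise TableParseError(
            f"total image count {total} != expected {TOTAL_IMAGES}"
        )
    return [records[c] for c in POSTURE_CODES]


def save_study_tables(records: Iterable[StudyGroupSummary], path: str | Path) -> None:
    """Write summaries back to CSV at the fixture's printed precision
    (2 dp for kg, 3 dp for m²); a load/save round-trip is lossless."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["posture", "n_images", "n_female", "n_male_neutered"]
            + list(_NUMERIC_FIELDS)
        )
        for r in records:
            writer.writerow(
                [r.posture, r.n_images, r.n_female, r.n_male_neutered]
                + [f"{getattr(r, k):.2f}" for k in _NUMERIC_FIELDS[:4]]
                + [f"{getattr(r, k):.3f}" for k in _NUMERIC_FIELDS[4:]]
            )


def load_correlations(path: str | Path) -> list[CorrelationRecord]:
    """Read per-posture Spearman coefficients from CSV (one row per posture)."""
    records: dict[str, CorrelationRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for line_no, row in enumerate(csv.DictReader(fh), start=2):
            code = row["posture"].strip()
            if code not in POSTURE_CODES:
                raise TableParseError(f"row {line_no}: unknown posture {code!r}")
            if code in records:
                raise TableParseError(f"row {line_no}: duplicate posture {code!r}")
            rho = float(row["rho"])
            if not -1.0 <= rho <= 1.0:
                raise TableParseError(f"row {line_no} ({code}): |rho| > 1")
            records[code] = CorrelationRecord(code, rho)
    missing = [c for c in POSTURE_CODES if c not in records]
    if missing:
        raise TableParseError(f"missing posture rows: {missing}")
    return [records[c] for c in POSTURE_CODES]


def _packaged(name: str) -> Path:
    return Path(str(resources.files("pigplanim").joinpath("data").joinpath(name)))


def packaged_study_tables() -> list[StudyGroupSummary]:
    """The study's per-posture summary tables shipped with the package."""
    return load_study_tables(_packaged("table1_table2.csv"))


def packaged_correlations() -> list[CorrelationRecord]:
    """The study's per-posture weight-area Spearman coefficients."""
    return load_correlations(_packaged("table3.csv"))


def overall_weight_summary() -> dict[str, float]:
    """Pooled live-weight summary over all 1,583 images (Total row)."""
    with open(_packaged("table1_table2.csv"), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["posture"].strip().lower() == "total":
                return {
                    "n_images": int(row["n_images"]),
                    "weight_mean": float(row["weight_mean"]),
                    "weight_sd": float(row["weight_sd"]),
                    "weight_min": float(row["weight_min"]),
                    "weight_max": float(row["weight_max"]),
                }
    raise TableParseError("no Total row in packaged fixture")
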