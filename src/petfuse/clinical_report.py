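"""RECIST response tallies: counts and percentages per category.

Treatment response is categorized per RECIST into complete remission
(CR), partial remission (PR), stable disease (SD) and progressive
disease (PD), re-evaluated at treatment-cycle checkpoints.  This module
turns per-patient response records into the counts and percentages a
clinical efficacy table reports.  Percentages are rounded half-up to one
decimal; whole percentages display without the decimal ("37%", not
"37.0%").
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class ResponseRecord:
    patient_id: str
    cycle_checkpoint: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )


@dataclass(frozen=True)
class EfficacyTally:
    """Counts and half-up-rounded percentages per RECIST category."""

    checkpoint: int
    n: int
    counts: dict[str, int]
    percentages: dict[str, float]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (bankers' rounding would turn
    0.25 -> 0.2; clinical tables round it to 0.3)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def tally(records: list[ResponseRecord], checkpoint: int) -> EfficacyTally:
    """Tally response categories among patients evaluable at a checkpoint.

    Raises on duplicate patient ids at the checkpoint and on an empty
    record set.  Percentages are count / n * 100 rounded half-up to one
    decimal, so they sum to 100 up to rounding slack.
    """
    at_cp = [r for r in records if r.cycle_checkpoint == checkpoint]
    if not at_cp:
        raise ValueError(f"no records at checkpoint {checkpoint}")
    seen: set[str] = set()
    for r in at_cp:
        if r.patient_id in seen:
            raise ValueError(
                f"duplicate patient {r.patient_id!r} at checkpoint {checkpoint}"
            )
        seen.add(r.patient_id)
    n = len(at_cp)
    counts = {c: sum(1 for r in at_cp if r.category == c) for c in CATEGORIES}
    percentages = {c: round_half_up(counts[c] / n * 100.0, 1) for c in CATEGORIES}
    return EfficacyTally(checkpoint=checkpoint, n=n, counts=counts, percentages=percentages)


def format_percent(p: float) -> str:
    """'37' for whole percentages, '59.3' otherwise."""
    return f"{p:.0f}" if p == int(p) else f"{p:.1f}"


def format_tally(t: EfficacyTally) -> str:
    lines = [f"checkpoint {t.checkpoint} cycles, n={t.n}"]
    for c in CATEGORIES:
        lines.append(f"  {c}\t{t.counts[c]}\t{format_percent(t.percentages[c])}%")
    return "\n".join(lines)


def read_records_csv(path: str | Path) -> list[ResponseRecord]:
    """Load records from a CSV with columns patient_id, cycle_checkpoint,
    category."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ResponseRecord(
                    patient_id=row["patient_id"].strip(),
                    cycle_checkpoint=int(row["cycle_checkpoint"]),
                    category=row["category"].strip(),
                )
            )
    return records
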