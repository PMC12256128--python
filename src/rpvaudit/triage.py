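"""Expert-verification bookkeeping and summary statistics.

Flagged specimens go to taxonomists, who record one of four closed verdicts
— the specimen is mislabelled in the collection (``labelled_wrong``), the
classifier was mistaken (``pipeline_wrong``), only the digital portal record
is wrong (``portal_wrong``), or the case is undeterminable (``unknown``) —
plus a visual-difficulty score from 1 (obvious by eye) to 4 (impossible
visually; referred for genetic verification).  Genetic results reconcile
disputed cases: either confirming that the pipeline was wrong or
contradicting both the pipeline and the visual assessment.  This module
only ever reports sums over its input records; no study totals are built in.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .utils import round_half_up

VERDICTS = ("labelled_wrong", "pipeline_wrong", "portal_wrong", "unknown")
DIFFICULTIES = (1, 2, 3, 4)
GENETIC_OUTCOMES = ("confirms_pipeline_wrong", "contradicts_both")

VERIFICATION_FIELDS = ["specimen_id", "group", "verdict", "difficulty", "rpv", "notes"]
GENETIC_FIELDS = ["specimen_id", "group", "outcome", "barcode_recovered"]


@dataclass(frozen=True)
class VerificationRecord:
    specimen_id: str
    group: str
    verdict: str
    difficulty: int
    rpv: int
    notes: str = ""

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise SchemaError(
                f"specimen {self.specimen_id}: unknown verdict {self.verdict!r}"
            )
        if self.difficulty not in DIFFICULTIES:
            raise SchemaError(
                f"specimen {self.specimen_id}: difficulty must be one of {DIFFICULTIES}"
            )


@dataclass(frozen=True)
class GeneticRecord:
    specimen_id: str
    group: str
    outcome: str
    barcode_recovered: bool = True

    def __post_init__(self):
        if self.outcome not in GENETIC_OUTCOMES:
            raise SchemaError(
                f"specimen {self.specimen_id}: unknown outcome {self.outcome!r}"
            )


# -- CSV round trip ------------------------------------------------------------


def verification_records_to_csv(records, path=None) -> str:
    """Serialise records in a stable field order; returns the CSV text."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=VERIFICATION_FIELDS, lineterminator="\n")
    writer.writeheader()
    for r in records:
        writer.writerow(
            {
                "specimen_id": r.specimen_id, "group": r.group, "verdict": r.verdict,
                "difficulty": r.difficulty, "rpv": r.rpv, "notes": r.notes,
            }
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def verification_records_from_csv(source) -> list[VerificationRecord]:
    """Parse records from a path or CSV text."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else str(source)
    reader = csv.DictReader(io.StringIO(text))
    missing = set(VERIFICATION_FIELDS) - set(reader.fieldnames or [])
    if missing:
        raise SchemaError(f"verification CSV missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(reader):
        try:
            out.append(
                VerificationRecord(
                    specimen_id=row["specimen_id"], group=row["group"],
                    verdict=row["verdict"], difficulty=int(row["difficulty"]),
                    rpv=int(row["rpv"]), notes=row["notes"],
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"row {i + 2}: {exc}") from None
    return out


# -- summaries -----------------------------------------------------------------


def verification_summary(records) -> pd.DataFrame:
    """Contingency counts of verdicts per taxon group.

    Rows are groups (plus a ``total`` row), columns the four verdicts plus a
    ``total`` column; empty input gives an all-zero table.
    """
    table = pd.DataFrame(0, index=pd.Index([], name="group", dtype=object),
                         columns=list(VERDICTS), dtype=int)
    for r in records:
        if r.verdict not in VERDICTS:  # defensive; dataclass already validates
            raise SchemaError(f"specimen {r.specimen_id}: unknown verdict {r.verdict!r}")
        if r.group not in table.index:
            table.loc[r.group] = 0
        table.loc[r.group, r.verdict] += 1
    table = table.sort_index()
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def difficulty_rpv_histogram(records, rpv_bins) -> pd.DataFrame:
    """Counts of examined specimens by (difficulty, RPV bin).

    ``rpv_bins`` is a sequence of inclusive ``(lo, hi)`` intervals tiling
    ``[1, n_runs]``; each record lands in exactly one cell.
    """
    bins = [tuple(b) for b in rpv_bins]
    for (lo, hi), (lo2, _) in zip(bins, bins[1:]):
        if lo2 != hi + 1:
            raise ValueError("rpv_bins must tile the range without gaps")
    cols = [f"{lo:02d}–{hi}" for lo, hi in bins]
    mat = pd.DataFrame(0, index=pd.Index(DIFFICULTIES, name="difficulty"),
                       columns=cols, dtype=int)
    for r in records:
        for (lo, hi), col in zip(bins, cols):
            if lo <= r.rpv <= hi:
                mat.loc[r.difficulty, col] += 1
                break
        else:
            raise ValueError(f"rpv {r.rpv} outside the binned range")
    return mat


def genetic_reconciliation(records) -> pd.DataFrame:
    """Counts of genetic outcomes per taxon group, with totals."""
    table = pd.DataFrame(0, index=pd.Index([], name="group", dtype=object),
                         columns=list(GENETIC_OUTCOMES), dtype=int)
    for r in records:
        if r.group not in table.index:
            table.loc[r.group] = 0
        table.loc[r.group, r.outcome] += 1
    table = table.sort_index()
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def flagged_fraction(n_flagged: int, n_total: int) -> float:
    """Percentage of the collection flagged at least once, half-up 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_flagged <= n_total:
        raise ValueError("n_flagged must lie in [0, n_total]")
    return round_half_up(100.0 * n_flagged / n_total)


def triage_export(rpv_records: pd.DataFrame, path=None) -> pd.DataFrame:
    """Expert-facing template: all flagged specimens sorted by rpv descending,
    with empty verdict/difficulty/notes columns to fill in."""
    df = pd.DataFrame(rpv_records)
    out = df[df["rpv"] >= 1].sort_values(
        ["rpv", "specimen_id"], ascending=[False, True], kind="mergesort"
    )[["specimen_id", "current_label", "modal_predicted_label", "rpv",
       "eligible_runs", "rpv_per_eligible"]].copy()
    out["verdict"] = ""
    out["difficulty"] = ""
    out["notes"] = ""
    if path is not None:
        out.to_csv(path, index=False)
    return out.reset_index(drop=True)
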