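"""The reoccurring prediction value (RPV) statistic.

Across N resampled pipeline runs, each specimen is scored in every run whose
test pool contains it.  The RPV is the number of runs in which the
classifier assigned the specimen its *modal mispredicted* label — i.e. the
most frequent label that differs from the specimen's current catalog label.
A specimen predicted as species A in all 100 runs while labelled species B
has RPV 100.  Specimens whose mispredictions disagree across runs are kept
(with ``consistent=False``) rather than dropped, since triage reporting
needs every flagged specimen.  Because training/validation sampling varies
per run, the number of eligible (test) runs varies per specimen; the ratio
``rpv / eligible_runs`` is exported alongside the raw count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .utils import round_half_up

RPV_COLUMNS = [
    "specimen_id", "current_label", "modal_predicted_label",
    "rpv", "mismatch_runs", "eligible_runs", "consistent", "rpv_per_eligible",
]


@dataclass(frozen=True)
class RpvRecord:
    specimen_id: str
    current_label: str
    modal_predicted_label: str | None
    rpv: int
    mismatch_runs: int
    eligible_runs: int
    consistent: bool

    def __post_init__(self):
        if not 0 <= self.rpv <= self.mismatch_runs <= self.eligible_runs:
            raise ValueError(f"count ordering violated for {self.specimen_id}")
        if (self.rpv == 0) != (self.modal_predicted_label is None):
            raise ValueError("rpv = 0 iff modal_predicted_label is None")
        if self.consistent and self.rpv != self.mismatch_runs:
            raise ValueError("consistent records must have rpv == mismatch_runs")


def compute_rpv(prediction_records, partitions) -> pd.DataFrame:
    """Aggregate per-run prediction records into one RPV row per specimen.

    ``prediction_records``: DataFrame (or convertible) with columns
    ``run_id, specimen_id, current_label, predicted_label``.  ``partitions``:
    the :class:`~rpvaudit.catalog.RunPartition` list covering every run_id in
    the records; eligibility is counted from the partitions, and a record for
    a specimen that was in its own run's train/val set raises
    :class:`IntegrityError`.
    """
    df = pd.DataFrame(prediction_records)
    parts = {p.run_id: p for p in partitions}
    missing = set(df["run_id"].unique()) - set(parts)
    if missing:
        raise IntegrityError(f"records reference runs without partitions: {sorted(missing)}")

    # integrity: no record may come from a specimen's own train/val run
    for run_id, sub in df.groupby("run_id"):
        forbidden = parts[run_id].all_train_val()
        bad = set(sub["specimen_id"]) & forbidden
        if bad:
            raise IntegrityError(
                f"run {run_id} has predictions for train/val specimens: {sorted(bad)[:5]}"
            )

    eligible: dict[str, int] = {}
    for p in parts.values():
        for sid in p.all_test():
            eligible[sid] = eligible.get(sid, 0) + 1

    current = dict(zip(df["specimen_id"], df["current_label"]))
    mism = df[df["predicted_label"] != df["current_label"]]
    rows = []
    counts_by_sid = {
        sid: sub["predicted_label"].value_counts()
        for sid, sub in mism.groupby("specimen_id")
    }
    for sid in sorted(eligible):
        n_eligible = eligible[sid]
        vc = counts_by_sid.get(sid)
        if vc is None or vc.empty:
            modal, rpv_count, mismatch_runs, consistent = None, 0, 0, True
        else:
            top = int(vc.max())
            modal = min(lbl for lbl, n in vc.items() if n == top)
            rpv_count = top
            mismatch_runs = int(vc.sum())
            consistent = len(vc) == 1
        rec = RpvRecord(
            specimen_id=sid,
            current_label=current.get(sid, ""),
            modal_predicted_label=modal,
            rpv=rpv_count,
            mismatch_runs=mismatch_runs,
            eligible_runs=n_eligible,
            consistent=consistent,
        )
        rows.append(
            {
                **rec.__dict__,
                "rpv_per_eligible": rec.rpv / rec.eligible_runs if rec.eligible_runs else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=RPV_COLUMNS)


def flag(rpv_records: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Specimens with ``rpv`` strictly greater than ``threshold``,
    sorted by rpv descending then specimen_id ascending."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    df = pd.DataFrame(rpv_records)
    out = df[df["rpv"] > threshold].sort_values(
        ["rpv", "specimen_id"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def interval_table(
    rpv_records: pd.DataFrame,
    interval_width: int = 10,
    n_runs: int = 100,
    total_flagged_override: int | None = None,
) -> pd.DataFrame:
    """Histogram of flagged specimens (rpv >= 1) in RPV intervals.

    Rows tile ``[1, n_runs]`` in inclusive intervals of ``interval_width``
    ([91,100], ..., [11,20], [01,10] for the defaults, highest first), with
    percentages of the flagged total rounded half-up to 2 decimals.  The
    denominator defaults to the number of flagged specimens;
    ``total_flagged_override`` substitutes an externally stated total.
    """
    if n_runs % interval_width != 0:
        raise ValueError("interval_width must divide n_runs")
    df = pd.DataFrame(rpv_records)
    flagged = df[df["rpv"] >= 1] if len(df) else df
    if len(flagged) == 0 and total_flagged_override is None:
        warnings.warn("no flagged specimens; interval table is empty")
        return pd.DataFrame(columns=["interval", "lo", "hi", "count", "percentage"])
    edges = [(k * interval_width + 1, (k + 1) * interval_width)
             for k in range(n_runs // interval_width)]
    counts = [
        int(((flagged["rpv"] >= lo) & (flagged["rpv"] <= hi)).sum()) if len(flagged) else 0
        for lo, hi in edges
    ]
    denom = total_flagged_override if total_flagged_override is not None else len(flagged)
    rows = [
        {
            "interval": f"{lo:02d}–{hi}",
            "lo": lo,
            "hi": hi,
            "count": c,
            "percentage": round_half_up(100.0 * c / denom),
        }
        for (lo, hi), c in zip(edges, counts)
    ]
    return pd.DataFrame(rows[::-1]).reset_index(drop=True)


def interval_percentages(counts, denominator: int) -> list[float]:
    """Percentage arithmetic of an interval table given printed counts."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return [round_half_up(100.0 * c / denominator) for c in counts]


def brute_force_rpv(prediction_records, partitions) -> pd.DataFrame:
    """Independent plain-Python recount of the RPV aggregation.

    Kept deliberately naive (dict loops over raw rows) as an oracle for
    :func:`compute_rpv`; do not use on large logs.
    """
    df = pd.DataFrame(prediction_records)
    eligible: dict[str, int] = {}
    for p in partitions:
        for ids in p.test_ids.values():
            for sid in ids:
                eligible[sid] = eligible.get(sid, 0) + 1
    per_sid: dict[str, dict[str, int]] = {}
    current: dict[str, str] = {}
    for row in df.to_dict("records"):
        sid = row["specimen_id"]
        current[sid] = row["current_label"]
        if row["predicted_label"] != row["current_label"]:
            d = per_sid.setdefault(sid, {})
            d[row["predicted_label"]] = d.get(row["predicted_label"], 0) + 1
    rows = []
    for sid in sorted(eligible):
        d = per_sid.get(sid, {})
        if d:
            top = max(d.values())
            modal = sorted(lbl for lbl, n in d.items() if n == top)[0]
            mismatch = sum(d.values())
            consistent = len(d) == 1
        else:
            top, modal, mismatch, consistent = 0, None, 0, True
        rows.append(
            {
                "specimen_id": sid,
                "current_label": current.get(sid, ""),
                "modal_predicted_label": modal,
                "rpv": top,
                "mismatch_runs": mismatch,
                "eligible_runs": eligible[sid],
                "consistent": consistent,
                "rpv_per_eligible": top / eligible[sid] if eligible[sid] else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=RPV_COLUMNS)
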