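"""Specimen catalog loading, class-size filtering and per-run partitions.

The audit treats the *current* catalog label as the class of record — it is
the label under audit, never ground truth.  Classes below ``min_class_size``
specimens are dropped (too few images to train on), and each resampling run
draws ``sample_n`` specimens per class without replacement
(``train_n`` train + ``val_n`` validation); everything else forms that run's
test pool.  Two seed streams keep the protocol reproducible: one constant
model-initialisation seed, and per-run sampling seeds ``base_seed + run_id``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import EmptyResultError, IntegrityError, InvalidStateError, SchemaError

REQUIRED_COLUMNS = ("specimen_id", "current_label", "image_path", "group")


@dataclass
class SpecimenRecord:
    specimen_id: str
    current_label: str
    image_path: str
    group: str
    metadata: dict = field(default_factory=dict)


def load_catalog(path) -> list[SpecimenRecord]:
    """Read a catalog CSV; extra columns are preserved in ``metadata``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog {path} is missing columns: {missing}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].unique()
    if len(dupes):
        raise IntegrityError(f"duplicate specimen ids: {sorted(dupes)[:5]}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SpecimenRecord(
                specimen_id=d["specimen_id"],
                current_label=d["current_label"],
                image_path=d["image_path"],
                group=d["group"],
                metadata={c: d[c] for c in extra},
            )
        )
    return records


def class_counts(records) -> dict[str, int]:
    return dict(Counter(r.current_label for r in records))


def filter_classes(records, min_class_size: int):
    """Keep classes with at least ``min_class_size`` specimens (inclusive).

    Returns ``(kept_class_names, retained_records)``; raises
    :class:`EmptyResultError` (carrying the observed counts) when nothing
    survives.
    """
    if not records:
        raise ValueError("records must be non-empty")
    counts = class_counts(records)
    kept = sorted(c for c, n in counts.items() if n >= min_class_size)
    if not kept:
        raise EmptyResultError(
            f"no class reaches {min_class_size} specimens "
            f"(max observed: {max(counts.values())})",
            counts=counts,
        )
    kept_set = set(kept)
    retained = [r for r in records if r.current_label in kept_set]
    return kept, retained


@dataclass
class RunPartition:
    """Per-class train/validation/test membership for one run."""

    run_id: int
    sampling_seed: int
    train_ids: dict[str, list[str]]
    val_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]

    def all_train_val(self) -> set[str]:
        out: set[str] = set()
        for d in (self.train_ids, self.val_ids):
            for ids in d.values():
                out.update(ids)
        return out

    def all_test(self) -> set[str]:
        return {sid for ids in self.test_ids.values() for sid in ids}

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "sampling_seed": self.sampling_seed,
            "train_ids": self.train_ids,
            "val_ids": self.val_ids,
            "test_ids": self.test_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunPartition":
        return cls(**d)


def save_partitions(partitions, path) -> None:
    Path(path).write_text(
        json.dumps([p.to_dict() for p in partitions], indent=1, sort_keys=True)
    )


def load_partitions(path) -> list["RunPartition"]:
    return [RunPartition.from_dict(d) for d in json.loads(Path(path).read_text())]


def make_partition(
    records, class_names, run_id: int, config: PipelineConfig
) -> RunPartition:
    """Draw one run's train/val/test split.

    Per class, ``sample_n`` ids are drawn uniformly without replacement with
    seed ``base_seed + run_id``; the first ``train_n`` go to training, the
    next ``val_n`` to validation, the remainder to the test pool.  Sampling
    is over sorted ids, so the result is independent of record order.
    """
    by_class: dict[str, list[str]] = {}
    for r in records:
        by_class.setdefault(r.current_label, []).append(r.specimen_id)
    seed = config.base_seed + run_id
    rng = np.random.default_rng(seed)
    train, val, test = {}, {}, {}
    for cls in sorted(class_names):
        ids = sorted(by_class.get(cls, []))
        if len(ids) < config.sample_n:
            raise InvalidStateError(
                f"class {cls} has {len(ids)} specimens < sample_n={config.sample_n}; "
                "apply filter_classes first"
            )
        perm = rng.permutation(len(ids))
        ordered = [ids[i] for i in perm]
        train[cls] = ordered[: config.train_n]
        val[cls] = ordered[config.train_n : config.sample_n]
        test[cls] = sorted(ordered[config.sample_n :])
    return RunPartition(
        run_id=run_id, sampling_seed=seed, train_ids=train, val_ids=val, test_ids=test
    )
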