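"""The resampling audit loop: repeated training runs -> prediction log -> RPV.

:class:`RPVAuditor` is the in-memory, scikit-learn-shaped core: ``fit(X, y)``
takes specimen images and their *current* catalog labels, repeats the
sample/augment/train/score cycle ``n_runs`` times and aggregates the per-run
mispredictions into per-specimen RPV records.  :func:`run_pipeline` wraps it
for on-disk catalogs: load, filter, crop, audit, write the auditable outputs
(per-run partitions, prediction log, RPV table, interval report, manifest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from . import catalog as cat
from .classifier import SmallImageClassifier, _resize_to_input, f1_score
from .config import PipelineConfig
from .preprocess import augment, default_detector, detect_and_crop
from .rpv import compute_rpv, flag, interval_table
from .utils import load_image

PREDICTION_COLUMNS = [
    "run_id", "specimen_id", "current_label", "predicted_label", "confidence", "match",
]


class RPVAuditor(BaseEstimator):
    """Mislabel auditor over images ``X`` and current labels ``y``.

    Parameters mirror :class:`~rpvaudit.config.PipelineConfig`; ``classifier``
    is a prototype estimator cloned afresh for every run (so each run starts
    from the same seeded initial weights, while the sampled training subset
    changes with ``base_seed + run_id``).

    Fitted attributes
    -----------------
    prediction_records_ : DataFrame of every per-run test prediction.
    rpv_records_ : one row per specimen ever tested (see :mod:`rpvaudit.rpv`).
    partitions_ : the per-run train/val/test memberships.
    run_scores_ : per-run macro/micro F1 against the current labels.
    """

    def __init__(
        self,
        n_runs: int = 20,
        sample_n: int = 40,
        train_n: int = 30,
        val_n: int = 10,
        aug_copies: int = 4,
        base_seed: int = 0,
        model_init_seed: int = 1234,
        classifier: SmallImageClassifier | None = None,
        rotation_deg: float = 15.0,
        zoom_range: tuple = (0.9, 1.1),
        brightness_range: tuple = (1.0, 1.2),
    ):
        self.n_runs = n_runs
        self.sample_n = sample_n
        self.train_n = train_n
        self.val_n = val_n
        self.aug_copies = aug_copies
        self.base_seed = base_seed
        self.model_init_seed = model_init_seed
        self.classifier = classifier
        self.rotation_deg = rotation_deg
        self.zoom_range = zoom_range
        self.brightness_range = brightness_range

    def _partition_config(self) -> PipelineConfig:
        return PipelineConfig(
            min_class_size=self.sample_n,
            sample_n=self.sample_n,
            train_n=self.train_n,
            val_n=self.val_n,
            n_runs=self.n_runs,
            flag_threshold=0,
            interval_width=self.n_runs,
            base_seed=self.base_seed,
            model_init_seed=self.model_init_seed,
            aug_copies=self.aug_copies,
        )

    def fit(self, X, y, specimen_ids=None):
        y = np.asarray(y, dtype=object)
        if specimen_ids is None:
            specimen_ids = np.array([f"specimen-{i:06d}" for i in range(len(y))])
        specimen_ids = np.asarray(specimen_ids, dtype=object)
        if not (len(X) == len(y) == len(specimen_ids)):
            raise ValueError("X, y and specimen_ids must have equal lengths")
        if len(set(specimen_ids)) != len(specimen_ids):
            raise ValueError("specimen_ids must be unique")

        proto = self.classifier if self.classifier is not None else SmallImageClassifier()
        proto = clone(proto)
        proto.set_params(random_state=self.model_init_seed)

        # resize once; per-run augmentation then works on small arrays
        size = proto.get_params()["input_size"]
        X_small = _resize_to_input(X, size).reshape(len(y), size, size, 3)
        index = {sid: i for i, sid in enumerate(specimen_ids)}
        records = [
            cat.SpecimenRecord(sid, lbl, image_path="", group="")
            for sid, lbl in zip(specimen_ids, y)
        ]
        class_names = sorted(set(y))
        pcfg = self._partition_config()

        partitions, all_rows, run_scores = [], [], []
        for run_id in range(1, self.n_runs + 1):
            part = cat.make_partition(records, class_names, run_id, pcfg)
            partitions.append(part)
            aug_rng = np.random.default_rng(
                np.random.SeedSequence([self.base_seed, run_id, 7])
            )

            def gather(id_map):
                ids = [sid for c in sorted(id_map) for sid in id_map[c]]
                imgs = [X_small[index[sid]] for sid in ids]
                lbls = [y[index[sid]] for sid in ids]
                return ids, imgs, lbls

            _, tr_imgs, tr_lbls = gather(part.train_ids)
            _, va_imgs, va_lbls = gather(part.val_ids)
            te_ids, te_imgs, te_lbls = gather(part.test_ids)

            def augmented(imgs, lbls):
                out_i, out_l = list(imgs), list(lbls)
                for img, lbl in zip(imgs, lbls):
                    u8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)
                    for copy in augment(
                        u8, aug_rng, n_copies=self.aug_copies,
                        rotation_deg=self.rotation_deg,
                        zoom_range=self.zoom_range,
                        brightness_range=self.brightness_range,
                    ):
                        out_i.append(copy.astype(np.float64) / 255.0)
                        out_l.append(lbl)
                return out_i, out_l

            tr_imgs, tr_lbls = augmented(tr_imgs, tr_lbls)
            va_imgs, va_lbls = augmented(va_imgs, va_lbls)

            model = clone(proto)
            model.fit(tr_imgs, tr_lbls, X_val=va_imgs, y_val=va_lbls)

            probs = model.predict_proba(te_imgs)
            pred_idx = probs.argmax(axis=1)
            run_rows = pd.DataFrame(
                {
                    "run_id": run_id,
                    "specimen_id": te_ids,
                    "current_label": te_lbls,
                    "predicted_label": model.classes_[pred_idx],
                    "confidence": probs[np.arange(len(te_ids)), pred_idx],
                }
            )
            run_rows["match"] = run_rows["predicted_label"] == run_rows["current_label"]
            all_rows.append(run_rows)
            rep = f1_score(run_rows)
            run_scores.append(
                {"run_id": run_id, "macro_f1": rep.macro_f1, "micro_f1": rep.micro_f1}
            )

        self.classes_ = np.array(class_names, dtype=object)
        self.partitions_ = partitions
        self.prediction_records_ = pd.concat(all_rows, ignore_index=True)
        self.run_scores_ = pd.DataFrame(run_scores)
        self.rpv_records_ = compute_rpv(self.prediction_records_, partitions)
        return self

    def flag(self, threshold: int) -> pd.DataFrame:
        return flag(self.rpv_records_, threshold)

    @property
    def mislabel_score_(self) -> pd.Series:
        """rpv / eligible_runs per specimen — the ranking statistic."""
        return self.rpv_records_.set_index("specimen_id")["rpv_per_eligible"]


@dataclass
class PipelineResult:
    out_dir: Path
    rpv_records: pd.DataFrame
    prediction_records: pd.DataFrame
    run_scores: pd.DataFrame
    interval: pd.DataFrame
    flagged: pd.DataFrame
    manifest: dict


def _format_predictions(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["confidence"] = out["confidence"].map(lambda c: f"{c:.6f}")
    return out


def run_pipeline(
    catalog_path,
    images_root,
    config: PipelineConfig,
    out_dir,
    crop: bool = True,
    progress: bool = False,
) -> PipelineResult:
    """Execute the full audit for one catalog and write auditable outputs.

    Writes ``partitions.json``, ``predictions.csv``, ``rpv.csv``,
    ``interval_table.csv``, ``flagged.csv`` and ``manifest.json`` under
    ``out_dir``; outputs are byte-identical across reruns with the same
    config and seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images_root = Path(images_root)

    records = cat.load_catalog(catalog_path)
    kept, retained = cat.filter_classes(records, config.min_class_size)

    ids, images, labels = [], [], []
    for r in retained:
        img = load_image(images_root / r.image_path)
        if crop:
            img, _ = detect_and_crop(
                img,
                detector=lambda im: default_detector(im, config.background_tolerance),
                margin_fraction=config.crop_margin,
            )
        ids.append(r.specimen_id)
        images.append(img)
        labels.append(r.current_label)
        if progress and len(ids) % 200 == 0:
            print(f"  loaded {len(ids)} images", flush=True)

    auditor = RPVAuditor(
        n_runs=config.n_runs,
        sample_n=config.sample_n,
        train_n=config.train_n,
        val_n=config.val_n,
        aug_copies=config.aug_copies,
        base_seed=config.base_seed,
        model_init_seed=config.model_init_seed,
        classifier=SmallImageClassifier(
            input_size=config.input_size,
            hidden_sizes=tuple(config.hidden_sizes),
            frozen_bottom_layers=config.frozen_bottom_layers,
            phase1_epochs=config.phase1_epochs,
            max_epochs=config.max_epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            random_state=config.model_init_seed,
        ),
        rotation_deg=config.rotation_deg,
        zoom_range=config.zoom_range,
        brightness_range=config.brightness_range,
    )
    auditor.fit(images, labels, specimen_ids=ids)

    interval = interval_table(
        auditor.rpv_records_, config.interval_width, config.n_runs
    )
    flagged = flag(auditor.rpv_records_, config.flag_threshold)

    cat.save_partitions(auditor.partitions_, out_dir / "partitions.json")
    _format_predictions(auditor.prediction_records_).to_csv(
        out_dir / "predictions.csv", index=False
    )
    rpv_out = auditor.rpv_records_.copy()
    rpv_out["rpv_per_eligible"] = rpv_out["rpv_per_eligible"].map(lambda v: f"{v:.6f}")
    rpv_out.to_csv(out_dir / "rpv.csv", index=False)
    interval.to_csv(out_dir / "interval_table.csv", index=False)
    flagged_out = flagged.copy()
    flagged_out["rpv_per_eligible"] = flagged_out["rpv_per_eligible"].map(
        lambda v: f"{v:.6f}"
    )
    flagged_out.to_csv(out_dir / "flagged.csv", index=False)
    auditor.run_scores_.to_csv(
        out_dir / "run_scores.csv", index=False, float_format="%.6f"
    )

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_runs": config.n_runs,
        "base_seed": config.base_seed,
        "model_init_seed": config.model_init_seed,
        "classes": kept,
        "n_specimens": len(ids),
        "n_flagged_at_least_once": int((auditor.rpv_records_["rpv"] >= 1).sum()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        out_dir=out_dir,
        rpv_records=auditor.rpv_records_,
        prediction_records=auditor.prediction_records_,
        run_scores=auditor.run_scores_,
        interval=interval,
        flagged=flagged,
        manifest=manifest,
    )
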