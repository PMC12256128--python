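"""The desk-scale recovery study: fixed conditions, measured outcomes.

One function runs the whole method end to end under the package's reference
conditions — 6 species (2 confusable pairs), 80 images per species, 3% of
labels swapped (preferentially to the confusable partner), 20 resampling
runs of 40 sampled / 30 train / 10 validation per class — and scores how
well the RPV statistic recovers the injected swaps:

* ``auc``: ROC-AUC of ranking specimens by rpv / eligible_runs against the
  injected-swap indicator;
* ``flag_precision``: among specimens with rpv / eligible_runs >= 0.8, the
  fraction that are injected swaps;
* ``flag_recall``: the fraction of injected swaps so flagged.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .auditor import RPVAuditor
from .classifier import SmallImageClassifier
from .preprocess import detect_and_crop
from .synthetic import generate_dataset, make_species_set
from .utils import load_image

# reference study conditions (kept fixed; see docs/methods.md)
N_SPECIES = 6
N_CONFUSABLE_PAIRS = 2
N_PER_SPECIES = 80
MISLABEL_RATE = 0.03
N_RUNS = 20
SAMPLE_N, TRAIN_N, VAL_N = 40, 30, 10
RATIO_FLAG_THRESHOLD = 0.8


@dataclass
class RecoveryOutcome:
    auc: float
    flag_precision: float
    flag_recall: float
    n_flagged: int
    n_injected: int
    mean_macro_f1: float
    rpv_records: "object"
    injected_ids: set


def recovery_experiment(
    dataset_seed: int,
    sampling_seed: int,
    model_init_seed: int = 1234,
    n_runs: int = N_RUNS,
    workdir=None,
) -> RecoveryOutcome:
    """Generate -> crop -> audit -> score one replicate of the study."""
    specs = make_species_set(N_SPECIES, N_CONFUSABLE_PAIRS, seed=dataset_seed)

    def _run(out_dir) -> RecoveryOutcome:
        ds = generate_dataset(
            specs, N_PER_SPECIES, MISLABEL_RATE, seed=dataset_seed, out_dir=out_dir
        )
        root = ds.catalog_path.parent
        from .catalog import load_catalog

        ids, imgs, labels = [], [], []
        for rec in load_catalog(ds.catalog_path):
            img, _ = detect_and_crop(load_image(root / rec.image_path))
            ids.append(rec.specimen_id)
            imgs.append(img)
            labels.append(rec.current_label)

        auditor = RPVAuditor(
            n_runs=n_runs, sample_n=SAMPLE_N, train_n=TRAIN_N, val_n=VAL_N,
            base_seed=sampling_seed, model_init_seed=model_init_seed,
            classifier=SmallImageClassifier(
                max_epochs=40, random_state=model_init_seed
            ),
        )
        auditor.fit(imgs, labels, specimen_ids=ids)

        injected = {sid for sid, _, _ in ds.ground_truth.injected_mislabels}
        rr = auditor.rpv_records_
        y = rr["specimen_id"].isin(injected).to_numpy().astype(int)
        auc = float(roc_auc_score(y, rr["rpv_per_eligible"]))
        flagged = rr[rr["rpv_per_eligible"] >= RATIO_FLAG_THRESHOLD]
        tp = int(flagged["specimen_id"].isin(injected).sum())
        return RecoveryOutcome(
            auc=auc,
            flag_precision=tp / len(flagged) if len(flagged) else 1.0,
            flag_recall=tp / len(injected) if injected else 1.0,
            n_flagged=int(len(flagged)),
            n_injected=len(injected),
            mean_macro_f1=float(auditor.run_scores_["macro_f1"].mean()),
            rpv_records=rr,
            injected_ids=injected,
        )

    if workdir is not None:
        return _run(Path(workdir))
    with tempfile.TemporaryDirectory() as td:
        return _run(Path(td))


def replicate_recovery(seed: int, n_replicates: int = 5) -> list[RecoveryOutcome]:
    """Run ``n_replicates`` seeded replicates (fresh species set, dataset and
    sampling seeds per replicate; one shared model-initialisation seed)."""
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**20)
    return [
        recovery_experiment(
            dataset_seed=base + 1000 * k, sampling_seed=base + 1000 * k + 500
        )
        for k in range(n_replicates)
    ]
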