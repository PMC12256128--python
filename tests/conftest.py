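"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest

import rpvaudit as ra
from rpvaudit.classifier import SmallImageClassifier
from rpvaudit.preprocess import detect_and_crop
from rpvaudit.utils import load_image


@pytest.fixture(scope="session")
def species6():
    """Six species, two confusable pairs — the standard study layout."""
    return ra.make_species_set(6, 2, seed=1)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """4 species x 30 images with 5% injected mislabels (fast unit-test scale)."""
    out = tmp_path_factory.mktemp("small_ds")
    specs = ra.make_species_set(4, 1, seed=3)
    ds = ra.generate_dataset(specs, 30, 0.05, seed=5, out_dir=out)
    return ds


def load_cropped(ds):
    """Catalog images of a generated dataset, detection-cropped."""
    root = ds.catalog_path.parent
    records = ra.load_catalog(ds.catalog_path)
    ids, imgs, labels = [], [], []
    for rec in records:
        img, _ = detect_and_crop(load_image(root / rec.image_path))
        ids.append(rec.specimen_id)
        imgs.append(img)
        labels.append(rec.current_label)
    return ids, imgs, labels


@pytest.fixture(scope="session")
def small_dataset_arrays(small_dataset):
    return load_cropped(small_dataset)


@pytest.fixture(scope="session")
def two_class_training(species6):
    """Well-separated two-class image arrays for classifier contract tests."""
    rng = np.random.default_rng(42)
    a, b = species6[4], species6[5]  # non-confusable pair
    images, labels = [], []
    for spec in (a, b):
        for _ in range(30):
            img, _ = ra.render_specimen(spec, rng, canvas_size=64)
            img, _ = detect_and_crop(img)
            images.append(img)
            labels.append(spec.species_name)
    idx = rng.permutation(len(images))
    images = [images[i] for i in idx]
    labels = [labels[i] for i in idx]
    return (images[:40], labels[:40], images[40:], labels[40:])


@pytest.fixture(scope="session")
def trained_two_class(two_class_training):
    tr_x, tr_y, va_x, va_y = two_class_training
    clf = SmallImageClassifier(
        input_size=32, hidden_sizes=(64, 32), learning_rate=3e-3,
        max_epochs=30, random_state=7,
    )
    clf.fit(tr_x, tr_y, X_val=va_x, y_val=va_y)
    return clf
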