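"""Procedural specimen images with known ground truth.

Real collection audits run on photographs of pinned specimens; to make every
stage of the pipeline testable at desk scale this module renders stylised
"specimens" — mirrored wing ellipses with a sinusoidal stripe texture on a
uniform background, optionally with a text-like label strip below the
specimen (the part of real images that distracts classifiers before
cropping).  A species is fully described by four visual parameters
(:class:`SpeciesSpec`); confusable species pairs differ by deliberately
small parameter deltas, emulating closely related taxa.  A controlled
fraction of catalog labels is swapped (preferentially to the confusable
partner) and recorded in :class:`GroundTruth`, so detection performance can
be measured exactly.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import round_half_up, save_png

# --- rendering constants (documented jitter bands) ---------------------------
BACKGROUND_RGB = (206, 206, 198)  # uniform board colour behind every specimen
SCALE_JITTER = 0.10        # per-specimen size multiplier: uniform in 1 +/- 0.10
ROTATION_JITTER_DEG = 5.0  # per-specimen rotation: uniform in +/- 5 degrees
HUE_JITTER_DEG = 5.0       # per-specimen hue shift: uniform in +/- 5 degrees
CENTER_JITTER = 0.03       # centre offset, fraction of canvas per axis
# Bounding-box area band implied by the jitters above: the un-jittered box is
# (nominal_scale * canvas)^2 by construction; size jitter contributes
# [0.81, 1.21]x and a 5-degree rotation can grow each side by up to
# cos(5) + sin(5) ~ 1.083.  Rasterisation adds at most a pixel per side.
BBOX_AREA_BAND = (0.75, 1.45)  # as a multiple of (nominal_scale * canvas)^2

# Confusable partners differ by these deltas only.  Each delta must exceed
# the ambiguity band its parameter's per-specimen jitter induces — otherwise
# partner classes overlap and no classifier could separate them: hue jitter
# is +/-5 deg, so partner hue supports are disjoint only for a delta > 10 deg;
# size jitter of +/-10% perturbs the post-crop apparent stripe frequency by
# ~10%, so the stripe delta must clear that.  Both deltas stay far below the
# >= 48 deg hue / >= 0.8 cycle spacing of non-confusable species.
CONFUSABLE_HUE_DELTA = 12.0
CONFUSABLE_STRIPE_DELTA = 1.0

MISLABEL_TO_PARTNER_PROB = 0.8  # injected swaps go to the confusable partner


@dataclass(frozen=True)
class SpeciesSpec:
    """Visual identity of one synthetic species."""

    species_name: str
    body_hue: float            # degrees in [0, 360)
    stripe_frequency: float    # stripe cycles per image width, > 0
    wing_aspect: float         # wing height/width balance, > 0
    nominal_scale: float       # specimen extent as a fraction of canvas, (0, 1]
    confusable_with: str | None = None

    def __post_init__(self):
        if not 0 <= self.body_hue < 360:
            raise ValueError("body_hue must lie in [0, 360)")
        if self.stripe_frequency <= 0 or self.wing_aspect <= 0:
            raise ValueError("stripe_frequency and wing_aspect must be > 0")
        if not 0 < self.nominal_scale <= 1:
            raise ValueError("nominal_scale must lie in (0, 1]")


def parameter_distance(a: SpeciesSpec, b: SpeciesSpec) -> float:
    """Normalised visual distance between two species specs.

    Each term is scaled by the spread the generator uses for that parameter,
    so confusable pairs (hue +10deg, stripe +0.5) come out well below any
    non-confusable pair.
    """
    dh = abs(a.body_hue - b.body_hue)
    dh = min(dh, 360 - dh)
    return (
        dh / 180.0
        + abs(a.stripe_frequency - b.stripe_frequency) / 6.0
        + abs(a.wing_aspect - b.wing_aspect) / 0.3
        + abs(a.nominal_scale - b.nominal_scale) / 0.15
    )


@dataclass
class GroundTruth:
    """True label per specimen plus the record of injected swaps."""

    true_labels: dict[str, str]
    assigned_labels: dict[str, str]
    injected_mislabels: list[tuple[str, str, str]] = field(default_factory=list)
    # tuples of (specimen_id, true_label, assigned_label)

    def __post_init__(self):
        injected_ids = {sid for sid, _, _ in self.injected_mislabels}
        for sid, true, assigned in self.injected_mislabels:
            if true == assigned:
                raise ValueError(f"injected specimen {sid} has unchanged label")
        for sid, true in self.true_labels.items():
            if sid not in injected_ids and self.assigned_labels[sid] != true:
                raise ValueError(f"non-injected specimen {sid} has a swapped label")

    def is_injected(self, specimen_id: str) -> bool:
        return any(sid == specimen_id for sid, _, _ in self.injected_mislabels)

    def to_json(self, path) -> None:
        payload = {
            sid: {"true_label": t, "assigned_label": self.assigned_labels[sid]}
            for sid, t in sorted(self.true_labels.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        true = {sid: d["true_label"] for sid, d in payload.items()}
        assigned = {sid: d["assigned_label"] for sid, d in payload.items()}
        injected = [
            (sid, d["true_label"], d["assigned_label"])
            for sid, d in payload.items()
            if d["assigned_label"] != d["true_label"]
        ]
        return cls(true, assigned, injected)


def make_species_set(
    n_species: int, n_confusable_pairs: int, seed: int
) -> list[SpeciesSpec]:
    """Draw ``n_species`` visually distinct species, the first
    ``2 * n_confusable_pairs`` of which form confusable pairs.

    Hues and stripe frequencies are evenly spaced (with a seeded hue offset
    and a seeded stripe ordering) so non-confusable species are always far
    apart in at least those two parameters; a confusable partner reuses its
    mate's parameters shifted by the small deltas above.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_confusable_pairs < 0 or 2 * n_confusable_pairs > n_species:
        raise ValueError("2 * n_confusable_pairs must not exceed n_species")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0, 360)
    stripe_levels = 3.0 + 4.0 * rng.permutation(n_species) / max(1, n_species - 1)
    specs: list[SpeciesSpec] = []
    for i in range(n_species):
        specs.append(
            SpeciesSpec(
                species_name=f"species_{i:02d}",
                body_hue=float((offset + 360.0 * i / n_species) % 360),
                stripe_frequency=float(stripe_levels[i]),
                wing_aspect=float(rng.uniform(0.65, 0.95)),
                nominal_scale=float(rng.uniform(0.45, 0.60)),
            )
        )
    for p in range(n_confusable_pairs):
        i, j = 2 * p, 2 * p + 1
        a = specs[i]
        specs[i] = SpeciesSpec(
            a.species_name, a.body_hue, a.stripe_frequency, a.wing_aspect,
            a.nominal_scale, confusable_with=specs[j].species_name,
        )
        specs[j] = SpeciesSpec(
            specs[j].species_name,
            float((a.body_hue + CONFUSABLE_HUE_DELTA) % 360),
            a.stripe_frequency + CONFUSABLE_STRIPE_DELTA,
            a.wing_aspect,
            a.nominal_scale,
            confusable_with=a.species_name,
        )
    return specs


def _hsv_to_rgb255(h_deg: float, s: float, v: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb((h_deg % 360) / 360.0, s, v)
    return np.array([round(r * 255), round(g * 255), round(b * 255)], dtype=np.uint8)


def render_specimen(
    spec: SpeciesSpec,
    rng_state,
    canvas_size: int = 128,
    with_label_strip: bool = False,
):
    """Render one specimen; returns ``(image, bounding_box)``.

    The background is exactly uniform (:data:`BACKGROUND_RGB`) and the
    returned box is the exact tight axis-aligned bounding box of the rendered
    foreground, computed from the analytic foreground mask.  When
    ``with_label_strip`` is set, a text-like strip is drawn below the
    specimen, always outside its bounding box.
    """
    if canvas_size < 32:
        raise ValueError("canvas_size must be >= 32")
    from .preprocess import BoundingBox  # local import to avoid a cycle

    rng = np.random.default_rng(rng_state) if isinstance(rng_state, (int, np.integer)) else rng_state
    c = canvas_size
    size_mult = 1.0 + rng.uniform(-SCALE_JITTER, SCALE_JITTER)
    theta = np.deg2rad(rng.uniform(-ROTATION_JITTER_DEG, ROTATION_JITTER_DEG))
    hue_jit = rng.uniform(-HUE_JITTER_DEG, HUE_JITTER_DEG)
    cx = c * (0.5 + rng.uniform(-CENTER_JITTER, CENTER_JITTER))
    cy = c * (0.45 + rng.uniform(-CENTER_JITTER, CENTER_JITTER))

    size = spec.nominal_scale * c * size_mult
    # normalise so the un-rotated bounding box is size x size regardless of aspect
    width = size / np.sqrt(spec.wing_aspect)
    height = size * np.sqrt(spec.wing_aspect)

    yy, xx = np.mgrid[0:c, 0:c].astype(np.float64)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)

    aw, bw = width / 4.0, height / 2.0  # wing semi-axes
    wings = (((u - width / 4) / aw) ** 2 + (v / bw) ** 2 <= 1.0) | (
        ((u + width / 4) / aw) ** 2 + (v / bw) ** 2 <= 1.0
    )
    body = ((u / (0.06 * size)) ** 2 + (v / (0.45 * height)) ** 2) <= 1.0
    mask = wings | body

    stripes = np.sin(2 * np.pi * spec.stripe_frequency * u / c) > 0
    hue = spec.body_hue + hue_jit
    light = _hsv_to_rgb255(hue, 0.85, 0.85)
    dark = _hsv_to_rgb255(hue, 0.85, 0.55)
    body_col = _hsv_to_rgb255(hue, 0.30, 0.25)

    image = np.empty((c, c, 3), dtype=np.uint8)
    image[:, :] = BACKGROUND_RGB
    image[wings & stripes] = light
    image[wings & ~stripes] = dark
    image[body] = body_col

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = BoundingBox(
        x_min=int(cols[0]), y_min=int(rows[0]),
        x_max=int(cols[-1]) + 1, y_max=int(rows[-1]) + 1,
    )

    if with_label_strip:
        y0, y1 = int(0.88 * c), min(int(0.96 * c), c)
        x0, x1 = int(0.10 * c), int(0.90 * c)
        image[y0:y1, x0:x1] = 245  # paper label
        # pseudo-text: short dark dashes on alternating lines
        for row in range(y0 + 1, y1 - 1, 2):
            n_dashes = int(rng.integers(4, 9))
            starts = rng.integers(x0 + 1, max(x0 + 2, x1 - 4), size=n_dashes)
            for s in starts:
                image[row, s : min(s + int(rng.integers(2, 5)), x1 - 1)] = 40
        if box.y_max > y0:
            raise AssertionError(
                "label strip would overlap the specimen; nominal_scale too large"
            )
    return image, box


@dataclass
class GeneratedDataset:
    """Paths and ground truth of one generated dataset."""

    catalog_path: Path
    images_dir: Path
    ground_truth: GroundTruth
    ground_truth_path: Path
    species: list[SpeciesSpec]


def generate_dataset(
    specs: list[SpeciesSpec],
    n_per_species: int,
    mislabel_rate: float,
    seed: int,
    out_dir,
    canvas_size: int = 128,
    with_label_strip: bool = True,
    group: str = "synthetic",
) -> GeneratedDataset:
    """Render ``n_per_species`` images per species, inject label swaps, and
    write catalog (CSV), images (PNG) and ground truth (JSON).

    Exactly ``round_half_up(mislabel_rate * total)`` specimens get a catalog
    label different from their true species; when the true species has a
    confusable partner the swap goes there with probability
    :data:`MISLABEL_TO_PARTNER_PROB`, otherwise to a uniformly drawn other
    species.  Fully deterministic for a fixed seed.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    if not 0 <= mislabel_rate < 1:
        raise ValueError("mislabel_rate must lie in [0, 1)")
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    images_dir.mkdir(parents=True, exist_ok=True)

    total = len(specs) * n_per_species
    ss = np.random.SeedSequence(seed)
    render_seeds = ss.spawn(total)
    inject_rng = np.random.default_rng(ss.spawn(1)[0])

    specimen_ids, true_labels, paths = [], {}, {}
    k = 0
    for spec in specs:
        for i in range(n_per_species):
            sid = f"{spec.species_name}-{i:04d}"
            img, _ = render_specimen(
                spec, np.random.default_rng(render_seeds[k]),
                canvas_size=canvas_size, with_label_strip=with_label_strip,
            )
            rel = f"images/{sid}.png"
            save_png(out_dir / rel, img)
            specimen_ids.append(sid)
            true_labels[sid] = spec.species_name
            paths[sid] = rel
            k += 1

    n_inject = int(round_half_up(mislabel_rate * total, 0))
    by_name = {s.species_name: s for s in specs}
    names = sorted(by_name)
    assigned = dict(true_labels)
    injected: list[tuple[str, str, str]] = []
    chosen = inject_rng.choice(total, size=n_inject, replace=False) if n_inject else []
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        sid = specimen_ids[idx]
        true = true_labels[sid]
        partner = by_name[true].confusable_with
        if partner is not None and inject_rng.random() < MISLABEL_TO_PARTNER_PROB:
            target = partner
        else:
            others = [n for n in names if n != true]
            target = others[int(inject_rng.integers(len(others)))]
        assigned[sid] = target
        injected.append((sid, true, target))

    catalog = pd.DataFrame(
        {
            "specimen_id": specimen_ids,
            "current_label": [assigned[s] for s in specimen_ids],
            "image_path": [paths[s] for s in specimen_ids],
            "group": group,
        }
    )
    catalog_path = out_dir / "catalog.csv"
    catalog.to_csv(catalog_path, index=False)

    gt = GroundTruth(true_labels, assigned, injected)
    gt_path = out_dir / "ground_truth.json"
    gt.to_json(gt_path)
    return GeneratedDataset(catalog_path, images_dir, gt, gt_path, list(specs))
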