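"""Small shared helpers: half-up rounding, background estimation, PNG I/O."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from PIL import Image


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero.

    Percentages in reports are conventionally rounded half-up (so 0.125 ->
    0.13), which differs from Python's banker's rounding.  Goes through
    ``Decimal(str(x))`` so the decision is made on the printed decimal value,
    not on binary float artefacts.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def estimate_background(image: np.ndarray) -> np.ndarray:
    """Modal colour of the image border, as a length-3 uint8 vector.

    Specimen photographs (and the synthetic renders) have a dominant uniform
    background that always touches the border; the mode over border pixels is
    robust to the specimen touching an edge.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[:, :, None]
    border = np.concatenate(
        [img[0, :], img[-1, :], img[:, 0], img[:, -1]], axis=0
    )
    colours, counts = np.unique(border.reshape(-1, img.shape[2]), axis=0, return_counts=True)
    return colours[int(np.argmax(counts))]


def save_png(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="PNG")


def load_image(path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def stable_hash(obj) -> str:
    """Short sha256 of a JSON-serialisable object with sorted keys."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
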