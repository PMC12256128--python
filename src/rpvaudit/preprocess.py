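"""Detection-based cropping, augmentation and the attention-QC metric.

Uncropped collection photographs contain labels, pins and scale bars that a
classifier can latch onto; cropping each image to the detected specimen
removes most of that signal.  The detector is a pluggable contract
(``image -> [(BoundingBox, confidence)]``); :func:`default_detector` is a
connected-component detector adequate for images with a dominant uniform
background.  The attention metric quantifies how much of a saliency map
falls inside the specimen's bounding box — the check that originally
motivated cropping.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from skimage import measure, transform

from .utils import estimate_background

DEFAULT_CROP_MARGIN = 0.05
DEFAULT_BACKGROUND_TOLERANCE = 12

# augmentation draw ranges ("rotations, zooms and slight brightening";
# brightening is an increase only)
DEFAULT_ROTATION_DEG = 15.0
DEFAULT_ZOOM_RANGE = (0.9, 1.1)
DEFAULT_BRIGHTNESS_RANGE = (1.0, 1.2)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open ``[min, max)`` pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box {self}")
        if min(self.x_min, self.y_min) < 0:
            raise ValueError(f"negative coordinate in {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def validate_within(self, height: int, width: int) -> None:
        if self.x_max > width or self.y_max > height:
            raise ValueError(f"{self} exceeds image bounds {width}x{height}")

    def expand(self, margin_fraction: float, height: int, width: int) -> "BoundingBox":
        """Grow by ``margin_fraction`` of the box size per side, clipped."""
        dx = int(round(margin_fraction * self.width))
        dy = int(round(margin_fraction * self.height))
        return BoundingBox(
            max(0, self.x_min - dx),
            max(0, self.y_min - dy),
            min(width, self.x_max + dx),
            min(height, self.y_max + dy),
        )


def default_detector(
    image: np.ndarray, background_tolerance: int = DEFAULT_BACKGROUND_TOLERANCE
):
    """Largest-connected-component detector for uniform-background images.

    Foreground is any pixel whose colour differs from the modal border
    colour by more than ``background_tolerance`` in any channel.  Returns
    one detection per connected component, largest area first, with
    confidence = component area / image area.
    """
    img = np.asarray(image)
    bg = estimate_background(img).astype(np.int16)
    chan = img if img.ndim == 3 else img[:, :, None]
    fg = (np.abs(chan.astype(np.int16) - bg) > background_tolerance).any(axis=2)
    if not fg.any():
        return []
    labels = measure.label(fg, connectivity=2)
    total = float(img.shape[0] * img.shape[1])
    detections = []
    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        detections.append(
            (BoundingBox(x0, y0, x1, y1), region.area / total)
        )
    # largest area first; ties by top-left-most box
    detections.sort(key=lambda d: (-d[0].area, d[0].y_min, d[0].x_min))
    return detections


def detect_and_crop(
    image: np.ndarray,
    detector=None,
    margin_fraction: float = DEFAULT_CROP_MARGIN,
):
    """Crop to the best detection, expanded by ``margin_fraction`` per side.

    The winning detection has the highest confidence; ties go to the larger
    area, then the top-left-most box.  If the detector returns nothing the
    full image is returned and the provenance record carries
    ``fallback=True``.

    Returns ``(cropped_image, provenance_dict)``.
    """
    if margin_fraction < 0:
        raise ValueError("margin_fraction must be >= 0")
    img = np.asarray(image)
    h, w = img.shape[:2]
    detector = detector or default_detector
    detections = list(detector(img))
    if not detections:
        return img, {
            "box": None, "expanded_box": None, "confidence": None,
            "fallback": True, "margin_fraction": margin_fraction,
        }
    for box, _ in detections:
        box.validate_within(h, w)
    box, conf = min(
        detections, key=lambda d: (-d[1], -d[0].area, d[0].y_min, d[0].x_min)
    )
    expanded = box.expand(margin_fraction, h, w)
    crop = img[expanded.y_min : expanded.y_max, expanded.x_min : expanded.x_max]
    return crop, {
        "box": asdict(box), "expanded_box": asdict(expanded),
        "confidence": float(conf), "fallback": False,
        "margin_fraction": margin_fraction,
    }


def _random_affine_params(rng, rotation_deg, zoom_range):
    theta = np.deg2rad(rng.uniform(-rotation_deg, rotation_deg))
    zoom = rng.uniform(*zoom_range)
    return theta, zoom


def _warp_about_center(image_f: np.ndarray, theta: float, zoom: float) -> np.ndarray:
    """Rotate by ``theta`` and zoom by ``zoom`` about the image centre."""
    h, w = image_f.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # output -> input mapping: rotate by -theta, scale by 1/zoom
    cos, sin = np.cos(-theta), np.sin(-theta)
    s = 1.0 / zoom
    m = np.array(
        [
            [s * cos, -s * sin, cx - s * (cos * cx - sin * cy)],
            [s * sin, s * cos, cy - s * (sin * cx + cos * cy)],
            [0, 0, 1],
        ]
    )
    tform = transform.AffineTransform(matrix=m)
    return transform.warp(
        image_f, tform, order=1, mode="constant", cval=0.0, preserve_range=True
    )


def augment(
    image: np.ndarray,
    rng_state,
    n_copies: int = 4,
    rotation_deg: float = DEFAULT_ROTATION_DEG,
    zoom_range=DEFAULT_ZOOM_RANGE,
    brightness_range=DEFAULT_BRIGHTNESS_RANGE,
    fill=None,
):
    """Produce ``n_copies`` independently jittered variants of ``image``.

    Each copy applies one random rotation, zoom and brightness multiplier.
    Rotation/zoom gaps are filled with ``fill`` (default: the modal border
    colour), output size equals input size, and results are deterministic
    for a fixed generator state.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    rng = np.random.default_rng(rng_state) if isinstance(rng_state, (int, np.integer)) else rng_state
    img = np.asarray(image)
    if fill is None:
        fill = estimate_background(img)
    fill = np.asarray(fill, dtype=np.float64)
    base = img.astype(np.float64) - fill  # warp in fill-relative space -> cval 0 == fill
    out = []
    for _ in range(n_copies):
        theta, zoom = _random_affine_params(rng, rotation_deg, zoom_range)
        bright = rng.uniform(*brightness_range)
        warped = _warp_about_center(base, theta, zoom) + fill
        out.append(np.clip(warped * bright, 0, 255).astype(np.uint8))
    return out


def attention_on_specimen_fraction(
    saliency_map: np.ndarray, specimen_box: BoundingBox
) -> float:
    """Fraction of total saliency mass inside the specimen box.

    Returns 0.0 when the map sums to zero.  Saliency values must be
    non-negative; the computation itself is method-agnostic (any CAM or
    gradient map works).
    """
    sal = np.asarray(saliency_map, dtype=np.float64)
    if sal.ndim != 2:
        raise ValueError("saliency map must be 2-D")
    if (sal < 0).any():
        raise ValueError("saliency values must be >= 0")
    specimen_box.validate_within(*sal.shape)
    total = sal.sum()
    if total == 0:
        return 0.0
    inside = sal[
        specimen_box.y_min : specimen_box.y_max,
        specimen_box.x_min : specimen_box.x_max,
    ].sum()
    return float(inside / total)
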