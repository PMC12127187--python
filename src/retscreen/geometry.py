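"""Vertical cup-to-disc ratio from binary disc and cup segmentation masks.

The measurement mirrors a segmentation-based CDR pipeline downstream of
the segmentation model: locate the optic-disc region of interest, measure
the vertical extents of disc and cup, map resized-ROI pixel counts back to
the original frame, and form CDR = cup height / disc height.

Conventions (fixed and tested):

* rasters are row-major with row 0 at the top; "vertical" is the row axis;
* connected components use 4-connectivity;
* a structure's height is the vertical *extent* of its largest connected
  component (max_row - min_row + 1), robust to interior holes;
* ROI boxes are 0-based and half-open, [top, bottom) x [left, right);
* the cup is intersected with the disc before measurement (anatomical
  containment; prevents CDR > 1 from segmentation spill);
* rescaled pixel counts round half-up.

Gradability gating is not performed here: callers decide which images are
measurable (an injectable predicate), keeping the geometry free of any
learned quality model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskPair",
    "RoiBox",
    "DiscCupMeasurement",
    "EmptyMaskError",
    "extract_roi",
    "vertical_height",
    "rescale_to_frame",
    "compute_cdr",
    "synthesize_mask_pair",
    "read_mask",
    "write_mask",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when a disc mask contains no foreground ("no disc found")."""


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {m.shape}")
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1, 255)).all():
            raise ValueError(f"{name} is not binary (values {vals[:10]})")
        m = m > 0
    return m


@dataclass(frozen=True)
class RoiBox:
    """0-based, half-open [top, bottom) x [left, right) pixel box."""

    top: int
    bottom: int
    left: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise ValueError(f"degenerate ROI {self}")
        if min(self.top, self.left) < 0:
            raise ValueError(f"ROI outside raster: {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class MaskPair:
    """Binary disc and cup rasters sharing one coordinate frame.

    Cup ⊆ disc is *not* assumed of the inputs — real segmentations violate
    it — containment is enforced at measurement time.
    """

    disc: np.ndarray
    cup: np.ndarray
    pixel_scale: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "disc", _as_binary(self.disc, "disc"))
        object.__setattr__(self, "cup", _as_binary(self.cup, "cup"))
        if self.disc.shape != self.cup.shape:
            raise ValueError(
                f"disc {self.disc.shape} and cup {self.cup.shape} shapes differ"
            )


@dataclass(frozen=True)
class DiscCupMeasurement:
    disc_height_px: int
    cup_height_px: int
    cdr: float
    cup_empty: bool = False
    cdr_exceeds_one: bool = False


def _largest_component(mask: np.ndarray) -> np.ndarray | None:
    """Boolean mask of the largest 4-connected component; None if empty."""
    lab, nlab = ndimage.label(mask, structure=_FOUR_CONN)
    if nlab == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def extract_roi(disc_mask: np.ndarray, pad_fraction: float = 0.0) -> RoiBox:
    """Bounding box of the largest 4-connected disc component, expanded by
    ``pad_fraction`` of its height/width and clipped to the raster."""
    m = _as_binary(disc_mask, "disc")
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be non-negative")
    comp = _largest_component(m)
    if comp is None:
        raise EmptyMaskError("no disc found: mask has no foreground pixels")
    rows = np.flatnonzero(comp.any(axis=1))
    cols = np.flatnonzero(comp.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1]) + 1
    left, right = int(cols[0]), int(cols[-1]) + 1
    pad_r = math.floor(pad_fraction * (bottom - top) + 0.5)
    pad_c = math.floor(pad_fraction * (right - left) + 0.5)
    return RoiBox(
        top=max(top - pad_r, 0),
        bottom=min(bottom + pad_r, m.shape[0]),
        left=max(left - pad_c, 0),
        right=min(right + pad_c, m.shape[1]),
    )


def vertical_height(mask: np.ndarray) -> int:
    """Rows spanned by the largest 4-connected component (0 when empty)."""
    comp = _largest_component(_as_binary(mask))
    if comp is None:
        return 0
    rows = np.flatnonzero(comp.any(axis=1))
    return int(rows[-1] - rows[0] + 1)


def rescale_to_frame(measurement_px: int, roi: RoiBox, resized_edge: int) -> int:
    """Map a pixel count measured in a resized ROI back to original-frame
    pixels via the ROI height ratio, rounding half-up."""
    if measurement_px < 0:
        raise ValueError("measurement_px must be non-negative")
    if resized_edge <= 0:
        raise ValueError("resized_edge must be positive")
    return math.floor(measurement_px * roi.height / resized_edge + 0.5)


def compute_cdr(pair: MaskPair) -> DiscCupMeasurement:
    """Vertical CDR of a disc/cup mask pair.

    The cup is intersected with the disc first. An empty disc raises; an
    empty cup yields CDR 0 with ``cup_empty`` set; CDR > 1 (possible only
    through pathological multi-component discs) is flagged, never clipped.
    """
    disc_h = vertical_height(pair.disc)
    if disc_h == 0:
        raise EmptyMaskError("no disc found: cannot compute CDR")
    cup_h = vertical_height(pair.cup & pair.disc)
    cdr = cup_h / disc_h
    return DiscCupMeasurement(
        disc_height_px=disc_h,
        cup_height_px=cup_h,
        cdr=cdr,
        cup_empty=(cup_h == 0),
        cdr_exceeds_one=(cdr > 1.0),
    )


def _filled_ellipse(
    shape: Sequence[int], center: Sequence[float], semi_axes: Sequence[float]
) -> np.ndarray:
    """Pixels whose centers lie inside or on the ellipse."""
    b, a = float(semi_axes[0]), float(semi_axes[1])
    if b <= 0 or a <= 0:
        return np.zeros(tuple(shape), dtype=bool)
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / b) ** 2 + ((cc - center[1]) / a) ** 2 <= 1.0


def synthesize_mask_pair(
    disc_semi_axes: tuple[float, float],
    cdr_target: float,
    center: tuple[float, float] | None = None,
    shape: tuple[int, int] = (256, 256),
    seed: int | None = None,
) -> MaskPair:
    """Deterministic elliptical disc/cup fixture.

    Axis-aligned filled ellipses with the cup's semi-axes scaled by
    ``cdr_target``; with integer vertical semi-axis b the disc spans
    exactly 2b+1 rows, so ``compute_cdr`` recovers the target within
    2/(2b+1). When ``center`` is None a valid center is drawn from
    ``seed``.
    """
    b, a = disc_semi_axes
    if b <= 0 or a <= 0:
        raise ValueError("semi-axes must be positive")
    if not 0.0 <= cdr_target <= 1.0:
        raise ValueError("cdr_target must be in [0, 1]")
    if center is None:
        rng = np.random.default_rng(seed)
        lo_r, hi_r = math.ceil(b), shape[0] - 1 - math.ceil(b)
        lo_c, hi_c = math.ceil(a), shape[1] - 1 - math.ceil(a)
        if lo_r > hi_r or lo_c > hi_c:
            raise ValueError("ellipse does not fit inside shape")
        center = (int(rng.integers(lo_r, hi_r + 1)), int(rng.integers(lo_c, hi_c + 1)))
    if not (
        center[0] - b >= 0
        and center[0] + b <= shape[0] - 1
        and center[1] - a >= 0
        and center[1] + a <= shape[1] - 1
    ):
        raise ValueError("ellipse out of bounds")
    disc = _filled_ellipse(shape, center, (b, a))
    if cdr_target == 0.0:
        cup = np.zeros(tuple(shape), dtype=bool)
    else:
        cup = _filled_ellipse(shape, center, (cdr_target * b, cdr_target * a))
    return MaskPair(disc=disc, cup=cup)


def read_mask(path) -> np.ndarray:
    """Read a single-channel PNG mask (0 background, nonzero foreground)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse RGB(A)
        img = img[..., :3].max(axis=-1)
    return img > 0


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (0 / 255)."""
    import imageio.v3 as iio

    m = _as_binary(mask)
    iio.imwrite(path, (m.astype(np.uint8) * 255))
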