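"""Set-theoretic binary morphology and the fractal segmentation stage.

Erosion, dilation, and boundary extraction are implemented directly from
their set definitions so the border conventions are explicit: pixels
outside the frame count as background for erosion (a structuring element
overhanging the border never fits) and are simply absent for dilation
(the result is clipped to the frame).

The segmentation stage combines three local feature maps -- normalized
intensity, gradient-magnitude edges, and local-standard-deviation
texture -- into a candidate tumor mask: edge pixels above a robust
MAD-based spike threshold seed the mask, which is then closed, filled,
and trimmed by one erosion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import RawImage

__all__ = [
    "StructuringElement",
    "SegmentationResult",
    "erode",
    "dilate",
    "boundary",
    "closing",
    "noise_sigma",
    "spike_threshold",
    "segment_fractal",
    "FractalSegmenter",
]

#: MAD-to-sigma conversion constant for Gaussian noise.
MAD_SCALE = 0.6745
#: Multiplier applied to the noise sigma to obtain the spike threshold.
THRESHOLD_FACTOR = 3.5


@dataclass(frozen=True)
class StructuringElement:
    """Binary footprint with an origin index (defaults to the center)."""

    footprint: np.ndarray
    origin: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if not fp.any():
            raise ValueError("structuring element footprint must be non-empty")
        origin = self.origin
        if origin is None:
            origin = tuple(s // 2 for s in fp.shape)
        origin = tuple(int(o) for o in origin)
        if len(origin) != fp.ndim or any(
            not (0 <= o < s) for o, s in zip(origin, fp.shape)
        ):
            raise ValueError("origin must lie inside the footprint")
        object.__setattr__(self, "origin", origin)

    @classmethod
    def box(cls, ndim: int = 2, size: int = 3) -> "StructuringElement":
        """All-true cube, the default 3x3 (or 3x3x3) neighborhood."""
        return cls(np.ones((size,) * ndim, dtype=bool))

    @property
    def offsets(self) -> np.ndarray:
        """(k, ndim) integer offsets of true cells relative to the origin."""
        idx = np.argwhere(self.footprint)
        return idx - np.asarray(self.origin)

    def reflect(self) -> "StructuringElement":
        """Reflection of the footprint through its origin."""
        fp = self.footprint[tuple(slice(None, None, -1) for _ in range(self.footprint.ndim))]
        new_origin = tuple(
            s - 1 - o for s, o in zip(self.footprint.shape, self.origin)
        )
        return StructuringElement(fp, new_origin)


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask, dtype=bool)


def _shifted(padded: np.ndarray, off, shape, pad) -> np.ndarray:
    sl = tuple(
        slice(p + int(o), p + int(o) + s) for p, o, s in zip(pad, off, shape)
    )
    return padded[sl]


def erode(A, se: StructuringElement, border_value: bool = False) -> np.ndarray:
    """Erosion {z | B_z subset of A}; border treated as background.

    ``border_value=True`` treats out-of-frame pixels as foreground
    instead, which is the exact convention for eroding the complement
    of a finite set (the complement extends beyond the frame); with it
    the duality dilate(A, B) == ~erode(~A, reflect(B), border_value=True)
    holds everywhere including the border.
    """
    A = _as_bool(A)
    offs = se.offsets
    if offs.shape[1] != A.ndim:
        raise ValueError("structuring element dimensionality mismatch")
    pad = tuple(int(np.abs(offs[:, d]).max()) for d in range(A.ndim))
    padded = np.pad(A, [(p, p) for p in pad], constant_values=bool(border_value))
    out = np.ones_like(A)
    for off in offs:
        out &= _shifted(padded, off, A.shape, pad)
    return out


def dilate(A, se: StructuringElement) -> np.ndarray:
    """Dilation {z | reflected(B)_z intersects A}, clipped to the frame."""
    A = _as_bool(A)
    offs = se.offsets
    if offs.shape[1] != A.ndim:
        raise ValueError("structuring element dimensionality mismatch")
    pad = tuple(int(np.abs(offs[:, d]).max()) for d in range(A.ndim))
    padded = np.pad(A, [(p, p) for p in pad], constant_values=False)
    out = np.zeros_like(A)
    for off in offs:
        out |= _shifted(padded, -off, A.shape, pad)
    return out


def boundary(A, se: StructuringElement) -> np.ndarray:
    """Boundary beta(A) = A minus its erosion (one-element rim)."""
    A = _as_bool(A)
    return A & ~erode(A, se)


def closing(A, se: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion; seals small gaps."""
    return erode(dilate(A, se), se)


# ---------------------------------------------------------------------------
# Robust spike threshold
# ---------------------------------------------------------------------------

def noise_sigma(x) -> float:
    """MAD noise estimate sigma = median(|x|) / 0.6745."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("noise_sigma requires a non-empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    return float(np.median(np.abs(x)) / MAD_SCALE)


def spike_threshold(x) -> float:
    """Spike threshold 3.5 * sigma_n; scale-equivariant in x."""
    return THRESHOLD_FACTOR * noise_sigma(x)


# ---------------------------------------------------------------------------
# Fractal segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Mask + boundary + the three feature maps used to derive them."""

    mask: np.ndarray
    boundary: np.ndarray
    feature_maps: Dict[str, np.ndarray]
    threshold_used: float


def _local_std(data: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    w = footprint.astype(np.float64)
    w /= w.sum()
    mean = ndimage.correlate(data, w, mode="reflect")
    mean_sq = ndimage.correlate(data * data, w, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    return np.sqrt(var)


def _gradient_magnitude(data: np.ndarray) -> np.ndarray:
    grads = np.gradient(data.astype(np.float64))
    if data.ndim == 1:
        grads = [grads]
    return np.sqrt(np.sum([g * g for g in grads], axis=0))


def segment_fractal(image, se: Optional[StructuringElement] = None) -> SegmentationResult:
    """Segment a preprocessed grayscale image into a candidate tumor mask.

    Feature maps: ``intensity`` (normalized to [0, 1]), ``edge``
    (gradient magnitude), ``texture`` (local standard deviation over the
    structuring-element footprint).  Edge pixels above the MAD spike
    threshold of the gradient values seed the mask; closing seals gaps
    in the edge band, hole filling recovers the enclosed region, and a
    final erosion trims the outward half of the gradient band.

    A constant image yields an empty mask without error.
    """
    if isinstance(image, RawImage):
        data = np.asarray(image.data, dtype=np.float64)
        max_value = image.max_value
    else:
        data = np.asarray(image, dtype=np.float64)
        max_value = max(float(data.max()), 1.0)
    if se is None:
        se = StructuringElement.box(ndim=data.ndim)

    intensity = data / max_value
    edge = _gradient_magnitude(data)
    texture = _local_std(data, se.footprint)

    thr = spike_threshold(edge.ravel())
    seed = edge > thr  # strict: a constant image (edge == 0 == thr) stays empty
    if seed.any():
        mask = closing(seed, se)
        mask = ndimage.binary_fill_holes(mask)
        mask = erode(mask, se)
    else:
        mask = seed
    return SegmentationResult(
        mask=mask,
        boundary=boundary(mask, se),
        feature_maps={"intensity": intensity, "edge": edge, "texture": texture},
        threshold_used=float(thr),
    )


class FractalSegmenter:
    """Callable wrapper holding the structuring element used per image."""

    def __init__(self, se: Optional[StructuringElement] = None):
        self.se = se

    def __call__(self, image) -> SegmentationResult:
        return self.segment(image)

    def segment(self, image) -> SegmentationResult:
        return segment_fractal(image, self.se)
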