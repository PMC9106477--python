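"""Image I/O and preprocessing for 2D slices and 3D volumes.

The preprocessing chain normalizes heterogeneous scanner output before
segmentation: resize to a standard frame, histogram equalization,
median denoising, Gaussian high-pass detail enhancement, and an optional
landmark-based de-rotation.  Geometry is driven by a pair of landmark
points (p5, p10): their half-distance defines the scale factor BASE,
their half-difference the coordinate origin, and their slope the
in-plane rotation to undo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import transform as _sktransform
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops

__all__ = [
    "RawImage",
    "LandmarkPair",
    "PreprocessConfig",
    "Preprocessor",
    "load_image",
    "save_image",
    "compute_base",
    "compute_origin",
    "rotation_angle",
    "deskew",
    "resize_to_standard",
    "equalize_histogram",
    "median_filter",
    "highpass_filter",
    "highpass_components",
    "rgb_to_gray",
    "default_landmarks",
    "GRAY_WEIGHTS",
]

#: BT.601 luma weights used for RGB -> grayscale conversion.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class RawImage:
    """A grayscale 2D image, RGB 2D image, or grayscale 3D volume.

    Parameters
    ----------
    data : ndarray
        Intensities in ``[0, max_value]``.  Shape ``(H, W)`` for 2D,
        ``(H, W, D)`` for volumes, ``(H, W, 3)`` with ``channels='rgb'``
        for color images.
    max_value : float
        Nominal intensity ceiling (255 for 8-bit input).
    channels : str or None
        ``None`` for grayscale, ``'rgb'`` for 3-channel color.
    spacing : tuple or None
        Optional per-axis physical voxel spacing.
    """

    data: np.ndarray
    max_value: float = 255.0
    channels: Optional[str] = None
    spacing: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if self.channels == "rgb":
            if self.data.ndim != 3 or self.data.shape[-1] != 3:
                raise ValueError("rgb image must have shape (H, W, 3)")
        elif self.data.ndim not in (2, 3):
            raise ValueError(
                f"image must be 2D or 3D, got shape {self.data.shape}"
            )
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}]"
            )

    @property
    def is_volume(self) -> bool:
        return self.channels is None and self.data.ndim == 3

    def with_data(self, data: np.ndarray, **kw) -> "RawImage":
        """New RawImage sharing metadata, replacing the pixel array."""
        meta = dict(max_value=self.max_value, channels=self.channels,
                    spacing=self.spacing)
        meta.update(kw)
        return RawImage(data, **meta)


@dataclass(frozen=True)
class LandmarkPair:
    """Two reference points used for scale/origin/rotation normalization."""

    p5: Tuple[float, float]
    p10: Tuple[float, float]

    def validate(self, shape: Optional[Sequence[int]] = None) -> None:
        if shape is not None:
            for (x, y) in (self.p5, self.p10):
                if not (0 <= x < shape[1] and 0 <= y < shape[0]):
                    raise ValueError(f"landmark ({x}, {y}) outside image bounds")


@dataclass
class PreprocessConfig:
    """Switches and parameters for the preprocessing chain.

    Steps run in the fixed order: resize -> equalize -> median ->
    high-pass -> de-rotation; each is individually switchable.
    """

    target_size: int = 256
    median_kernel: int = 3
    highpass_sigma: float = 2.0
    equalize: bool = True
    resize: bool = True
    median: bool = True
    highpass: bool = True
    deskew: bool = True
    landmarks: Optional[LandmarkPair] = None

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_PIL_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return float(min(info.max, 65535))
    m = float(arr.max()) if arr.size else 1.0
    return max(m, 1.0)


def load_image(path, format_hint: Optional[str] = None) -> RawImage:
    """Read PNG/JPEG/TIFF, NIfTI (.nii/.nii.gz) or DICOM into a RawImage.

    3D volumes keep axis order (H, W, D).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: no such file {path}")
    name = path.name.lower()
    fmt = (format_hint or "").lower()
    try:
        if fmt == "nifti" or name.endswith(_NIFTI_SUFFIXES):
            import nibabel as nib

            vol = np.asanyarray(nib.load(str(path)).dataobj)
            return RawImage(vol.astype(np.float64), max_value=_dtype_max(vol))
        if fmt == "dicom" or name.endswith(".dcm"):
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array
            return RawImage(arr.astype(np.float64), max_value=_dtype_max(arr))
        if fmt in ("png", "jpeg", "tiff") or name.endswith(_PIL_SUFFIXES):
            from PIL import Image

            with Image.open(path) as im:
                arr = np.asarray(im)
            channels = "rgb" if arr.ndim == 3 else None
            if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
                arr = arr[..., :3]
            return RawImage(arr.astype(np.float64), max_value=_dtype_max(arr),
                            channels=channels)
    except (IOError, ValueError):
        raise
    except Exception as exc:  # corrupt file
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raise ValueError(f"unsupported image format: {path}")


def save_image(image: RawImage, path) -> None:
    """Write a RawImage as PNG (2D) or NIfTI (3D)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(image.data, dtype=np.float32),
                                 np.eye(4)), str(path))
        return
    if name.endswith(".png"):
        from PIL import Image

        arr = np.asarray(image.data)
        scaled = np.clip(arr / image.max_value * 255.0, 0, 255)
        mode_arr = np.round(scaled).astype(np.uint8)
        Image.fromarray(mode_arr).save(path)
        return
    raise ValueError(f"unsupported output format: {path}")


# ---------------------------------------------------------------------------
# Landmark geometry
# ---------------------------------------------------------------------------

def compute_base(landmarks: LandmarkPair) -> float:
    """Scale factor BASE = sqrt(((x5-x10)/2)^2 + ((y5-y10)/2)^2).

    Half the Euclidean distance between the two landmarks; zero iff the
    points coincide (downstream normalization must reject zero).
    """
    (x5, y5), (x10, y10) = landmarks.p5, landmarks.p10
    return float(np.hypot((x5 - x10) / 2.0, (y5 - y10) / 2.0))


def compute_origin(landmarks: LandmarkPair) -> Tuple[float, float]:
    """Coordinate origin (x0, y0) = ((x5-x10)/2, (y5-y10)/2).

    No rounding: integer landmarks may give half-integer origins.
    """
    (x5, y5), (x10, y10) = landmarks.p5, landmarks.p10
    return ((x5 - x10) / 2.0, (y5 - y10) / 2.0)


def rotation_angle(landmarks: LandmarkPair) -> float:
    """Baseline angle theta = arctan((y5-y10)/(x5-x10)), in (-pi/2, pi/2).

    Raises
    ------
    ValueError
        If the baseline is vertical (x5 == x10), where the formula is
        undefined.
    """
    (x5, y5), (x10, y10) = landmarks.p5, landmarks.p10
    if x5 == x10:
        raise ValueError("vertical baseline: rotation angle undefined")
    return float(np.arctan((y5 - y10) / (x5 - x10)))


def deskew(image: RawImage, angle_radians: float,
           origin: Optional[Tuple[float, float]] = None) -> RawImage:
    """Rotate by -angle about ``origin`` (bilinear, zero fill, shape kept).

    For volumes each (H, W) slice is rotated in-plane.
    """
    if not np.isfinite(angle_radians):
        raise ValueError("angle must be finite")
    deg = -np.degrees(angle_radians)
    center = None if origin is None else (float(origin[0]), float(origin[1]))

    def _rot2d(sl: np.ndarray) -> np.ndarray:
        out = _sktransform.rotate(sl, deg, center=center, order=1, cval=0.0,
                                  preserve_range=True, resize=False)
        return np.clip(out, 0.0, image.max_value)

    data = np.asarray(image.data, dtype=np.float64)
    if image.is_volume:
        out = np.stack([_rot2d(data[:, :, k]) for k in range(data.shape[2])],
                       axis=2)
    else:
        out = _rot2d(data)
    return image.with_data(out)


# ---------------------------------------------------------------------------
# Intensity preprocessing
# ---------------------------------------------------------------------------

def resize_to_standard(image: RawImage, target_size: int = 256) -> RawImage:
    """Resize to ``target_size x target_size`` (per slice for 3D)."""
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    data = np.asarray(image.data, dtype=np.float64)
    if image.is_volume:
        shape = (target_size, target_size, data.shape[2])
    elif image.channels == "rgb":
        shape = (target_size, target_size, 3)
    else:
        shape = (target_size, target_size)
    if data.shape == shape:
        return image.with_data(data)
    anti = data.shape[0] > target_size
    out = _sktransform.resize(data, shape, order=1, preserve_range=True,
                              anti_aliasing=anti)
    return image.with_data(np.clip(out, 0.0, image.max_value))


def equalize_histogram(image: RawImage, nbins: int = 256) -> RawImage:
    """Classical CDF histogram equalization over ``nbins`` bins.

    The mapping v -> CDF(v) * max_value is monotone non-decreasing, so
    pixel rank order is preserved; output spans up to [0, max_value].
    """
    if image.channels == "rgb":
        raise ValueError("equalize_histogram expects a grayscale image")
    data = np.asarray(image.data, dtype=np.float64)
    idx = np.clip((data / image.max_value * (nbins - 1)), 0, nbins - 1)
    idx = idx.astype(np.intp)
    hist = np.bincount(idx.ravel(), minlength=nbins).astype(np.float64)
    cdf = np.cumsum(hist) / data.size
    out = cdf[idx] * image.max_value
    return image.with_data(out)


def median_filter(image: RawImage, kernel: int = 3) -> RawImage:
    """Median over a ``kernel``-per-axis neighborhood, reflect padding."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be an odd integer >= 1")
    out = ndimage.median_filter(np.asarray(image.data, dtype=np.float64),
                                size=kernel, mode="reflect")
    return image.with_data(out)


def highpass_components(image: RawImage, sigma: float = 2.0):
    """Split into (lowpass, highpass) with lowpass + highpass == data."""
    data = np.asarray(image.data, dtype=np.float64)
    low = ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
    return low, data - low


def highpass_filter(image: RawImage, sigma: float = 2.0) -> RawImage:
    """Detail image: input minus Gaussian low-pass, rescaled to full range.

    A constant input has no detail and maps to all zeros.
    """
    if image.channels == "rgb":
        raise ValueError("highpass_filter expects a grayscale image")
    _, high = highpass_components(image, sigma)
    span = high.max() - high.min()
    if span <= 0:
        return image.with_data(np.zeros_like(high))
    out = (high - high.min()) / span * image.max_value
    return image.with_data(out)


def rgb_to_gray(image: RawImage) -> RawImage:
    """Luminance-weighted grayscale (0.2989 R + 0.5870 G + 0.1140 B)."""
    if image.channels != "rgb":
        warnings.warn("rgb_to_gray called on a grayscale image; passing through")
        return image
    w = np.asarray(GRAY_WEIGHTS)
    w = w / w.sum()  # the printed weights sum to 0.9999; renormalize so r=g=b=v maps to v
    gray = np.tensordot(np.asarray(image.data, dtype=np.float64), w, axes=([-1], [0]))
    return RawImage(np.clip(gray, 0.0, image.max_value),
                    max_value=image.max_value, spacing=image.spacing)


# ---------------------------------------------------------------------------
# Landmark auto-detection and the chained preprocessor
# ---------------------------------------------------------------------------

def default_landmarks(image: RawImage) -> Optional[LandmarkPair]:
    """Endpoints of the Otsu foreground's major axis, or None.

    Used when no anatomical landmarks are supplied: the two extremal
    points of the largest foreground component's major axis play the
    role of the reference pair.  Returns None for images with no
    usable foreground (constant or empty).
    """
    data = image.data
    if image.channels == "rgb":
        data = rgb_to_gray(image).data
    if image.is_volume:
        data = data[:, :, data.shape[2] // 2]
    if np.ptp(data) <= 0:
        return None
    try:
        fg = data > threshold_otsu(np.asarray(data, dtype=np.float64))
    except ValueError:
        return None
    if not fg.any():
        return None
    lab = _cc_label(fg)
    props = max(regionprops(lab), key=lambda p: p.area)
    cy, cx = props.centroid
    half = props.axis_major_length / 2.0
    if half <= 0:
        return None
    ang = props.orientation  # angle between major axis and vertical
    dx, dy = half * np.sin(ang), half * np.cos(ang)
    h, w = data.shape
    p5 = (float(np.clip(cx + dx, 0, w - 1)), float(np.clip(cy - dy, 0, h - 1)))
    p10 = (float(np.clip(cx - dx, 0, w - 1)), float(np.clip(cy + dy, 0, h - 1)))
    if p5 == p10:
        return None
    return LandmarkPair(p5=p5, p10=p10)


class Preprocessor:
    """Apply the standard chain: resize -> equalize -> median -> high-pass
    -> de-rotation, as enabled in the config."""

    def __init__(self, config: Optional[PreprocessConfig] = None):
        self.config = config or PreprocessConfig()

    def __call__(self, image: RawImage) -> RawImage:
        return self.run(image)

    def run(self, image: RawImage) -> RawImage:
        cfg = self.config
        out = image
        if out.channels == "rgb":
            out = rgb_to_gray(out)
        if cfg.resize:
            out = resize_to_standard(out, cfg.target_size)
        if cfg.equalize:
            out = equalize_histogram(out)
        if cfg.median:
            out = median_filter(out, cfg.median_kernel)
        if cfg.highpass:
            out = highpass_filter(out, cfg.highpass_sigma)
        if cfg.deskew:
            lm = cfg.landmarks or default_landmarks(out)
            if lm is not None and lm.p5 != lm.p10:
                try:
                    theta = rotation_angle(lm)
                except ValueError:
                    theta = None
                if theta is not None:
                    out = deskew(out, theta)
        return out
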