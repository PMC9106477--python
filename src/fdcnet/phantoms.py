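"""Deterministic synthetic tumor phantoms with ground-truth masks.

Each phantom is a smooth low-frequency background with one radially
perturbed ellipsoidal "tumor" of controllable radius, boundary
irregularity, contrast, and within-tumor texture, degraded by Gaussian
noise and salt-and-pepper speckle (in that order, so median filtering
has a defined target).  The three classes are encoded geometrically:

* ``benign``     -- nearly smooth boundary, little internal texture;
* ``malignant``  -- strongly irregular boundary, strong texture;
* ``suspicious`` -- intermediate on both axes, overlapping the others.

The boundary perturbation is a random truncated Fourier series
r(theta) = r0 (1 + irregularity * s(theta)) with harmonics k = 2..5 and
coefficients a_k, b_k ~ N(0, 1/8), so E[sum a_k^2 + b_k^2] = 1 and the
expected enclosed area is pi r0^2 (1 + irregularity^2 / 2).  Identical
spec + seed reproduces bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .image import RawImage

__all__ = [
    "CLASS_NAMES",
    "CLASS_PARAMS",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "expected_tumor_area",
]

CLASS_NAMES = ("benign", "malignant", "suspicious")

#: Class encodings: (boundary irregularity, texture amplitude in gray levels).
CLASS_PARAMS: Dict[str, Tuple[float, float]] = {
    "benign": (0.03, 2.0),
    "malignant": (0.50, 45.0),
    "suspicious": (0.25, 20.0),
}

_HARMONICS = (2, 3, 4, 5)
_COEF_STD = 1.0 / np.sqrt(2 * len(_HARMONICS))  # E[sum coef^2] = 1


@dataclass
class PhantomSpec:
    """Full description of one phantom; identical spec+seed is bit-stable."""

    shape: Tuple[int, ...] = (64, 64)
    class_label: str = "benign"
    tumor_radius: float = 10.0
    boundary_irregularity: Optional[float] = None   # None -> class default
    contrast: float = 60.0
    texture_amplitude: Optional[float] = None       # None -> class default
    noise_gaussian_sigma: float = 3.0
    salt_pepper_rate: float = 0.002
    background_mean: float = 70.0
    background_amplitude: float = 8.0
    max_value: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label: {self.class_label}")
        if not (0.0 <= self.salt_pepper_rate <= 1.0):
            raise ValueError("salt_pepper_rate must lie in [0, 1]")
        irr = self.irregularity
        if not (0.0 <= irr <= 1.0):
            raise ValueError("boundary_irregularity must lie in [0, 1]")
        margin = self.tumor_radius * (1.0 + 2.0 * irr) + 2.0
        if 2.0 * margin >= min(self.shape):
            raise ValueError(
                f"tumor_radius {self.tumor_radius} too large for shape "
                f"{self.shape}"
            )

    @property
    def irregularity(self) -> float:
        if self.boundary_irregularity is not None:
            return self.boundary_irregularity
        return CLASS_PARAMS[self.class_label][0]

    @property
    def texture(self) -> float:
        if self.texture_amplitude is not None:
            return self.texture_amplitude
        return CLASS_PARAMS[self.class_label][1]


@dataclass
class PhantomSample:
    image: RawImage
    mask: np.ndarray
    label: str

    @property
    def label_id(self) -> int:
        return CLASS_NAMES.index(self.label)


def expected_tumor_area(spec: PhantomSpec) -> float:
    """Analytic expected enclosed area (2D): pi r^2 (1 + irr^2 / 2)."""
    if len(spec.shape) != 2:
        raise ValueError("closed-form area is provided for 2D phantoms")
    return float(np.pi * spec.tumor_radius ** 2
                 * (1.0 + spec.irregularity ** 2 / 2.0))


def _radial_profile(theta: np.ndarray, rng: np.random.Generator,
                    irregularity: float) -> np.ndarray:
    s = np.zeros_like(theta)
    for k in _HARMONICS:
        a, b = rng.normal(0.0, _COEF_STD, size=2)
        s += a * np.cos(k * theta) + b * np.sin(k * theta)
    np.clip(s, -2.0, 2.0, out=s)  # keeps the tumor inside the margin bound
    return np.maximum(1.0 + irregularity * s, 0.2)


def _smooth_noise(shape, rng: np.random.Generator, sigma: float) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    sd = n.std()
    return n / sd if sd > 0 else n


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; see the module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nd = len(shape)
    if nd not in (2, 3):
        raise ValueError("phantoms are 2D or 3D")

    background = (spec.background_mean
                  + spec.background_amplitude
                  * _smooth_noise(shape, rng, min(shape) / 4.0))

    irr = spec.irregularity
    margin = spec.tumor_radius * (1.0 + 2.0 * irr) + 2.0
    center = np.array([rng.uniform(margin, s - margin) for s in shape])

    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    deltas = [g - c for g, c in zip(grids, center)]
    rho = np.sqrt(np.sum([d * d for d in deltas], axis=0))
    theta = np.arctan2(deltas[1], deltas[0])
    if nd == 2:
        limit = spec.tumor_radius * _radial_profile(theta, rng, irr)
    else:
        rho_xy = np.sqrt(deltas[0] ** 2 + deltas[1] ** 2)
        phi = np.arctan2(deltas[2], rho_xy)
        prof = (_radial_profile(theta, rng, irr / np.sqrt(2))
                + _radial_profile(2 * phi, rng, irr / np.sqrt(2)) - 1.0)
        limit = spec.tumor_radius * np.maximum(prof, 0.2)
    mask = rho <= limit

    image = background.copy()
    if spec.contrast != 0.0:
        texture = _smooth_noise(shape, rng, 1.5)
        image[mask] += spec.contrast + spec.texture * texture[mask]

    if spec.noise_gaussian_sigma > 0:
        image += rng.normal(0.0, spec.noise_gaussian_sigma, size=shape)
    if spec.salt_pepper_rate > 0:
        hits = rng.random(size=shape) < spec.salt_pepper_rate
        salt = rng.random(size=shape) < 0.5
        image[hits & salt] = spec.max_value
        image[hits & ~salt] = 0.0

    image = np.clip(image, 0.0, spec.max_value)
    return PhantomSample(image=RawImage(image, max_value=spec.max_value),
                         mask=mask, label=spec.class_label)


def generate_dataset(n: int, class_mix: Optional[Dict[str, float]] = None,
                     base_spec: Optional[PhantomSpec] = None, seed: int = 0,
                     radius_jitter: float = 0.15,
                     param_jitter: bool = True) -> List[PhantomSample]:
    """Generate ``n`` labeled phantoms with largest-remainder class counts.

    Per-sample seeds derive from the master ``seed``; the tumor radius
    is jittered uniformly within ``+-radius_jitter`` of the base radius
    and, when ``param_jitter`` is set, irregularity and texture are
    jittered around their class encodings so the classes overlap.
    """
    if n == 0:
        return []
    base = base_spec or PhantomSpec()
    mix = class_mix or {c: 1.0 / len(CLASS_NAMES) for c in CLASS_NAMES}
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ValueError("class_mix proportions must sum to 1")

    # largest-remainder apportionment
    quotas = {c: n * p for c, p in mix.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n - sum(counts.values())
    for c in sorted(mix, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1

    master = np.random.default_rng(seed)
    samples: List[PhantomSample] = []
    for label in CLASS_NAMES:
        for _ in range(counts.get(label, 0)):
            child_seed = int(master.integers(0, 2 ** 31 - 1))
            irr0, tex0 = CLASS_PARAMS[label]
            irr = base.boundary_irregularity
            tex = base.texture_amplitude
            if param_jitter:
                irr = float(np.clip(master.normal(irr0, 0.02), 0.0, 1.0)) \
                    if irr is None else irr
                tex = float(max(master.normal(tex0, 0.1 * max(tex0, 1.0)), 0.0)) \
                    if tex is None else tex
            r = base.tumor_radius * (1.0 + master.uniform(-radius_jitter,
                                                          radius_jitter))
            # clamp to the largest radius whose margin fits the frame
            irr_eff = CLASS_PARAMS[label][0] if irr is None else irr
            r_max = (min(base.shape) / 2.0 - 2.0) / (1.0 + 2.0 * irr_eff)
            r = min(r, 0.98 * r_max)
            spec = replace(base, class_label=label, seed=child_seed,
                           tumor_radius=float(r),
                           boundary_irregularity=irr,
                           texture_amplitude=tex)
            samples.append(generate_phantom(spec))
    order = master.permutation(len(samples))
    return [samples[i] for i in order]
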