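"""Eigenimage feature extraction via the snapshot method.

Given M training images flattened to length-d vectors (row-major), the
extractor centers them on the mean image psi, forms the small M x M
matrix C = A^T A of the difference matrix A = [phi_1 ... phi_M]
(phi_i = image_i - psi), eigendecomposes C, and lifts the eigenvectors
back to image space via U = A V.  The top-f unit-norm lifted
eigenvectors form the component matrix W (f x d); features are
y = W (x - psi).  Detection compares the Euclidean distance between a
query's feature vector and a gallery of training features against a
threshold tau: a match is declared iff the smallest distance is
strictly below tau.

The huge d x d covariance A A^T is never formed here -- the snapshot
route gives the identical nonzero spectrum and projections, which is
verified against the direct route at small d in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EigenModel",
    "MatchResult",
    "EigenFeatureExtractor",
    "mean_image",
    "center",
    "snapshot_covariance",
    "eigen_decompose",
    "total_scatter",
    "project",
    "match",
]


@dataclass
class EigenModel:
    """Mean image, component matrix, spectrum, and detection threshold."""

    mean: np.ndarray          # (d,)
    components: np.ndarray    # (f, d), orthonormal rows
    eigenvalues: np.ndarray   # (f,), non-increasing, >= 0
    f: int
    tau: Optional[float] = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.components = np.atleast_2d(np.asarray(self.components, np.float64))
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if self.components.shape[0] != self.f:
            raise ValueError("components row count must equal f")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted non-increasing")

    def save(self, path, provenance: Optional[dict] = None) -> None:
        """Write arrays to ``path`` (.npz) with a JSON provenance sidecar."""
        path = Path(path)
        np.savez(path, mean=self.mean, components=self.components,
                 eigenvalues=self.eigenvalues, f=self.f,
                 tau=np.nan if self.tau is None else self.tau)
        meta = {"f": int(self.f), "d": int(self.mean.size),
                "tau": self.tau, **(provenance or {})}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "EigenModel":
        with np.load(Path(path)) as z:
            tau = float(z["tau"])
            return cls(mean=z["mean"], components=z["components"],
                       eigenvalues=z["eigenvalues"], f=int(z["f"]),
                       tau=None if np.isnan(tau) else tau)


@dataclass(frozen=True)
class MatchResult:
    """Nearest-gallery distance and the strict-threshold detection flag."""

    distance: float
    detected: bool
    nearest_index: int


# ---------------------------------------------------------------------------
# Core algebra
# ---------------------------------------------------------------------------

def _as_rows(T) -> np.ndarray:
    X = np.asarray(T, dtype=np.float64)
    if X.ndim != 2:
        X = X.reshape(X.shape[0], -1)  # row-major flattening, fixed
    return X


def mean_image(T) -> np.ndarray:
    """Elementwise mean psi = (1/M) sum_i Gamma_i over the training rows."""
    X = _as_rows(T)
    if X.shape[0] < 1:
        raise ValueError("mean_image requires at least one image")
    return X.mean(axis=0)


def center(T, psi) -> np.ndarray:
    """Difference matrix A (d x M) with columns phi_i = Gamma_i - psi."""
    X = _as_rows(T)
    psi = np.asarray(psi, dtype=np.float64).ravel()
    if X.shape[1] != psi.size:
        raise ValueError("mean vector length does not match image length")
    return (X - psi).T


def snapshot_covariance(A) -> np.ndarray:
    """Small covariance C = A^T A (M x M, symmetric PSD)."""
    A = np.asarray(A, dtype=np.float64)
    return A.T @ A


def eigen_decompose(C, A, f: int, mean: Optional[np.ndarray] = None,
                    tau: Optional[float] = None) -> EigenModel:
    """Snapshot eigendecomposition lifted to image space.

    Eigenvectors V of the M x M matrix C are lifted via U = A V and
    normalized to unit length; the top-f by eigenvalue become the
    component rows.  The nonzero eigenvalues of A^T A equal those of
    A A^T, so this is the spectrum of the full covariance without ever
    forming it.
    """
    A = np.asarray(A, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    M = C.shape[0]
    if f > M - 1:
        raise ValueError(f"f={f} exceeds the rank bound M-1={M - 1}")
    if f < 1:
        raise ValueError("f must be >= 1")
    evals, V = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    V = V[:, order]
    U = A @ V[:, :f]                      # lift: U_i = A v_i
    norms = np.linalg.norm(U, axis=0)
    norms[norms == 0] = 1.0
    components = (U / norms).T
    if mean is None:
        mean = np.zeros(A.shape[0])
    return EigenModel(mean=mean, components=components,
                      eigenvalues=evals[:f], f=f, tau=tau)


def total_scatter(X, mu) -> np.ndarray:
    """Scatter S_T = sum_k (x_k - mu)(x_k - mu)^T; equals A A^T at mu = mean."""
    X = _as_rows(X)
    mu = np.asarray(mu, dtype=np.float64).ravel()
    D = X - mu
    return D.T @ D


def project(x, model: EigenModel) -> np.ndarray:
    """Feature vector y = W (x - psi), length f."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size != model.mean.size:
        raise ValueError("input length does not match model dimension")
    return model.components @ (x - model.mean)


def match(y, gallery: Sequence[np.ndarray], tau: float) -> MatchResult:
    """Nearest-gallery Euclidean match with a strict detection threshold.

    ``detected`` iff min distance < tau; ties broken by lowest index.
    """
    if len(gallery) == 0:
        raise ValueError("gallery must be non-empty")
    if tau <= 0:
        raise ValueError("tau must be positive")
    y = np.asarray(y, dtype=np.float64).ravel()
    G = np.stack([np.asarray(g, dtype=np.float64).ravel() for g in gallery])
    dists = np.linalg.norm(G - y, axis=1)
    idx = int(np.argmin(dists))           # argmin takes the lowest index on ties
    d = float(dists[idx])
    return MatchResult(distance=d, detected=bool(d < tau), nearest_index=idx)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class EigenFeatureExtractor(TransformerMixin, BaseEstimator):
    """Snapshot-PCA feature extractor with nearest-neighbor detection.

    Parameters
    ----------
    n_components : int or None
        Retained dimension f.  ``None`` keeps the smallest f capturing
        ``variance_threshold`` of the total eigenvalue mass, capped at
        M - 1.
    variance_threshold : float
        Eigenvalue-mass fraction used when ``n_components`` is None.
    tau : float or None
        Detection threshold; ``None`` sets ``tau_scale`` times the
        median nearest-neighbor distance within the training gallery.
    tau_scale : float
        Multiplier for the automatic threshold.

    Attributes
    ----------
    mean_ : (d,) mean image psi
    components_ : (f, d) orthonormal eigenimage rows
    eigenvalues_ : (f,) retained spectrum, non-increasing
    f_ : retained dimension
    tau_ : detection threshold actually used
    gallery_ : (M, f) projected training features
    """

    def __init__(self, n_components: Optional[int] = None,
                 variance_threshold: float = 0.95,
                 tau: Optional[float] = None, tau_scale: float = 3.0):
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.tau = tau
        self.tau_scale = tau_scale

    def fit(self, X, y=None):
        X = _as_rows(X)
        M = X.shape[0]
        if M < 2:
            raise ValueError("need at least two training images")
        psi = mean_image(X)
        A = center(X, psi)
        C = snapshot_covariance(A)
        evals = np.clip(np.linalg.eigvalsh(C), 0.0, None)[::-1]
        if self.n_components is not None:
            f = int(self.n_components)
        else:
            total = evals.sum()
            if total <= 0:
                f = 1
            else:
                frac = np.cumsum(evals) / total
                f = int(np.searchsorted(frac, self.variance_threshold) + 1)
            f = min(f, M - 1)
        model = eigen_decompose(C, A, f, mean=psi, tau=self.tau)

        self.mean_ = model.mean
        self.components_ = model.components
        self.eigenvalues_ = model.eigenvalues
        self.f_ = model.f
        gallery = (model.components @ A).T    # (M, f)
        self.gallery_ = gallery
        if self.tau is not None:
            self.tau_ = float(self.tau)
        else:
            d2 = np.linalg.norm(gallery[:, None, :] - gallery[None, :, :], axis=2)
            np.fill_diagonal(d2, np.inf)
            nn = d2.min(axis=1)
            med = float(np.median(nn[np.isfinite(nn)])) if np.isfinite(nn).any() else 1.0
            self.tau_ = self.tau_scale * max(med, np.finfo(float).tiny)
        model.tau = self.tau_
        self.model_ = model
        return self

    def transform(self, X) -> np.ndarray:
        X = _as_rows(X)
        return (X - self.mean_) @ self.components_.T

    def detect(self, x) -> MatchResult:
        """Match a single flattened image against the training gallery."""
        y = project(x, self.model_)
        return match(y, list(self.gallery_), self.tau_)
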