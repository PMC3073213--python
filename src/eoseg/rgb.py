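"""RGB rendering of multispectral cubes and the k-means color baseline.

A conventional color camera integrates the spectrum through three broad
filters, which blurs narrow-band differences between similarly stained
tissue; clustering pixels on those three channels is the baseline the
spectral-residual method is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DimensionError, ParameterError
from .io import SpectralCube

__all__ = ["RgbRendering", "default_sensitivity", "render_rgb", "kmeans_rgb"]

#: broadband channel centers (R, G, B) in nm and common width
RGB_CENTERS_NM = (610.0, 550.0, 470.0)
RGB_SIGMA_NM = 35.0


@dataclass
class RgbRendering:
    """H×W×3 image in [0, 1] plus the 3×N band-weight matrix that made it."""

    image: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if np.any(self.sensitivity < 0):
            raise ParameterError("sensitivity weights must be nonnegative")
        rowsum = self.sensitivity.sum(axis=1)
        if not np.allclose(rowsum, 1.0):
            raise ParameterError("sensitivity rows must sum to 1")


def default_sensitivity(band_centers: np.ndarray) -> np.ndarray:
    """Three Gaussian broadband curves (610/550/470 nm, σ 35 nm) sampled on
    the band centers and row-normalized."""
    centers = np.asarray(band_centers, dtype=float)
    rows = [
        np.exp(-((centers - c) ** 2) / (2.0 * RGB_SIGMA_NM**2))
        for c in RGB_CENTERS_NM
    ]
    s = np.stack(rows)
    return s / s.sum(axis=1, keepdims=True)


def render_rgb(cube: SpectralCube, sensitivity: np.ndarray | None = None) -> RgbRendering:
    """Weighted band average per channel, clipped to [0, 1]."""
    if sensitivity is None:
        sensitivity = default_sensitivity(cube.band_centers)
    s = np.asarray(sensitivity, dtype=float)
    if s.shape != (3, cube.n_bands):
        raise DimensionError(
            f"sensitivity must be 3×{cube.n_bands}, got {s.shape}"
        )
    image = np.clip(cube.pixels.astype(float) @ s.T, 0.0, 1.0)
    return RgbRendering(image=image, sensitivity=s)


def kmeans_rgb(rendering: RgbRendering, k: int = 6, seed: int = 0) -> np.ndarray:
    """Cluster pixels by RGB color with k-means; returns an H×W label image.

    Deterministic under a fixed seed (k-means++ init, best of 10 restarts,
    Lloyd iterations to convergence).
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    h, w, _ = rendering.image.shape
    pixels = rendering.image.reshape(-1, 3)
    n_colors = np.unique(pixels, axis=0).shape[0]
    if k > n_colors:
        raise ParameterError(f"k={k} exceeds the {n_colors} distinct pixel colors")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(pixels)
    return labels.reshape(h, w)
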