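"""Band-pair selection from the mean spectral error of the target class.

The mean residual of target-class spectra under the in-model PCA basis
shows a positive and a negative extremum at characteristic wavelengths;
the difference of the per-pixel residuals at those two bands is the scalar
that separates the target class from everything in the model.  Selecting
the pair is an offline step whose result is stored with the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, SelectionError
from .pca import LabeledSpectrumSet, PCABasis, spectral_error

__all__ = ["BandPair", "mean_class_error", "select_band_pair"]


@dataclass
class BandPair:
    """Indices of the residual extrema: r (positive peak), s (negative peak).

    Indices are 0-based; use :meth:`as_one_based` when reporting against
    the published band numbering.
    """

    r: int
    s: int
    mean_error: np.ndarray

    def __post_init__(self) -> None:
        self.mean_error = np.asarray(self.mean_error, dtype=float)
        if self.r == self.s:
            raise SelectionError("r and s must be distinct bands")
        if not (self.mean_error[self.r] > 0 > self.mean_error[self.s]):
            raise SelectionError(
                "mean_error must be positive at r and negative at s"
            )

    def as_one_based(self) -> tuple[int, int]:
        return self.r + 1, self.s + 1


def mean_class_error(
    basis: PCABasis, target_spectra: LabeledSpectrumSet, m: int
) -> np.ndarray:
    """Arithmetic mean of the spectral error over all target samples."""
    if target_spectra.n_samples == 0:
        raise DataError("target spectrum set is empty")
    errors = [
        spectral_error(basis, target_spectra.spectra[:, j], m).error
        for j in range(target_spectra.n_samples)
    ]
    return np.mean(errors, axis=0)


def select_band_pair(mean_error: np.ndarray) -> BandPair:
    """Pick r = band of the highest positive peak, s = band of the
    largest-magnitude negative peak.

    Peaks are global extrema of the mean-error vector; ties break toward
    the lowest band index.  If the vector has no strictly positive or no
    strictly negative entry, the residual carries no usable two-band
    signature and selection fails.
    """
    e = np.asarray(mean_error, dtype=float)
    if e.ndim != 1:
        raise SelectionError("mean_error must be a vector")
    if not np.any(e > 0):
        raise SelectionError(
            "mean error has no positive entry: no positive residual peak; "
            "the two-band difference method is inapplicable"
        )
    if not np.any(e < 0):
        raise SelectionError(
            "mean error has no negative entry: no negative residual peak; "
            "the two-band difference method is inapplicable"
        )
    r = int(np.argmax(e))  # argmax/argmin return the first (lowest) index on ties
    s = int(np.argmin(e))
    return BandPair(r=r, s=s, mean_error=e)
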