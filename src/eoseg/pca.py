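"""PCA basis of tissue-class transmittance spectra and spectral residuals.

The detection principle: fit a principal-component basis to transmittance
samples of every tissue class *except* the target class.  With m principal
components (by default one per in-model class) the in-model spectra
reconstruct almost perfectly, while spectra of the excluded class retain a
structured residual — the *spectral error* — whose band-wise peaks identify
where its absorption departs from everything in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DimensionError, ParameterError

__all__ = [
    "LabeledSpectrumSet",
    "PCABasis",
    "SpectralError",
    "fit_pca",
    "explained_variance",
    "reconstruct",
    "spectral_error",
]


@dataclass
class LabeledSpectrumSet:
    """An n×q matrix of q sample spectra (columns) with one class label each."""

    spectra: np.ndarray
    labels: list[str]
    band_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.ndim != 2:
            raise DataError("spectra must be an n×q matrix (columns are samples)")
        if self.spectra.shape[1] < 1:
            raise DataError("at least one sample is required")
        if not np.all(np.isfinite(self.spectra)):
            raise DataError("spectra contain non-finite entries")
        self.labels = list(self.labels)
        if len(self.labels) != self.spectra.shape[1]:
            raise DataError("one label per sample column is required")

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct class names in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def subset(self, classes: list[str]) -> "LabeledSpectrumSet":
        keep = np.array([lab in classes for lab in self.labels])
        if not keep.any():
            raise DataError(f"no samples for classes {classes}")
        labels = [lab for lab, k in zip(self.labels, keep) if k]
        return LabeledSpectrumSet(self.spectra[:, keep], labels, self.band_edges)


@dataclass
class PCABasis:
    """Mean spectrum plus eigenpairs of the training covariance.

    Eigenvector columns are sorted by descending eigenvalue and sign-fixed
    so that each column's largest-magnitude entry is positive, making bases
    reproducible across eigensolvers.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    band_edges: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n = self.mean.shape[0]
        if self.eigenvectors.shape != (n, n):
            raise DimensionError("eigenvectors must be n×n")
        if self.eigenvalues.shape != (n,):
            raise DimensionError("one eigenvalue per eigenvector is required")

    @property
    def n_bands(self) -> int:
        return self.mean.shape[0]

    @property
    def default_m(self) -> int:
        """Number of components used by default: one per training class."""
        return len(self.classes) if self.classes else self.n_bands


@dataclass
class SpectralError:
    """Residual e = f − f̂ of a spectrum against its m-component estimate."""

    error: np.ndarray
    m_used: int


def fit_pca(training: LabeledSpectrumSet, exclude_classes: list[str] | None = None) -> PCABasis:
    """Fit the PCA basis on all training samples except the excluded classes.

    The covariance is taken about the sample mean with 1/(q−1) normalization
    and decomposed with a dense symmetric eigensolver.  Eigenvalues (tiny
    negative values from round-off are clipped to 0) are returned in
    descending order, ties broken stably in solver order.
    """
    exclude = set(exclude_classes or [])
    keep = np.array([lab not in exclude for lab in training.labels])
    q = int(keep.sum())
    if q < 2:
        raise DataError(f"need at least 2 samples after exclusion, got {q}")
    F = training.spectra[:, keep]
    mean = F.mean(axis=1)
    centered = F - mean[:, None]
    cov = (centered @ centered.T) / (q - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(-vals, kind="stable")
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    # sign convention: largest-|entry| of each column is positive
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip
    classes = [c for c in training.classes if c not in exclude]
    return PCABasis(mean, vecs, vals, training.band_edges, classes)


def _check_m(basis: PCABasis, m: int) -> None:
    if not 0 <= m <= basis.n_bands:
        raise ParameterError(f"m must be in [0, {basis.n_bands}], got {m}")


def explained_variance(basis: PCABasis, m: int) -> float:
    """Fraction of total variance captured by the first m components."""
    _check_m(basis, m)
    total = basis.eigenvalues.sum()
    if total == 0.0:
        return 1.0 if m == basis.n_bands else 0.0
    return float(basis.eigenvalues[:m].sum() / total)


def reconstruct(basis: PCABasis, spectrum: np.ndarray, m: int) -> np.ndarray:
    """Estimate a spectrum from the mean and its first-m PC coefficients.

    f̂ = f̄ + Σ_{i≤m} α_i v_i with α_i = v_iᵀ(f − f̄): the orthogonal
    projection of the centered spectrum onto the leading components.
    """
    _check_m(basis, m)
    f = np.asarray(spectrum, dtype=float)
    if f.shape != (basis.n_bands,):
        raise DimensionError(
            f"spectrum has shape {f.shape}, expected ({basis.n_bands},)"
        )
    V = basis.eigenvectors[:, :m]
    coeffs = V.T @ (f - basis.mean)
    return basis.mean + V @ coeffs


def spectral_error(basis: PCABasis, spectrum: np.ndarray, m: int) -> SpectralError:
    """Spectral error e = f − f̂ of a spectrum under the m-component estimate."""
    f = np.asarray(spectrum, dtype=float)
    return SpectralError(f - reconstruct(basis, f, m), m_used=m)
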