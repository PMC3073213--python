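"""Multispectral cube and ROI-mask I/O, transmittance, and band reduction.

A multispectral acquisition is stored as a multi-page TIFF (one page per
band, 16-bit unsigned) plus a plain-text wavelength *sidecar* with one
``lo_nm hi_nm`` pair per line, in page order.  Degenerate bands with
``lo == hi`` are permitted and denote point samples on a wavelength grid
(the native 55-band capture at 5 nm spacing is such a grid); averaged bands
produced by :func:`band_average` are proper intervals spanning the first to
the last member wavelength, which reproduces the published 14-band scheme
(band 1 = 450–465 nm, …, band 14 = 710–720 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DataError, DimensionError, FormatError, ParameterError
from .pca import LabeledSpectrumSet

__all__ = [
    "SpectralCube",
    "ReferenceSignal",
    "RoiMask",
    "read_sidecar",
    "write_sidecar",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "compute_transmittance",
    "band_average",
    "extract_labeled_spectra",
]

#: floor applied to the glass reference, as a fraction of its maximum
REFERENCE_FLOOR_FRACTION = 1e-6


def _validate_band_edges(band_edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise FormatError("band_edges must be an (N, 2) array of (lo_nm, hi_nm) pairs")
    if np.any(edges[:, 0] > edges[:, 1]):
        raise FormatError("each band must satisfy lo_nm <= hi_nm")
    if len(edges) > 1:
        if np.any(np.diff(edges[:, 0]) <= 0):
            raise FormatError("bands must be sorted strictly ascending by lo_nm")
        if np.any(edges[:-1, 1] > edges[1:, 0]):
            raise FormatError("bands must not overlap")
    return edges


@dataclass
class SpectralCube:
    """H×W×N image cube with per-band wavelength ranges.

    ``kind`` is ``"raw"`` for camera counts and ``"transmittance"`` for
    glass-normalized data.  Transmittance values slightly above 1 are kept:
    noise can push blank-glass pixels above unity and clipping would bias a
    downstream PCA fit.
    """

    pixels: np.ndarray
    band_edges: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError("cube pixels must be H×W×N")
        self.band_edges = _validate_band_edges(self.band_edges)
        if self.pixels.shape[2] != len(self.band_edges):
            raise FormatError(
                f"cube has {self.pixels.shape[2]} bands but sidecar lists "
                f"{len(self.band_edges)}"
            )
        if self.kind not in ("raw", "transmittance"):
            raise ParameterError(f"unknown cube kind {self.kind!r}")
        if self.kind == "transmittance" and np.any(self.pixels < 0):
            raise FormatError("transmittance values must be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def band_centers(self) -> np.ndarray:
        """Center wavelength of each band in nm."""
        return self.band_edges.mean(axis=1)


@dataclass
class ReferenceSignal:
    """Per-band glass (blank) signal: a length-N vector or an H×W×N cube."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 3):
            raise FormatError("reference must be a length-N vector or H×W×N cube")

    def floored(self) -> np.ndarray:
        """Reference clamped away from zero so the transmittance ratio is defined."""
        floor = REFERENCE_FLOOR_FRACTION * float(self.values.max(initial=0.0))
        if floor <= 0.0:
            raise DataError("reference signal is everywhere zero")
        return np.maximum(self.values, floor)


@dataclass
class RoiMask:
    """Integer label image with a label→class-name map; 0 is unlabeled."""

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("mask labels must be a 2-D integer array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.class_names)
        if missing:
            raise FormatError(f"labels {sorted(missing)} have no class name")

    def label_of(self, class_name: str) -> int:
        for label, name in self.class_names.items():
            if name == class_name:
                return label
        raise ParameterError(f"class {class_name!r} not present in mask")


def read_sidecar(path: str | Path) -> np.ndarray:
    """Read a wavelength sidecar: one ``lo_nm hi_nm`` pair per line."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"sidecar line {line!r} is not 'lo_nm hi_nm'")
        edges.append((float(parts[0]), float(parts[1])))
    if not edges:
        raise FormatError(f"sidecar {path} lists no bands")
    return _validate_band_edges(np.array(edges))


def write_sidecar(band_edges: np.ndarray, path: str | Path) -> None:
    edges = _validate_band_edges(band_edges)
    lines = [f"{lo:g} {hi:g}" for lo, hi in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path, sidecar_path: str | Path) -> SpectralCube:
    """Read a multi-page TIFF cube (one page per band) and its sidecar."""
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:  # single page
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected one 2-D page per band")
    edges = read_sidecar(sidecar_path)
    if pages.shape[0] != len(edges):
        raise FormatError(
            f"{path}: {pages.shape[0]} TIFF pages but sidecar lists {len(edges)} bands"
        )
    return SpectralCube(np.moveaxis(pages, 0, -1), edges, kind="raw")


def write_cube(cube: SpectralCube, path: str | Path, sidecar_path: str | Path) -> None:
    """Write a cube as a multi-page TIFF plus wavelength sidecar.

    Raw cubes are written with their native (16-bit) dtype; transmittance
    cubes as 32-bit float.
    """
    pages = np.moveaxis(cube.pixels, -1, 0)
    if cube.kind == "transmittance":
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages)
    write_sidecar(cube.band_edges, sidecar_path)


def read_mask(path: str | Path, class_names: dict[int, str]) -> RoiMask:
    labels = np.asarray(iio.imread(path))
    if labels.ndim == 3:  # greyscale PNG decoded with a channel axis
        labels = labels[..., 0]
    return RoiMask(labels.astype(np.int64), dict(class_names))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    labels = mask.labels
    if labels.max(initial=0) > 255:
        raise FormatError("more than 255 labels; cannot write 8-bit mask")
    iio.imwrite(path, labels.astype(np.uint8))


def compute_transmittance(
    specimen: SpectralCube,
    reference: ReferenceSignal,
    clip: bool = False,
) -> SpectralCube:
    """Per-band ratio of specimen signal to glass signal.

    The transmittance of pixel spectrum i_s against glass signal i_g is
    t = i_s / i_g per band.  The reference is floored to a small positive
    fraction of its maximum before division.  With ``clip=True`` the result
    is clipped to [0, 1.05]; by default values above 1 are kept.
    """
    if specimen.kind != "raw":
        raise ParameterError("specimen must be a raw cube")
    ref = reference.floored()
    if ref.ndim == 1:
        if ref.shape[0] != specimen.n_bands:
            raise DimensionError(
                f"reference has {ref.shape[0]} bands, specimen {specimen.n_bands}"
            )
    elif ref.shape != specimen.pixels.shape:
        raise DimensionError("reference cube shape does not match specimen")
    t = specimen.pixels.astype(float) / ref
    if clip:
        t = np.clip(t, 0.0, 1.05)
    return SpectralCube(t, specimen.band_edges.copy(), kind="transmittance")


def band_average(cube: SpectralCube, group_size: int) -> SpectralCube:
    """Reduce the cube by averaging ``group_size`` contiguous bands.

    Grouping is sequential from the first band; a final partial group is
    averaged over its actual members (the 55-band 5 nm grid reduced in
    fours ends with a 3-member band spanning 710–720 nm).  Each output
    band spans from the lo of its first member to the hi of its last.
    """
    if group_size < 1:
        raise ParameterError("group_size must be >= 1")
    n = cube.n_bands
    if group_size > n:
        raise ParameterError(f"group_size {group_size} exceeds band count {n}")
    starts = range(0, n, group_size)
    planes = []
    edges = []
    for lo_idx in starts:
        hi_idx = min(lo_idx + group_size, n)
        planes.append(cube.pixels[:, :, lo_idx:hi_idx].mean(axis=2))
        edges.append((cube.band_edges[lo_idx, 0], cube.band_edges[hi_idx - 1, 1]))
    return SpectralCube(np.stack(planes, axis=-1), np.array(edges), kind=cube.kind)


def extract_labeled_spectra(
    cube: SpectralCube,
    mask: RoiMask,
    classes: list[str],
) -> LabeledSpectrumSet:
    """Collect per-pixel spectra for the requested classes.

    Pixels are scanned in row-major order, so the column order of the
    resulting training matrix is reproducible.  An empty class raises a
    warning; only if *all* requested classes are empty is it an error.
    """
    if mask.labels.shape != cube.shape:
        raise DimensionError("mask shape does not match cube")
    name_by_label = mask.class_names
    wanted = {label for label, name in name_by_label.items() if name in classes}
    unknown = set(classes) - set(name_by_label.values())
    if unknown:
        raise ParameterError(f"classes {sorted(unknown)} not present in mask")
    selected = np.isin(mask.labels, list(wanted))
    rows, cols = np.nonzero(selected)  # row-major order
    labels_flat = mask.labels[rows, cols]
    spectra = cube.pixels[rows, cols, :].T.astype(float)  # n × q
    sample_names = [name_by_label[int(v)] for v in labels_flat]
    for cls in classes:
        if cls not in sample_names:
            warnings.warn(f"class {cls!r} has no labeled pixels", stacklevel=2)
    if spectra.shape[1] == 0:
        raise DataError("no labeled pixels found for any requested class")
    return LabeledSpectrumSet(spectra, sample_names, cube.band_edges.copy())
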