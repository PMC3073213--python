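"""Persistence of a fitted spectral-residual model.

A model bundles everything the ``segment`` step needs: the PCA basis
(mean, eigenpairs, band edges, training classes), the number of components
m, and the band pair (r, s) identified offline from the target class's
mean residual.  It is stored as a single YAML document so a fitted model
is human-inspectable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .bands import BandPair
from .errors import FormatError
from .pca import PCABasis

__all__ = ["SpectralResidualModel", "save_model", "load_model"]


@dataclass
class SpectralResidualModel:
    basis: PCABasis
    m: int
    pair: BandPair


def save_model(model: SpectralResidualModel, path: str | Path) -> None:
    basis, pair = model.basis, model.pair
    doc = {
        "m": int(model.m),
        "classes": list(basis.classes),
        "mean": basis.mean.tolist(),
        "eigenvalues": basis.eigenvalues.tolist(),
        "eigenvectors": basis.eigenvectors.tolist(),
        "band_edges": None if basis.band_edges is None else np.asarray(basis.band_edges).tolist(),
        "band_pair": {
            "r": int(pair.r),
            "s": int(pair.s),
            "mean_error": pair.mean_error.tolist(),
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> SpectralResidualModel:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        basis = PCABasis(
            mean=np.array(doc["mean"], dtype=float),
            eigenvectors=np.array(doc["eigenvectors"], dtype=float),
            eigenvalues=np.array(doc["eigenvalues"], dtype=float),
            band_edges=None if doc["band_edges"] is None else np.array(doc["band_edges"]),
            classes=list(doc["classes"]),
        )
        pair = BandPair(
            r=int(doc["band_pair"]["r"]),
            s=int(doc["band_pair"]["s"]),
            mean_error=np.array(doc["band_pair"]["mean_error"], dtype=float),
        )
        return SpectralResidualModel(basis=basis, m=int(doc["m"]), pair=pair)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path} is not a valid model file: {exc}") from exc
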