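"""Synthetic multispectral H&E phantoms with exact ground truth.

Tissue classes are modeled through Beer–Lambert transmittance

    T(λ) = 10^(−[c_H·a_H(λ) + c_E·a_E(λ) + p(λ)])

where a_H, a_E are hematoxylin and eosin absorbance curves (smooth
two-Gaussian parameterizations sampled on the band grid), (c_H, c_E) are
per-class dye loadings, and p(λ) is a small spectral perturbation that is
zero for every class except the eosinophil.  The perturbation is a dipole
straddling the hematoxylin absorption peak — extra absorption in the
570–585 nm band and a deficit in the 630–645 nm band — encoding the
hypothesis that eosinophils differ from RBCs chiefly in their hematoxylin
uptake.  Under a PCA basis fit to the other five classes the eosinophil
residual therefore peaks negative at band 7 and positive at band 10 of the
14-band grid, which is the signature the segmentation pipeline exploits.

Within-class variability is a per-pixel lognormal brightness factor;
acquisition noise is multiplicative Gaussian per band.  All randomness
flows from a single seeded generator so scenes are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import GenerationError, ParameterError
from .io import RoiMask, SpectralCube
from .pca import LabeledSpectrumSet

__all__ = [
    "DyeSpectrum",
    "TissueClassModel",
    "PhantomConfig",
    "PhantomScene",
    "table1_band_edges",
    "fine_band_edges",
    "hematoxylin_absorbance",
    "eosin_absorbance",
    "default_dyes",
    "default_class_models",
    "endmember_transmittance",
    "generate_phantom",
    "generate_training_set",
    "IN_MODEL_CLASSES",
    "TARGET_CLASS",
]

#: the five classes represented in the PCA training set
IN_MODEL_CLASSES = ["nucleus", "cytoplasm", "rbc", "fiber", "white"]
#: the class excluded from training and recovered by the residual
TARGET_CLASS = "eosinophil"

# dye curve parameters (nm): peak center and Gaussian width; hematoxylin
# additionally has a flat broadband term (its absorption tails far into the
# red, which is why nuclei look dark blue rather than cyan)
_HEMATOXYLIN_PEAK, _HEMATOXYLIN_SIGMA, _HEMATOXYLIN_BROADBAND = 600.0, 45.0, 0.2
_EOSIN_PEAK, _EOSIN_SIGMA = 525.0, 30.0
# eosinophil perturbation dipole: lobes at the band-7 and band-10 centers of
# the 14-band grid.  Narrow lobes (σ 6 nm) keep the dipole nearly orthogonal
# to the smooth in-model endmembers; the lobe weights compensate for the
# lower transmittance headroom under the eosin peak at 577.5 nm so that the
# PCA residual's negative extremum lands on band 7 rather than on projection
# ringing at neighboring bands.
_PERTURB_NEG_NM, _PERTURB_POS_NM, _PERTURB_SIGMA = 577.5, 637.5, 6.0
_PERTURB_NEG_WEIGHT, _PERTURB_POS_WEIGHT = 1.3, 0.8


def table1_band_edges() -> np.ndarray:
    """The 14-band scheme: 20 nm steps from 450 nm, 15 nm span each,
    final band 710–720 nm."""
    edges = [(450.0 + 20.0 * k, 465.0 + 20.0 * k) for k in range(13)]
    edges.append((710.0, 720.0))
    return np.array(edges)


def fine_band_edges() -> np.ndarray:
    """The native 55-band grid: point samples at 450, 455, …, 720 nm."""
    wl = 450.0 + 5.0 * np.arange(55)
    return np.stack([wl, wl], axis=1)


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def hematoxylin_absorbance(band_centers: np.ndarray) -> np.ndarray:
    """Hematoxylin absorbance per unit concentration: a peak near 600 nm
    (within bands 7–10 of the 14-band grid) on a flat broadband floor."""
    x = np.asarray(band_centers, float)
    return _gaussian(x, _HEMATOXYLIN_PEAK, _HEMATOXYLIN_SIGMA) + _HEMATOXYLIN_BROADBAND


def eosin_absorbance(band_centers: np.ndarray) -> np.ndarray:
    """Eosin absorbance per unit concentration, peaking near 525 nm."""
    return _gaussian(np.asarray(band_centers, float), _EOSIN_PEAK, _EOSIN_SIGMA)


@dataclass
class DyeSpectrum:
    """Named absorbance curve on the working band grid (OD per unit conc.)."""

    name: str
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(self.absorbance < 0):
            raise ParameterError("dye absorbance must be nonnegative")


def default_dyes(band_centers: np.ndarray) -> dict[str, DyeSpectrum]:
    return {
        "hematoxylin": DyeSpectrum("hematoxylin", hematoxylin_absorbance(band_centers)),
        "eosin": DyeSpectrum("eosin", eosin_absorbance(band_centers)),
    }


@dataclass
class TissueClassModel:
    """Per-class optics and geometry of the phantom."""

    name: str
    c_hematoxylin: float
    c_eosin: float
    spectral_perturbation: np.ndarray | None = None
    shape: str = "ellipse"  # or "background"
    area_fraction: float = 0.0
    axis_range: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.c_hematoxylin < 0 or self.c_eosin < 0:
            raise ParameterError("dye loadings must be nonnegative")


def eosinophil_perturbation(band_centers: np.ndarray, delta: float) -> np.ndarray:
    """Absorbance dipole distinguishing eosinophils from RBC: extra
    absorption around 577.5 nm (lower transmittance → negative residual at
    band 7) and an absorption deficit around 637.5 nm (positive residual at
    band 10)."""
    x = np.asarray(band_centers, float)
    return delta * (
        _PERTURB_NEG_WEIGHT * _gaussian(x, _PERTURB_NEG_NM, _PERTURB_SIGMA)
        - _PERTURB_POS_WEIGHT * _gaussian(x, _PERTURB_POS_NM, _PERTURB_SIGMA)
    )


def default_class_models(
    band_centers: np.ndarray, eosinophil_delta: float = 0.06
) -> dict[str, TissueClassModel]:
    """The six-class H&E scene: cytoplasm background, ellipse inclusions.

    Loadings are chosen so nuclei are hematoxylin-dominated (blue-purple),
    RBC and eosinophils eosin-dominated (pink-red) with nearly identical
    broadband color, fiber intermediate, and white area unstained.
    """
    perturb = eosinophil_perturbation(band_centers, eosinophil_delta)
    return {
        "cytoplasm": TissueClassModel("cytoplasm", 0.20, 0.40, shape="background"),
        "nucleus": TissueClassModel("nucleus", 1.60, 0.15, area_fraction=0.08),
        "rbc": TissueClassModel("rbc", 0.08, 1.50, area_fraction=0.06),
        "fiber": TissueClassModel("fiber", 0.15, 0.90, area_fraction=0.08),
        "white": TissueClassModel("white", 0.0, 0.0, area_fraction=0.10),
        "eosinophil": TissueClassModel(
            "eosinophil", 0.08, 1.50,
            spectral_perturbation=perturb, area_fraction=0.04,
        ),
    }


def endmember_transmittance(
    model: TissueClassModel, dyes: dict[str, DyeSpectrum]
) -> np.ndarray:
    """Noise-free class transmittance under the Beer–Lambert model."""
    absorbance = (
        model.c_hematoxylin * dyes["hematoxylin"].absorbance
        + model.c_eosin * dyes["eosin"].absorbance
    )
    if model.spectral_perturbation is not None:
        absorbance = absorbance + model.spectral_perturbation
    return np.power(10.0, -absorbance)


@dataclass
class PhantomConfig:
    """Generator settings; the defaults define the study conditions."""

    height: int = 256
    width: int = 256
    fine_grid: bool = False  # True → native 55-band point-sample grid
    within_class_cv: float = 0.02
    noise_sd: float = 0.005
    eosinophil_delta: float = 0.06
    class_order: list[str] = field(
        default_factory=lambda: ["white", "fiber", "nucleus", "rbc", "eosinophil"]
    )
    max_retries_per_class: int = 5000

    def band_edges(self) -> np.ndarray:
        return fine_band_edges() if self.fine_grid else table1_band_edges()


@dataclass
class PhantomScene:
    cube: SpectralCube
    truth: RoiMask
    params: dict


def _class_setup(config: PhantomConfig):
    edges = config.band_edges()
    centers = edges.mean(axis=1)
    dyes = default_dyes(centers)
    models = default_class_models(centers, config.eosinophil_delta)
    return edges, dyes, models


def _place_shapes(
    labels: np.ndarray,
    label_value: int,
    model: TissueClassModel,
    rng: np.random.Generator,
    max_retries: int,
) -> None:
    h, w = labels.shape
    target_px = model.area_fraction * h * w
    placed = 0
    retries = 0
    lo, hi = model.axis_range
    while placed < target_px:
        r0 = rng.uniform(0, h)
        c0 = rng.uniform(0, w)
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        rot = rng.uniform(0, np.pi)
        # require a 1-px margin of free background around the new shape
        rr_m, cc_m = draw_ellipse(r0, c0, a + 1, b + 1, shape=(h, w), rotation=rot)
        rr, cc = draw_ellipse(r0, c0, a, b, shape=(h, w), rotation=rot)
        if len(rr) == 0 or np.any(labels[rr_m, cc_m] != 0):
            retries += 1
            if retries > max_retries:
                raise GenerationError(
                    f"could not place {model.name!r} shapes without overlap "
                    f"after {max_retries} retries"
                )
            continue
        labels[rr, cc] = label_value
        placed += len(rr)


def _noisy_samples(
    endmember: np.ndarray,
    n: int,
    cv: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """n samples of a class: endmember × lognormal pixel factor ×
    per-band multiplicative Gaussian noise.  Returns (n, N)."""
    factor = (
        rng.lognormal(mean=-0.5 * cv**2, sigma=cv, size=(n, 1)) if cv > 0
        else np.ones((n, 1))
    )
    noise = 1.0 + rng.normal(0.0, noise_sd, size=(n, endmember.size)) if noise_sd > 0 \
        else np.ones((n, endmember.size))
    return np.clip(endmember[None, :] * factor * noise, 0.0, None)


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> PhantomScene:
    """Generate a phantom scene: ellipse inclusions of each foreground class
    on a cytoplasm background, with an exact ground-truth mask.

    Deterministic given the seed.  Shapes never overlap; placement fails
    with a generation error if the requested area fractions cannot be
    realized after bounded retries.
    """
    config = config or PhantomConfig()
    if config.height < 64 or config.width < 64:
        raise ParameterError("phantom must be at least 64×64")
    edges, dyes, models = _class_setup(config)
    rng = np.random.default_rng(seed)

    class_order = ["cytoplasm"] + list(config.class_order)
    if set(class_order) != set(models):
        raise ParameterError(f"class_order must cover {sorted(models)}")
    labels = np.zeros((config.height, config.width), dtype=np.int64)
    for value, name in enumerate(class_order, start=1):
        model = models[name]
        if model.shape == "background":
            continue
        _place_shapes(labels, value, model, rng, config.max_retries_per_class)
    labels[labels == 0] = 1  # cytoplasm background

    endmembers = np.stack(
        [endmember_transmittance(models[name], dyes) for name in class_order]
    )
    pix = endmembers[labels - 1]  # H×W×N
    h, w, n = pix.shape
    if config.within_class_cv > 0:
        pix = pix * rng.lognormal(
            mean=-0.5 * config.within_class_cv**2,
            sigma=config.within_class_cv,
            size=(h, w, 1),
        )
    if config.noise_sd > 0:
        pix = pix * (1.0 + rng.normal(0.0, config.noise_sd, size=(h, w, n)))
    cube = SpectralCube(np.clip(pix, 0.0, None), edges, kind="transmittance")
    truth = RoiMask(labels, {i + 1: name for i, name in enumerate(class_order)})
    params = {
        "seed": seed,
        "height": config.height,
        "width": config.width,
        "fine_grid": config.fine_grid,
        "within_class_cv": config.within_class_cv,
        "noise_sd": config.noise_sd,
        "eosinophil_delta": config.eosinophil_delta,
        "class_labels": {i + 1: name for i, name in enumerate(class_order)},
        "area_fractions": {
            name: models[name].area_fraction for name in config.class_order
        },
    }
    return PhantomScene(cube=cube, truth=truth, params=params)


def generate_training_set(
    config: PhantomConfig | None = None,
    seed: int = 0,
    n_per_class: int = 600,
    classes: list[str] | None = None,
) -> LabeledSpectrumSet:
    """Draw labeled training spectra from the class models.

    By default only the five in-model classes are sampled; target-class
    (eosinophil) spectra for band selection are drawn by a separate call
    with ``classes=["eosinophil"]`` and are never mixed into the
    in-model set.
    """
    config = config or PhantomConfig()
    if n_per_class < 2:
        raise ParameterError("n_per_class must be >= 2")
    edges, dyes, models = _class_setup(config)
    classes = list(classes) if classes is not None else list(IN_MODEL_CLASSES)
    unknown = [c for c in classes if c not in models]
    if unknown:
        raise ParameterError(f"unknown class names {unknown}")
    rng = np.random.default_rng(seed)
    blocks = []
    labels: list[str] = []
    for name in classes:
        em = endmember_transmittance(models[name], dyes)
        blocks.append(
            _noisy_samples(em, n_per_class, config.within_class_cv,
                           config.noise_sd, rng)
        )
        labels.extend([name] * n_per_class)
    spectra = np.concatenate(blocks, axis=0).T  # n_bands × q
    return LabeledSpectrumSet(spectra, labels, edges)
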