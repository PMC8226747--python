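"""Macenko stain normalization for H&E histopathology tiles.

Pixels of a transmitted-light image follow the Beer-Lambert law: in optical
density (OD) space, OD = log10(I_t / I), a pixel is a non-negative linear
combination of the two dye absorption vectors (hematoxylin and eosin).  The
Macenko estimator finds those vectors as the robust angular extremes of the
OD point cloud projected onto its top-2 SVD plane; normalization then
re-renders each tile's per-pixel stain concentrations through a fixed
reference basis so that slides share one color appearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainEstimationError",
    "InsufficientTissueError",
    "DegenerateStainPlaneError",
    "StainBasis",
    "NormalizationConfig",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_basis",
    "compute_concentrations",
    "normalize_image",
    "histogram_report",
]


class StainEstimationError(ValueError):
    """Base class for stain-estimation failures."""


class InsufficientTissueError(StainEstimationError):
    """Too few pixels survive the OD (beta) threshold — blank or faint tile."""


class DegenerateStainPlaneError(StainEstimationError):
    """The OD cloud is effectively rank-1 (single stain); no plane exists."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length stain vector")
    return v / n


@dataclass(frozen=True)
class StainBasis:
    """Two unit-norm, component-wise non-negative OD absorption vectors."""

    hematoxylin: np.ndarray
    eosin: np.ndarray

    def __post_init__(self):
        for name in ("hematoxylin", "eosin"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if (v < -1e-12).any():
                raise ValueError(f"{name} has negative components")
            object.__setattr__(self, name, _unit(np.maximum(v, 0.0)))
        m = self.matrix
        if np.linalg.matrix_rank(m) < 2:
            raise ValueError("stain vectors are linearly dependent")

    @property
    def matrix(self) -> np.ndarray:
        """3x2 matrix [h | e] mapping concentrations to OD."""
        return np.stack([self.hematoxylin, self.eosin], axis=1)


#: Canonical H&E absorption basis and the matching reference maximum
#: concentrations, as popularized by the reference Macenko implementation.
CANONICAL_HE = StainBasis(
    hematoxylin=np.array([0.5626, 0.7201, 0.4062]),
    eosin=np.array([0.2159, 0.8012, 0.5581]),
)
CANONICAL_MAX_CONC = np.array([1.9705, 1.0308])

#: Default normalization target: the canonical concentration pair scaled so
#: that the standard appearance of a typical tile centers near the 8-bit
#: midpoint (127), which is how normalized histograms are expected to look.
DEFAULT_MAX_CONC = 0.75 * CANONICAL_MAX_CONC


@dataclass
class NormalizationConfig:
    """Knobs of the normalization pipeline.

    ``i0``: transmitted light intensity (240); ``beta``: OD threshold below
    which pixels count as background (0.15); ``alpha``: robust angle
    percentile in percent (1); ``conc_percentile``: concentration percentile
    matched to ``reference_max_conc`` (99).  ``beta_rule`` selects whether a
    pixel is discarded when *any* channel is <= beta (default, strictest
    reading) or only when *all* channels are.
    """

    i0: float = 240.0
    beta: float = 0.15
    alpha: float = 1.0
    conc_percentile: float = 99.0
    beta_rule: str = "any"
    min_pixels: int = 100
    reference_basis: StainBasis = field(default_factory=lambda: CANONICAL_HE)
    reference_max_conc: np.ndarray = field(
        default_factory=lambda: DEFAULT_MAX_CONC.copy())

    def __post_init__(self):
        if not (0 < self.i0 <= 255):
            raise ValueError("i0 must be in (0, 255]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0 < self.alpha < 50):
            raise ValueError("alpha must be in (0, 50)")
        if not (50 < self.conc_percentile <= 100):
            raise ValueError("conc_percentile must be in (50, 100]")
        if self.beta_rule not in ("any", "all"):
            raise ValueError("beta_rule must be 'any' or 'all'")


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("RGB pixels must be integers in [0, 255]")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("RGB pixel values out of [0, 255]")
    return img


def rgb_to_od(image: np.ndarray, i0: float = 240.0) -> np.ndarray:
    """OD = log10(I_t / I) per channel, intensities clamped to >= 1 before the
    log so OD stays finite; pixels brighter than I_t clip to OD 0."""
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    img = _validate_rgb(image)
    od = np.log10(i0 / np.maximum(img.astype(np.float64), 1.0))
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, i0: float = 240.0) -> np.ndarray:
    """Inverse transform I = round(I_t * 10^-OD), clipped to [0, 255]."""
    od = np.asarray(od, dtype=np.float64)
    if (od < 0).any():
        raise ValueError("optical density must be non-negative")
    return np.clip(np.rint(i0 * np.power(10.0, -od)), 0, 255).astype(np.uint8)


def _tissue_od(image, config) -> np.ndarray:
    od = rgb_to_od(image, config.i0).reshape(-1, 3)
    if config.beta_rule == "any":
        keep = (od > config.beta).all(axis=1)
    else:
        keep = (od > config.beta).any(axis=1)
    return od[keep]


def estimate_stain_basis(image: np.ndarray,
                         config: NormalizationConfig | None = None) -> StainBasis:
    """Estimate the two-stain OD basis of a tile (Macenko SVD-plane method).

    Background pixels are removed by the beta threshold; the surviving OD
    tuples are projected onto their top-2 SVD plane; the alpha-th and
    (100-alpha)-th percentile of the in-plane angles give the two extreme
    directions, which map back to OD space as the stain vectors.  The vector
    with the larger red-channel OD component is hematoxylin (hematoxylin
    absorbs red light most strongly); green breaks exact ties.
    """
    config = config or NormalizationConfig()
    od = _tissue_od(image, config)
    if len(od) < config.min_pixels:
        raise InsufficientTissueError(
            f"only {len(od)} pixels above beta={config.beta}; "
            f"need at least {config.min_pixels}")
    # plane of the top-2 right singular vectors of the OD cloud
    _, s, vt = np.linalg.svd(od, full_matrices=False)
    # uint8 quantization alone contributes ~0.4% relative spread, so the
    # rank test must tolerate it; a genuine two-stain cloud sits far above
    if s[1] < 0.01 * s[0]:
        raise DegenerateStainPlaneError(
            "OD cloud is rank-1 (single stain); cannot span a stain plane")
    plane = vt[:2].T  # 3x2
    # orient plane vectors so projections land in a consistent half-space
    for j in range(2):
        if plane[:, j].sum() < 0:
            plane[:, j] = -plane[:, j]
    proj = od @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, (config.alpha, 100.0 - config.alpha))
    v1 = plane @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = plane @ np.array([np.cos(phi_max), np.sin(phi_max)])
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        vecs.append(_unit(np.maximum(v, 0.0)))
    a, b = vecs
    # hematoxylin absorbs red the most -> larger red OD component
    if (a[0], a[1]) >= (b[0], b[1]):
        return StainBasis(hematoxylin=a, eosin=b)
    return StainBasis(hematoxylin=b, eosin=a)


def compute_concentrations(od: np.ndarray, basis: StainBasis,
                           max_condition: float = 1e6) -> np.ndarray:
    """Per-pixel least-squares stain concentrations, negatives clipped to 0.

    Solves od ~= c_h * h + c_e * e for every pixel of an (..., 3) OD array;
    returns an (..., 2) concentration array.
    """
    m = basis.matrix
    if np.linalg.cond(m) > max_condition:
        raise ValueError("stain basis is near-parallel; deconvolution unstable")
    od = np.asarray(od, dtype=np.float64)
    flat = od.reshape(-1, 3)
    conc = flat @ np.linalg.pinv(m).T
    return np.maximum(conc, 0.0).reshape(od.shape[:-1] + (2,))


def normalize_image(image: np.ndarray,
                    config: NormalizationConfig | None = None) -> np.ndarray:
    """Re-render a tile against the reference stain basis.

    Concentrations are computed against the tile's own estimated basis, each
    stain channel is rescaled so its ``conc_percentile``-th percentile (over
    tissue pixels) matches ``reference_max_conc``, and the result is rendered
    through ``reference_basis`` back to RGB.
    """
    config = config or NormalizationConfig()
    basis = estimate_stain_basis(image, config)
    od = rgb_to_od(image, config.i0)
    conc = compute_concentrations(od, basis)
    flat = conc.reshape(-1, 2)
    tissue = flat[(flat > 0.0).any(axis=1)]
    max_conc = np.percentile(tissue if len(tissue) else flat,
                             config.conc_percentile, axis=0)
    scale = np.divide(np.asarray(config.reference_max_conc, dtype=np.float64),
                      max_conc, out=np.ones(2), where=max_conc > 1e-12)
    od_new = (flat * scale) @ config.reference_basis.matrix.T
    return od_to_rgb(od_new.reshape(od.shape), config.i0)


def histogram_report(images: list[np.ndarray]) -> dict:
    """Per-image 256-bin intensity histograms + summary statistics.

    Intensity is the rounded per-pixel channel mean, so each histogram sums
    to H*W.  Returns ``{"histograms": [...], "mean": [...],
    "variance": [...]}`` with one entry per image.
    """
    if not images:
        raise ValueError("need at least one image")
    hists, means, variances = [], [], []
    for img in images:
        img = _validate_rgb(img)
        gray = np.rint(img.mean(axis=2)).astype(np.intp).reshape(-1)
        hists.append(np.bincount(gray, minlength=256)[:256])
        means.append(float(gray.mean()))
        variances.append(float(gray.var()))
    return {"histograms": hists, "mean": means, "variance": variances}
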