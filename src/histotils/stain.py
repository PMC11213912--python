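"""Masked Macenko stain deconvolution and the tile informativeness score.

H&E color formation follows the Beer-Lambert law in optical density (OD)
space: ``od = S @ c`` where the columns of the 3x2 stain matrix ``S`` are the
unit OD vectors of hematoxylin and eosin and ``c`` the per-pixel stain
concentrations.  The Macenko estimator recovers ``S`` from the angular
extremes of the masked OD cloud projected onto its top-2 singular plane.

The tile informativeness score used to rank slide tiles at low resolution is
the product of mean hematoxylin and mean eosin concentration over tissue
pixels; tiles mixing cellular (hematoxylin-rich) and acellular (eosin-rich)
material - i.e. peritumoral stroma - score highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Reference H&E optical-density unit vectors (columns: hematoxylin, eosin).
DEFAULT_STAIN_VECTORS = np.array(
    [[0.65, 0.07],
     [0.70, 0.99],
     [0.29, 0.11]]
) / np.linalg.norm([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], axis=0)

#: Pixels brighter than this mean RGB are treated as white space.
WHITE_RGB_THRESHOLD = 220.0
#: Minimum OD magnitude for a pixel to count as tissue.
MIN_TISSUE_OD = 0.05
#: Minimum masked-pixel fraction for a tile to be scoreable.
MIN_TISSUE_FRACTION = 0.05


class StainEstimationError(RuntimeError):
    """Raised when a stain matrix cannot be estimated; fall back to defaults."""


@dataclass(frozen=True)
class StainMatrix:
    """3x2 matrix of unit OD vectors, hematoxylin column first."""

    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=np.float64)
        if S.shape != (3, 2):
            raise ValueError(f"stain matrix must be 3x2, got {S.shape}")
        norms = np.linalg.norm(S, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            S = S / norms
        ang = angle_between_deg(S[:, 0], S[:, 1])
        if ang <= 10.0:
            raise StainEstimationError(
                f"stain vectors nearly parallel ({ang:.2f} deg apart)"
            )
        object.__setattr__(self, "S", S)


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(abs(c), -1.0, 1.0))))


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density: ``-log10((rgb + 1) / 256)``."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return -np.log10((rgb + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (float result, not quantized)."""
    return 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0


def tissue_mask_for_stains(rgb: np.ndarray) -> np.ndarray:
    """Tissue pixels for masked deconvolution: non-white and with real OD."""
    rgb = np.asarray(rgb, dtype=np.float64)
    od = rgb_to_od(rgb)
    return (rgb.mean(axis=-1) < WHITE_RGB_THRESHOLD) & (
        np.linalg.norm(od, axis=-1) > MIN_TISSUE_OD
    )


def _order_hematoxylin_first(S: np.ndarray) -> np.ndarray:
    # hematoxylin absorbs strongly in red, eosin barely: the hematoxylin
    # column is the one with the larger red/blue OD ratio
    ratio = S[0] / np.maximum(S[2], 1e-12)
    if ratio[0] >= ratio[1]:
        return S
    return S[:, ::-1]


def estimate_stain_matrix(
    od: np.ndarray,
    mask: np.ndarray,
    angle_percentiles: tuple = (1.0, 99.0),
    min_pixels: int = 100,
) -> StainMatrix:
    """Macenko estimation of the H&E stain matrix from masked OD pixels.

    Projects masked OD onto the top-2 right-singular plane and takes the
    angular extremes (robust percentiles) as the stain directions.
    """
    pixels = np.asarray(od, dtype=np.float64).reshape(-1, 3)[
        np.asarray(mask, bool).reshape(-1)
    ]
    if pixels.shape[0] < min_pixels:
        raise StainEstimationError(
            f"only {pixels.shape[0]} masked pixels (< {min_pixels}); "
            "fall back to default stain vectors"
        )
    # top-2 singular plane of the OD cloud
    _, _, vt = np.linalg.svd(pixels, full_matrices=False)
    basis = vt[:2]  # 2 x 3
    # orient basis so projections land in a consistent half-plane
    basis = basis * np.where(basis.sum(axis=1, keepdims=True) < 0, -1.0, 1.0)
    proj = pixels @ basis.T  # n x 2
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, angle_percentiles)
    v1 = np.array([np.cos(lo), np.sin(lo)]) @ basis
    v2 = np.array([np.cos(hi), np.sin(hi)]) @ basis
    S = np.stack([v1, v2], axis=1)
    S = S * np.where(S.sum(axis=0) < 0, -1.0, 1.0)  # OD vectors are nonnegative-ish
    S = S / np.linalg.norm(S, axis=0)
    return StainMatrix(_order_hematoxylin_first(S))


def deconvolve(od: np.ndarray, stains: StainMatrix) -> tuple:
    """Least-squares per-pixel stain concentrations (H, E), clipped at 0."""
    S = stains.S
    if np.linalg.matrix_rank(S) < 2:
        raise np.linalg.LinAlgError("singular stain matrix")
    pinv = np.linalg.pinv(S)  # 2 x 3
    flat = np.asarray(od, dtype=np.float64).reshape(-1, 3)
    conc = np.clip(flat @ pinv.T, 0.0, None)
    shape = np.asarray(od).shape[:-1]
    return conc[:, 0].reshape(shape), conc[:, 1].reshape(shape)


def informativeness(rgb: np.ndarray, fallback_stains: StainMatrix | None = None) -> float:
    """Tile informativeness: mean(H) * mean(E) over tissue pixels.

    Returns 0 for tiles with less than :data:`MIN_TISSUE_FRACTION` tissue.
    Stains are estimated per tile where possible, falling back to
    ``fallback_stains`` (default: reference H&E vectors).
    """
    if fallback_stains is None:
        fallback_stains = StainMatrix(DEFAULT_STAIN_VECTORS)
    mask = tissue_mask_for_stains(rgb)
    if mask.mean() < MIN_TISSUE_FRACTION:
        return 0.0
    od = rgb_to_od(rgb)
    try:
        stains = estimate_stain_matrix(od, mask)
    except StainEstimationError:
        stains = fallback_stains
    h, e = deconvolve(od, stains)
    return float(h[mask].mean() * e[mask].mean())


class MacenkoStainEstimator:
    """sklearn-style estimator for masked Macenko stain deconvolution.

    ``fit(rgb)`` estimates the stain matrix from one RGB tile; ``transform``
    returns an ``(H, E)`` concentration stack.  After ``fit`` the matrix is
    available as ``stain_matrix_``; ``fallback_used_`` records whether the
    per-tile estimate failed and the fallback vectors were used.
    """

    def __init__(self, angle_percentiles=(1.0, 99.0), min_pixels=100, fallback=None):
        self.angle_percentiles = angle_percentiles
        self.min_pixels = min_pixels
        self.fallback = fallback

    def get_params(self, deep=True):
        return {
            "angle_percentiles": self.angle_percentiles,
            "min_pixels": self.min_pixels,
            "fallback": self.fallback,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, rgb, y=None):
        mask = tissue_mask_for_stains(rgb)
        od = rgb_to_od(rgb)
        try:
            self.stain_matrix_ = estimate_stain_matrix(
                od, mask, self.angle_percentiles, self.min_pixels
            )
            self.fallback_used_ = False
        except StainEstimationError:
            fb = self.fallback if self.fallback is not None else StainMatrix(DEFAULT_STAIN_VECTORS)
            self.stain_matrix_ = fb
            self.fallback_used_ = True
        return self

    def transform(self, rgb):
        h, e = deconvolve(rgb_to_od(rgb), self.stain_matrix_)
        return np.stack([h, e], axis=-1)

    def fit_transform(self, rgb, y=None):
        return self.fit(rgb).transform(rgb)
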