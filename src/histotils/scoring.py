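"""TIL score variants, ROI saliency, slide aggregation, and calibration.

Three computational stromal-TILs score variants are supported, mirroring the
components of the visual stromal TILs score:

* ``nTSa`` - number of TILs per stromal area (cells/mm^2);
* ``nTnS`` - number of TILs / number of cells in the stromal compartment;
* ``nTnA`` - number of TILs / number of cells anywhere.

TILs are lymphocyte and plasma-cell instances; the stromal compartment is the
stroma plus TILs-dense region classes; membership is decided by the instance
centroid's region code; debris instances are excluded from all cell counts.

Slide scores aggregate per-ROI counts either globally (pool counts, then
score) or by saliency-weighted averaging, where each ROI's weight is the
fraction of its pixels occupied by peritumoral stroma - stroma within 32
microns of the epithelial tumor boundary, measured with a Euclidean distance
transform.

Calibration maps computational scores onto the visual-score scale: both score
lists are z-scored, slides whose z-disagreement exceeds 1.96 standard
deviations are flagged as outliers, and a no-intercept linear regression on
the inliers gives the scaling factor applied to every slide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .taxonomy import ClassTaxonomy, build_default_taxonomy

logger = logging.getLogger(__name__)

VARIANTS = ("nTSa", "nTnS", "nTnA")
AGGREGATIONS = ("global", "saliency_weighted")

#: peritumoral stroma distance (microns) for the saliency score
SALIENCY_DISTANCE_MICRONS = 32.0
#: survival-stratification thresholds (exposed constants; survival analysis
#: itself is out of scope): 10% for stromal scores, 3% for nTnA
STROMAL_SCORE_THRESHOLD = 0.10
NTNA_SCORE_THRESHOLD = 0.03


@dataclass
class RoiCounts:
    n_til_stroma: int
    n_cells_stroma: int
    n_cells_total: int
    stromal_area_mm2: float
    saliency: float = 0.0

    def __post_init__(self):
        if not (self.n_til_stroma <= self.n_cells_stroma <= self.n_cells_total):
            raise ValueError("count ordering violated: TILs <= stromal <= total")
        if self.stromal_area_mm2 < 0:
            raise ValueError("stromal area must be nonnegative")


@dataclass
class CalibrationResult:
    scale: float
    inlier_mask: np.ndarray
    calibrated: np.ndarray
    z_disagreement: np.ndarray


def saliency(region_map: np.ndarray, mpp: float,
             dist_microns: float = SALIENCY_DISTANCE_MICRONS,
             taxonomy: ClassTaxonomy | None = None) -> float:
    """Fraction of map pixels that are stroma within ``dist_microns`` of tumor.

    Tumor = epithelium-superclass region pixels.  Distance is Euclidean, in
    microns (pixels x mpp).  Returns 0 when the map has no tumor pixels.
    """
    tax = taxonomy or build_default_taxonomy()
    tumor = np.isin(region_map, tax.region_codes_in_group("epithelium"))
    stroma = np.isin(region_map, tax.region_codes_in_group("stroma"))
    if not tumor.any() or not stroma.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~tumor) * mpp
    peritumoral = stroma & (dist > 0) & (dist <= dist_microns)
    return float(peritumoral.sum() / region_map.size)


def roi_counts(prediction, mpp: float | None = None,
               taxonomy: ClassTaxonomy | None = None,
               dist_microns: float = SALIENCY_DISTANCE_MICRONS) -> RoiCounts:
    """Count TILs and cells from one panoptic prediction.

    ``prediction`` needs ``instances`` (with ``class_code`` and
    ``region_code``) and a ``region_map``; region membership of an instance
    is its centroid's region code.
    """
    tax = taxonomy or build_default_taxonomy()
    mpp = mpp if mpp is not None else prediction.mpp
    stromal_codes = set(tax.region_codes_in_group("stroma"))
    til_codes = set(tax.nucleus_codes_in_group("TILs"))
    debris = tax.nucleus_code("debris")

    n_til_stroma = n_cells_stroma = n_cells_total = 0
    for inst in prediction.instances:
        if inst.class_code == debris:
            continue
        n_cells_total += 1
        if inst.region_code in stromal_codes:
            n_cells_stroma += 1
            if inst.class_code in til_codes:
                n_til_stroma += 1
    region_map = prediction.region_map
    stromal_px = int(np.isin(region_map, list(stromal_codes)).sum())
    area = stromal_px * (mpp ** 2) * 1e-6
    sal = saliency(region_map, mpp, dist_microns, tax)
    return RoiCounts(n_til_stroma, n_cells_stroma, n_cells_total, area, sal)


def score_variants(counts: RoiCounts) -> dict:
    """The three score variants; zero denominators give NaN, never 0."""
    def ratio(num, den):
        return float(num) / float(den) if den > 0 else float("nan")

    return {
        "nTSa": ratio(counts.n_til_stroma, counts.stromal_area_mm2),
        "nTnS": ratio(counts.n_til_stroma, counts.n_cells_stroma),
        "nTnA": ratio(counts.n_til_stroma, counts.n_cells_total),
    }


def pool_counts(count_list) -> RoiCounts:
    return RoiCounts(
        n_til_stroma=sum(c.n_til_stroma for c in count_list),
        n_cells_stroma=sum(c.n_cells_stroma for c in count_list),
        n_cells_total=sum(c.n_cells_total for c in count_list),
        stromal_area_mm2=sum(c.stromal_area_mm2 for c in count_list),
        saliency=float(np.mean([c.saliency for c in count_list])),
    )


def aggregate(count_list, mode: str = "global") -> dict:
    """Slide-level scores from per-ROI counts.

    ``global`` pools counts then scores once; ``saliency_weighted`` averages
    per-ROI scores with saliency weights, skipping NaN scores, and falls back
    to the unweighted mean (with a warning) when all weights are zero.
    """
    if not count_list:
        raise ValueError("need at least one ROI")
    if mode == "global":
        return score_variants(pool_counts(count_list))
    if mode != "saliency_weighted":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    out = {}
    per_roi = [score_variants(c) for c in count_list]
    weights = np.array([c.saliency for c in count_list], dtype=float)
    for variant in VARIANTS:
        s = np.array([r[variant] for r in per_roi])
        ok = ~np.isnan(s)
        if not ok.any():
            out[variant] = float("nan")
            continue
        w = weights[ok]
        if w.sum() == 0:
            logger.warning(
                "all saliency weights are zero for %s; using unweighted mean",
                variant,
            )
            out[variant] = float(s[ok].mean())
        else:
            out[variant] = float((w * s[ok]).sum() / w.sum())
    return out


def slide_score_table(count_list, slide_id: str = "slide",
                      calibration_scales: dict | None = None) -> pd.DataFrame:
    """One-row tidy table of all variant x aggregation scores for a slide."""
    row = {"slide_id": slide_id, "n_rois": len(count_list)}
    sal = [c.saliency for c in count_list]
    row["saliency_mean"] = float(np.mean(sal))
    row["saliency_max"] = float(np.max(sal))
    for mode in AGGREGATIONS:
        scores = aggregate(count_list, mode)
        for variant, value in scores.items():
            row[f"{variant}_{mode}"] = value
            if calibration_scales and variant in calibration_scales:
                row[f"{variant}_{mode}_calibrated"] = (
                    calibration_scales[variant] * value
                )
    return pd.DataFrame([row])


def calibrate(computational, visual, z_threshold: float = 1.96) -> CalibrationResult:
    """No-intercept linear calibration with 1.96-SD outlier exclusion.

    Outliers are slides where the difference of z-scored visual and
    computational scores, standardized by its own standard deviation, exceeds
    1.96 in magnitude.  They are excluded from fitting the scale only;
    calibrated scores are returned for every slide.
    """
    comp = np.asarray(computational, dtype=np.float64)
    vis = np.asarray(visual, dtype=np.float64)
    if comp.shape != vis.shape or comp.ndim != 1:
        raise ValueError("computational and visual scores must be paired 1-D")
    if len(comp) < 3:
        raise ValueError("need at least 3 score pairs")
    if comp.std(ddof=1) == 0 or vis.std(ddof=1) == 0:
        raise ValueError("zero variance in scores; cannot calibrate")
    zc = (comp - comp.mean()) / comp.std(ddof=1)
    zv = (vis - vis.mean()) / vis.std(ddof=1)
    d = zv - zc
    sd = d.std(ddof=1)
    z_dis = d / sd if sd > 0 else np.zeros_like(d)
    inliers = np.abs(z_dis) <= z_threshold
    if not inliers.any():
        raise ValueError("all slides flagged as outliers; cannot calibrate")
    k = float(
        (vis[inliers] * comp[inliers]).sum() / (comp[inliers] ** 2).sum()
    )
    return CalibrationResult(scale=k, inlier_mask=inliers,
                             calibrated=k * comp, z_disagreement=z_dis)


def calibration_report(computational, visual, slide_ids=None) -> tuple:
    """(per-slide DataFrame, fitted scale) in the interchange layout."""
    res = calibrate(computational, visual)
    n = len(res.calibrated)
    ids = list(slide_ids) if slide_ids is not None else [f"slide_{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "slide_id": ids,
            "computational": np.asarray(computational, dtype=float),
            "visual": np.asarray(visual, dtype=float),
            "z_disagreement": res.z_disagreement,
            "inlier": res.inlier_mask,
            "calibrated": res.calibrated,
        }
    )
    return df, res.scale


class ScoreCalibrator:
    """sklearn-style estimator for visual-scale calibration.

    ``fit(computational, visual)`` fits the no-intercept scale on inliers;
    ``transform(computational)`` applies it.  Fitted attributes: ``scale_``,
    ``inlier_mask_``, ``z_disagreement_``.
    """

    def __init__(self, z_threshold: float = 1.96):
        self.z_threshold = z_threshold

    def get_params(self, deep=True):
        return {"z_threshold": self.z_threshold}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, computational, visual):
        res = calibrate(computational, visual, self.z_threshold)
        self.scale_ = res.scale
        self.inlier_mask_ = res.inlier_mask
        self.z_disagreement_ = res.z_disagreement
        return self

    def transform(self, computational):
        return self.scale_ * np.asarray(computational, dtype=np.float64)

    def fit_transform(self, computational, visual):
        return self.fit(computational, visual).transform(computational)
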