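"""Whole-slide orchestration: tissue detection, tiling, ROI selection, ensembling.

A slide is scored in four steps: detect tissue on a low-resolution thumbnail
(~8 micron/px) and drop marker-ink artifacts; tile the slide on a
non-overlapping grid and score each tile's informativeness at 2 micron/px
(product of mean hematoxylin and eosin, which favors peritumoral stroma);
analyze the top-k (default 300) most informative tiles at full resolution,
assigning tiles to the cross-validation ensemble members cyclically (tile
rank mod 5); extract panoptic predictions per ROI.  Fixing the number of
analyzed regions keeps run time near-constant regardless of slide size.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_closing
from skimage.color import rgb2hsv
from skimage.morphology import disk

from . import net as _net
from .stain import StainMatrix, DEFAULT_STAIN_VECTORS, informativeness

logger = logging.getLogger(__name__)

THUMBNAIL_MPP = 8.0
TISSUE_SATURATION_MIN = 0.05
TISSUE_VALUE_MAX = 0.95
INK_HUE_PURITY = 0.8
INK_SATURATION_MIN = 0.6


@dataclass
class TileRecord:
    tile_id: str
    grid_row: int
    grid_col: int
    origin_xy: tuple          # level-0 pixels
    mpp: float                # resolution the score was computed at
    informativeness: float
    selected: bool = False
    model_index: int | None = None
    saliency: float | None = None

    def __post_init__(self):
        if self.informativeness < 0:
            raise ValueError("informativeness must be nonnegative")


class SlideHandle:
    """Uniform access to a slide: synthetic tile directory or image file.

    Exposes level-0 dimensions, native micron-per-pixel, and
    ``read_region(x, y, out_px, out_mpp)`` with white padding outside the
    slide.  Resolutions coarser than native are produced by integer-factor
    block averaging.
    """

    def __init__(self, array: np.ndarray, mpp: float, slide_id: str = "slide"):
        if mpp <= 0:
            raise ValueError("mpp must be positive")
        self.array = np.asarray(array)
        self.mpp = float(mpp)
        self.slide_id = slide_id

    @classmethod
    def from_tile_dir(cls, path) -> "SlideHandle":
        """Stitch a ``slide_<id>/tile_<row>_<col>.png`` directory."""
        path = Path(path)
        meta = json.loads((path / "slide.json").read_text())
        rows, cols = meta["grid"]
        tp = meta["tile_px"]
        full = np.full((rows * tp, cols * tp, 3), 255, dtype=np.uint8)
        pat = re.compile(r"tile_(\d+)_(\d+)\.png$")
        for f in sorted(path.glob("tile_*_*.png")):
            if ".region." in f.name:
                continue
            m = pat.match(f.name)
            if not m:
                continue
            r, c = int(m.group(1)), int(m.group(2))
            full[r * tp : (r + 1) * tp, c * tp : (c + 1) * tp] = np.asarray(
                Image.open(f).convert("RGB")
            )
        return cls(full, meta["mpp"], slide_id=meta.get("slide_id", path.name))

    @classmethod
    def from_image_file(cls, path, mpp: float) -> "SlideHandle":
        import tifffile

        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
        return cls(arr, mpp, slide_id=path.stem)

    @property
    def dimensions(self) -> tuple:
        h, w = self.array.shape[:2]
        return w, h  # (width, height) in level-0 pixels

    def read_region(self, x: int, y: int, out_px: int, out_mpp: float) -> np.ndarray:
        """RGB region of ``out_px`` square at ``out_mpp``, origin level-0 (x, y)."""
        factor = out_mpp / self.mpp
        if factor < 1 - 1e-9:
            raise ValueError(
                f"requested {out_mpp} MPP finer than native {self.mpp} MPP"
            )
        f = int(round(factor))
        span = out_px * f
        h, w = self.array.shape[:2]
        out = np.full((span, span, 3), 255, dtype=np.float64)
        x0, y0 = max(0, x), max(0, y)
        x1, y1 = min(w, x + span), min(h, y + span)
        if x1 > x0 and y1 > y0:
            out[y0 - y : y1 - y, x0 - x : x1 - x] = self.array[y0:y1, x0:x1]
        if f == 1:
            return out.astype(np.uint8)
        blocked = out.reshape(out_px, f, out_px, f, 3).mean(axis=(1, 3))
        return np.clip(np.round(blocked), 0, 255).astype(np.uint8)

    def thumbnail(self, mpp: float = THUMBNAIL_MPP) -> np.ndarray:
        w, h = self.dimensions
        f = max(1, int(round(mpp / self.mpp)))
        out_px = int(np.ceil(max(h, w) / f))
        return self.read_region(0, 0, out_px, self.mpp * f)[
            : int(np.ceil(h / f)), : int(np.ceil(w / f))
        ]


# --- tissue detection --------------------------------------------------------

def detect_tissue(thumbnail_rgb: np.ndarray) -> np.ndarray:
    """Tissue pixels on a thumbnail: saturated, non-bright, morphologically closed."""
    hsv = rgb2hsv(np.asarray(thumbnail_rgb, dtype=np.uint8))
    mask = (hsv[..., 1] > TISSUE_SATURATION_MIN) & (hsv[..., 2] < TISSUE_VALUE_MAX)
    # pad with edge values so the closing does not erode the image border
    padded = np.pad(mask, 2, mode="edge")
    return binary_closing(padded, structure=disk(2))[2:-2, 2:-2]


def exclude_artifacts(thumbnail_rgb: np.ndarray, tissue_mask: np.ndarray) -> np.ndarray:
    """Remove saturated single-hue connected components (marker/ink).

    A component is ink when its hue histogram concentrates > 80% of pixels in
    one of 12 bins and its mean saturation is high; H&E tissue is neither as
    monochrome nor as saturated.  Warns if more than half the mask vanishes.
    """
    from scipy import ndimage

    thumbnail_rgb = np.asarray(thumbnail_rgb, dtype=np.uint8)
    if thumbnail_rgb.shape[:2] != tissue_mask.shape:
        raise ValueError("thumbnail and mask extents differ")
    hsv = rgb2hsv(thumbnail_rgb)
    labels, n = ndimage.label(tissue_mask)
    cleaned = tissue_mask.copy()
    for comp in range(1, n + 1):
        sel = labels == comp
        hue = hsv[..., 0][sel]
        sat = hsv[..., 1][sel]
        hist, _ = np.histogram(hue, bins=12, range=(0.0, 1.0))
        purity = hist.max() / max(1, hist.sum())
        if purity > INK_HUE_PURITY and sat.mean() > INK_SATURATION_MIN:
            cleaned[sel] = False
    removed = tissue_mask.sum() - cleaned.sum()
    if tissue_mask.sum() > 0 and removed > 0.5 * tissue_mask.sum():
        logger.warning(
            "artifact exclusion removed %.0f%% of the tissue mask",
            100.0 * removed / tissue_mask.sum(),
        )
    return cleaned


# --- tiling and ranking ------------------------------------------------------

def tile_and_rank(slide: SlideHandle, tile_microns: float = 512.0,
                  mpp: float = 2.0,
                  fallback_stains: StainMatrix | None = None) -> list:
    """Score every grid tile's informativeness at low resolution and rank.

    The grid is non-overlapping over the whole slide; tiles without any
    cleaned-tissue pixel score 0 without being read at scoring resolution.
    Records are sorted by (score desc, row asc, col asc).
    """
    if fallback_stains is None:
        fallback_stains = StainMatrix(DEFAULT_STAIN_VECTORS)
    thumb = slide.thumbnail(THUMBNAIL_MPP)
    cleaned = exclude_artifacts(thumb, detect_tissue(thumb))
    if not cleaned.any():
        logger.warning("no tissue detected on slide %s", slide.slide_id)
        return []
    tile_px0 = int(round(tile_microns / slide.mpp))     # level-0 pixels
    tile_px_score = int(round(tile_microns / mpp))      # scoring resolution
    thumb_factor = THUMBNAIL_MPP / slide.mpp
    w, h = slide.dimensions
    n_rows = int(np.ceil(h / tile_px0))
    n_cols = int(np.ceil(w / tile_px0))
    records = []
    for r in range(n_rows):
        for c in range(n_cols):
            x0, y0 = c * tile_px0, r * tile_px0
            ty0 = int(y0 / thumb_factor)
            ty1 = max(ty0 + 1, int(np.ceil((y0 + tile_px0) / thumb_factor)))
            tx0 = int(x0 / thumb_factor)
            tx1 = max(tx0 + 1, int(np.ceil((x0 + tile_px0) / thumb_factor)))
            has_tissue = cleaned[ty0:ty1, tx0:tx1].any()
            if has_tissue:
                rgb = slide.read_region(x0, y0, tile_px_score, mpp)
                score = informativeness(rgb, fallback_stains)
            else:
                score = 0.0
            records.append(
                TileRecord(
                    tile_id=f"tile_{r}_{c}", grid_row=r, grid_col=c,
                    origin_xy=(x0, y0), mpp=mpp, informativeness=score,
                )
            )
    records.sort(key=lambda t: (-t.informativeness, t.grid_row, t.grid_col))
    return records


def select_rois(records: list, k: int = 300) -> list:
    """Mark the top-``min(k, len)`` ranked records as selected ROIs."""
    selected = records[: max(0, k)]
    for rec in records:
        rec.selected = False
        rec.model_index = None
    for rec in selected:
        rec.selected = True
    return selected


def assign_models_cyclic(selected: list, n_models: int = 5) -> list:
    """model_index = selection rank mod n_models (cyclic ensembling)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    for rank, rec in enumerate(selected):
        rec.model_index = rank % n_models
    return selected


# --- inference ---------------------------------------------------------------

def infer_slide(slide: SlideHandle, models: list, selected: list,
                mode: str = "cyclic", min_size_px: int = 10) -> list:
    """Panoptic predictions for every selected ROI.

    Each ROI is read at the network's two resolutions centered on the tile.
    ``cyclic`` mode runs the assigned ensemble member; ``all_models``
    averages all members' region and constrained-nucleus probability maps
    before instance extraction.
    """
    if mode not in ("cyclic", "all_models"):
        raise ValueError(f"unknown inference mode {mode!r}")
    nets = [m.net_ if hasattr(m, "net_") else m for m in models]
    cfg = nets[0].config
    roi_um = cfg.roi_input_px * cfg.roi_mpp
    hpf_um = cfg.hpf_input_px * cfg.hpf_mpp
    predictions = []
    for rec in selected:
        if rec.model_index is None and mode == "cyclic":
            raise ValueError(f"tile {rec.tile_id} has no assigned model")
        # tile center in level-0 px
        tile_px0 = int(round(hpf_um / slide.mpp))  # ROI == tile footprint at HPF
        cx = rec.origin_xy[0] + tile_px0 // 2
        cy = rec.origin_xy[1] + tile_px0 // 2
        x10 = cx - int(round(roi_um / 2 / slide.mpp))
        y10 = cy - int(round(roi_um / 2 / slide.mpp))
        x20 = cx - int(round(hpf_um / 2 / slide.mpp))
        y20 = cy - int(round(hpf_um / 2 / slide.mpp))
        try:
            rgb10 = slide.read_region(x10, y10, cfg.roi_input_px, cfg.roi_mpp)
            rgb20 = slide.read_region(x20, y20, cfg.hpf_input_px, cfg.hpf_mpp)
        except ValueError as exc:
            raise ValueError(f"cannot read ROI {rec.tile_id}: {exc}") from exc
        r10 = np.moveaxis(rgb10, -1, 0)[None]
        r20 = np.moveaxis(rgb20, -1, 0)[None]
        if mode == "cyclic":
            out = nets[rec.model_index].forward(r10, r20)
            region_probs = out.hpf_region_probs.data[0]
            nucleus_probs = out.nucleus_probs_constrained.data[0]
        else:
            region_stack, nucleus_stack = [], []
            for net in nets:
                out = net.forward(r10, r20)
                region_stack.append(out.hpf_region_probs.data[0])
                nucleus_stack.append(out.nucleus_probs_constrained.data[0])
            region_probs = np.mean(region_stack, axis=0)
            nucleus_probs = np.mean(nucleus_stack, axis=0)
        instances = _net.extract_instances(
            nucleus_probs, min_size_px=min_size_px, region_probs=region_probs
        )
        predictions.append(
            _net.PanopticPrediction(
                region_probs=region_probs, nucleus_probs=nucleus_probs,
                instances=instances, mpp=cfg.hpf_mpp,
                origin_xy=(x20, y20),
            )
        )
    return predictions
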