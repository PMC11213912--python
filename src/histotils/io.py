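"""File formats: mask PNGs, nucleus interchange CSV, checkpoints, run config.

Masks are single-channel 8-bit PNGs holding integer taxonomy codes (not RGB),
so round trips are bit-exact.  Per-nucleus results interchange as CSV with
columns (slide_id, roi_id, instance_id, x, y, class, p_class1..p_class6),
0-based pixel coordinates at 0.5 micron/px.  Network weights serialize to a
single ``.npz`` checkpoint with the architecture config embedded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .net import NetworkConfig, PanopticNet
from .taxonomy import ClassTaxonomy, build_default_taxonomy


class FormatError(ValueError):
    pass


# --- masks -------------------------------------------------------------------

def write_mask_png(path, mask: np.ndarray, palette: dict | None = None):
    """Write an integer-code mask losslessly; optional palette sidecar JSON."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise FormatError("mask must be single-channel")
    if mask.min() < 0 or mask.max() > 255 or not np.issubdtype(mask.dtype, np.integer):
        raise FormatError("mask must hold integer codes in [0, 255]")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    if palette is not None:
        Path(str(path) + ".palette.json").write_text(
            json.dumps({str(k): list(v) for k, v in palette.items()})
        )


def read_mask_png(path, taxonomy: ClassTaxonomy | None = None,
                  kind: str = "region") -> np.ndarray:
    """Read a code mask, validating codes against the taxonomy."""
    img = Image.open(path)
    if img.mode == "P":
        img = img.convert("L")
    if img.mode != "L":
        raise FormatError(f"mask {path} must be single-channel 8-bit, got {img.mode}")
    mask = np.asarray(img).astype(np.int32)
    if taxonomy is not None:
        n = taxonomy.n_regions if kind == "region" else taxonomy.n_nuclei
        bad = np.setdiff1d(np.unique(mask), np.arange(n + 1))
        if bad.size:
            raise FormatError(
                f"mask {path} holds codes outside the taxonomy: {bad.tolist()}"
            )
    return mask


DEFAULT_PALETTE = {
    0: (255, 255, 255),
    1: (200, 0, 0),
    2: (255, 128, 0),
    3: (0, 160, 0),
    4: (0, 200, 200),
    5: (128, 0, 128),
    6: (220, 220, 220),
}


# --- nucleus interchange CSV ---------------------------------------------------

_NUCLEUS_COLUMNS = ["slide_id", "roi_id", "instance_id", "x", "y", "class"] + [
    f"p_class{i}" for i in range(1, 7)
]


def nuclei_to_frame(predictions, slide_id: str = "slide") -> pd.DataFrame:
    """Flatten per-ROI predictions into the interchange layout."""
    rows = []
    for i, pred in enumerate(predictions):
        for inst in pred.instances:
            row = {
                "slide_id": slide_id,
                "roi_id": f"roi_{i}",
                "instance_id": inst.instance_id,
                "x": inst.centroid_xy[0],
                "y": inst.centroid_xy[1],
                "class": inst.class_code,
            }
            for k, p in enumerate(inst.class_probs, start=1):
                row[f"p_class{k}"] = float(p)
            rows.append(row)
    return pd.DataFrame(rows, columns=_NUCLEUS_COLUMNS)


def write_nuclei_csv(path, predictions, slide_id: str = "slide"):
    nuclei_to_frame(predictions, slide_id).to_csv(path, index=False)


def read_nuclei_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _NUCLEUS_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"nucleus CSV {path} missing columns {missing}")
    return df


# --- annotated-ROI loading -----------------------------------------------------

def load_roi_sample(rgb_png, region_png, nucleus_instance_png=None,
                    nucleus_classes_csv=None, annotated_center_px: int = 256,
                    taxonomy: ClassTaxonomy | None = None,
                    slide_id: str = "roi", hospital_id: str = "hospital_0"):
    """Load one annotated ROI in the standard layout into a RoiSample.

    The region mask covers the full field; nucleus annotations (instance mask
    + class table) cover only the central ``annotated_center_px`` square, so
    the returned sample's ``nucleus_annotated_mask_20x`` marks that window.
    """
    from .synthetic import RoiSample

    tax = taxonomy or build_default_taxonomy()
    rgb = np.asarray(Image.open(rgb_png).convert("RGB"))
    region = read_mask_png(region_png, tax, kind="region")
    if region.shape != rgb.shape[:2]:
        raise FormatError("region mask and image extents differ")
    n = rgb.shape[0]
    inst = np.zeros((n, n), dtype=np.int32)
    classes: dict = {}
    if nucleus_instance_png is not None:
        inst = np.asarray(Image.open(nucleus_instance_png)).astype(np.int32)
        table = pd.read_csv(nucleus_classes_csv)
        classes = dict(zip(table["instance_id"].astype(int),
                           table["class"].astype(int)))
        missing = np.setdiff1d(np.unique(inst[inst > 0]), list(classes))
        if missing.size:
            raise FormatError(f"instances without classes: {missing.tolist()}")
    annotated = np.zeros((n, n), dtype=bool)
    c0 = (n - annotated_center_px) // 2
    annotated[c0 : c0 + annotated_center_px, c0 : c0 + annotated_center_px] = True

    from .synthetic import _box_downsample2

    return RoiSample(
        rgb_20x=rgb,
        rgb_10x=_box_downsample2(rgb),
        region_mask_20x=region,
        region_mask_10x=region[::2, ::2].copy(),
        nucleus_instance_map_20x=inst,
        nucleus_class_per_instance=classes,
        nucleus_annotated_mask_20x=annotated,
        slide_id=slide_id,
        hospital_id=hospital_id,
    )


# --- checkpoints ---------------------------------------------------------------

def save_checkpoint(path, net: PanopticNet):
    cfg = asdict(net.config)
    arrays = {f"param_{i}": p.data for i, p in enumerate(net.params)}
    arrays["kernel"] = net.kernel.K
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path) -> PanopticNet:
    from .taxonomy import CompatibilityKernel

    data = np.load(path, allow_pickle=False)
    cfg = NetworkConfig(**json.loads(str(data["config"])))
    net = PanopticNet(cfg, kernel=CompatibilityKernel(data["kernel"]))
    for i, p in enumerate(net.params):
        arr = data[f"param_{i}"]
        if arr.shape != p.data.shape:
            raise FormatError(f"checkpoint parameter {i} shape mismatch")
        p.data = arr.astype(np.float64)
    return net


# --- run configuration ---------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline constants and paths for one scoring run."""

    input_path: str = ""
    weights: list = field(default_factory=list)
    output_dir: str = "out"
    taxonomy_file: str | None = None
    scoring_mpp: float = 2.0
    roi_mpp: float = 1.0
    hpf_mpp: float = 0.5
    tile_microns: float = 512.0
    top_k: int = 300
    saliency_distance_microns: float = 32.0
    min_instance_px: int = 10
    n_models: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("scoring_mpp", "roi_mpp", "hpf_mpp", "tile_microns",
                     "saliency_distance_microns"):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        if self.top_k < 1:
            raise FormatError("top_k must be >= 1")


def save_run_config(path, config: RunConfig):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))
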