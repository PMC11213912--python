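"""Synthetic H&E-like ROIs, slides and score cohorts with exact ground truth.

The generator emulates the geometry of an annotated breast-cancer ROI: a
region mask over the six tissue classes at 0.5 micron/pixel (20x objective),
non-overlapping elliptical nuclei placed per region with classes sampled in
accordance with the default compatibility kernel, and RGB rendered from the
latent stain-concentration maps by base-10 Beer-Lambert color formation
(``rgb = 255 * 10**(-S @ c)``), so that Macenko deconvolution of the render
recovers the generating concentrations in the same units.

Every output is a deterministic function of the seed.  Real H&E features the
generator does NOT model: texture within nuclei and stroma, overlapping or
non-elliptical nuclei, staining batch effects, and out-of-focus regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .stain import DEFAULT_STAIN_VECTORS
from .taxonomy import ClassTaxonomy, build_default_kernel, build_default_taxonomy

# per-class multipliers on the mean nucleus radius (lymphocytes are small
# and chromatin-dense; carcinoma nuclei are large)
_RADIUS_SCALE = {
    "cancer": 1.4,
    "normal_epithelium": 1.2,
    "fibroblast": 1.0,
    "lymphocyte": 0.7,
    "plasma_cell": 0.8,
    "debris": 0.6,
}

# per-class hematoxylin concentration inside the nucleus
_NUCLEUS_HEMATOXYLIN = {
    "cancer": 0.85,
    "normal_epithelium": 0.80,
    "fibroblast": 0.70,
    "lymphocyte": 1.20,
    "plasma_cell": 1.05,
    "debris": 0.45,
}

# background eosin concentration per region (cytoplasm / collagen)
_REGION_EOSIN = {
    "cancer": 0.35,
    "normal_epithelium": 0.35,
    "stroma": 0.60,
    "tils_dense": 0.50,
    "necrosis_debris": 0.45,
    "empty": 0.0,
}

# nucleus class sampling per region: (classes, probabilities); stromal
# compartments are handled separately through til_fraction
_REGION_CLASS_MIX = {
    "cancer": (("cancer", "lymphocyte", "plasma_cell"), (0.90, 0.07, 0.03)),
    "normal_epithelium": (("normal_epithelium", "lymphocyte", "plasma_cell"), (0.90, 0.07, 0.03)),
    "necrosis_debris": (("debris", "lymphocyte", "plasma_cell"), (0.80, 0.15, 0.05)),
}

# nuclei per mm^2 by region (stromal compartments use stromal_cellularity)
_REGION_CELLULARITY = {
    "cancer": 5000.0,
    "normal_epithelium": 4000.0,
    "necrosis_debris": 1500.0,
    "empty": 0.0,
}


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one generated ROI."""

    roi_size_px: int = 1024          # at 0.5 MPP (20x)
    mpp: float = 0.5
    region_layout: str = "half_plane"  # {half_plane, blobs, rings}
    til_fraction: float = 0.3
    stromal_cellularity: float = 3000.0  # nuclei per mm^2 of stroma
    nucleus_radius_px: tuple = (5.0, 1.0)  # mean, sd at 0.5 MPP
    stain_vectors: np.ndarray = field(
        default_factory=lambda: DEFAULT_STAIN_VECTORS.copy()
    )
    background_rgb: tuple = (255, 255, 255)
    tumor_coverage: float = 0.5      # fraction of the ROI that is epithelial
    seed: int = 0

    def __post_init__(self):
        if self.roi_size_px <= 0:
            raise ValueError("roi_size_px must be positive")
        if not 0.0 <= self.til_fraction <= 1.0:
            raise ValueError("til_fraction must be in [0, 1]")
        S = np.asarray(self.stain_vectors, dtype=np.float64)
        if not np.allclose(np.linalg.norm(S, axis=0), 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit-norm columns")
        if np.linalg.matrix_rank(S) < 2:
            raise ValueError("stain vectors must be linearly independent")
        object.__setattr__(self, "stain_vectors", S)


@dataclass
class RoiSample:
    """Paired 10x/20x crops with region masks and nucleus instance truth."""

    rgb_20x: np.ndarray          # H x W x 3 uint8 at 0.5 MPP
    rgb_10x: np.ndarray          # (H/2) x (W/2) x 3 uint8 at 1.0 MPP
    region_mask_20x: np.ndarray  # int, taxonomy codes
    region_mask_10x: np.ndarray
    nucleus_instance_map_20x: np.ndarray  # int, 0 = background
    nucleus_class_per_instance: dict      # instance id -> nucleus code
    nucleus_annotated_mask_20x: np.ndarray  # bool; False = ignore in loss
    slide_id: str = "synthetic"
    hospital_id: str = "hospital_0"
    origin_xy: tuple = (0, 0)
    mpp: float = 0.5
    conc_h: np.ndarray | None = None  # latent hematoxylin map (render truth)
    conc_e: np.ndarray | None = None

    @property
    def nucleus_class_mask_20x(self) -> np.ndarray:
        """Per-pixel nucleus class codes (0 = background)."""
        inst = self.nucleus_instance_map_20x
        out = np.zeros_like(inst)
        for iid, code in self.nucleus_class_per_instance.items():
            out[inst == iid] = code
        return out

    def truth_table(self) -> pd.DataFrame:
        """Per-nucleus truth (centroid, class, region at centroid)."""
        rows = []
        inst = self.nucleus_instance_map_20x
        for iid, code in sorted(self.nucleus_class_per_instance.items()):
            ys, xs = np.nonzero(inst == iid)
            cy, cx = float(ys.mean()), float(xs.mean())
            rows.append(
                {
                    "instance_id": iid,
                    "x": cx,
                    "y": cy,
                    "class": code,
                    "region": int(self.region_mask_20x[int(round(cy)), int(round(cx))]),
                    "pixel_count": len(ys),
                }
            )
        return pd.DataFrame(
            rows, columns=["instance_id", "x", "y", "class", "region", "pixel_count"]
        )


# --- region layouts ----------------------------------------------------------

def _layout_half_plane(n, tumor_coverage, tax, rng):
    mask = np.full((n, n), tax.region_code("stroma"), dtype=np.int32)
    split = int(round(n * tumor_coverage))
    mask[:, :split] = tax.region_code("cancer")
    return mask


def _layout_blobs(n, tumor_coverage, tax, rng):
    mask = np.full((n, n), tax.region_code("stroma"), dtype=np.int32)
    yy, xx = np.mgrid[0:n, 0:n]
    target = tumor_coverage * n * n
    covered = 0.0
    for _ in range(12):
        if covered >= target:
            break
        cy, cx = rng.uniform(0.2 * n, 0.8 * n, size=2)
        ry = rng.uniform(0.10 * n, 0.25 * n)
        rx = rng.uniform(0.10 * n, 0.25 * n)
        blob = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        mask[blob] = tax.region_code("cancer")
        covered = (mask == tax.region_code("cancer")).sum()
    # a small TILs-dense pocket hugging the tumor border
    cy, cx = rng.uniform(0.3 * n, 0.7 * n, size=2)
    r = 0.08 * n
    pocket = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r) & (
        mask == tax.region_code("stroma")
    )
    mask[pocket] = tax.region_code("tils_dense")
    return mask


def _layout_rings(n, tumor_coverage, tax, rng):
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    mask = np.full((n, n), tax.region_code("empty"), dtype=np.int32)
    r_tumor = np.sqrt(tumor_coverage / np.pi) * n
    mask[r <= 0.48 * n] = tax.region_code("stroma")
    mask[r <= r_tumor] = tax.region_code("cancer")
    return mask


_LAYOUTS = {
    "half_plane": _layout_half_plane,
    "blobs": _layout_blobs,
    "rings": _layout_rings,
}


# --- nucleus placement -------------------------------------------------------

def _place_nuclei(region_mask, params, tax, rng, max_rejections=50, gap_px=2):
    """Dart-throwing placement of non-overlapping elliptical nuclei.

    Returns (instance_map, {id: class_code}).  Classes are sampled per the
    region the centroid falls in, respecting the default kernel by
    construction; stromal-compartment nuclei are TILs with probability
    ``til_fraction`` (70/30 lymphocyte/plasma split) and fibroblasts
    otherwise.
    """
    n = region_mask.shape[0]
    mm2_per_px = (params.mpp ** 2) * 1e-6
    inst = np.zeros_like(region_mask, dtype=np.int32)
    occupied = np.zeros_like(region_mask, dtype=bool)
    classes: dict = {}
    next_id = 1
    mean_r, sd_r = params.nucleus_radius_px

    stromal_codes = {tax.region_code("stroma"), tax.region_code("tils_dense")}

    for region_name in tax.region_classes:
        code = tax.region_code(region_name)
        coords = np.flatnonzero(region_mask == code)
        if coords.size == 0:
            continue
        if code in stromal_codes:
            cellularity = params.stromal_cellularity
        else:
            cellularity = _REGION_CELLULARITY[region_name]
        expected = cellularity * coords.size * mm2_per_px
        count = int(rng.poisson(expected))
        for _ in range(count):
            if code in stromal_codes:
                if rng.random() < params.til_fraction:
                    cname = "lymphocyte" if rng.random() < 0.7 else "plasma_cell"
                else:
                    cname = "fibroblast"
            else:
                names, probs = _REGION_CLASS_MIX[region_name]
                cname = names[rng.choice(len(names), p=np.asarray(probs))]
            r = max(2.0, rng.normal(mean_r * _RADIUS_SCALE[cname], sd_r))
            placed = False
            for _attempt in range(max_rejections):
                flat = coords[rng.integers(coords.size)]
                cy, cx = divmod(int(flat), n)
                rr = int(np.ceil(r + gap_px))
                y0, y1 = max(0, cy - rr), min(n, cy + rr + 1)
                x0, x1 = max(0, cx - rr), min(n, cx + rr + 1)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                guard = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + gap_px) ** 2
                if occupied[y0:y1, x0:x1][guard].any():
                    continue
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
                inst[y0:y1, x0:x1][disk] = next_id
                occupied[y0:y1, x0:x1][guard] = True
                classes[next_id] = tax.nucleus_code(cname)
                next_id += 1
                placed = True
                break
            if not placed:
                continue
    return inst, classes


def _render(region_mask, inst, classes, params, tax):
    """Base-10 Beer-Lambert render from latent concentration maps."""
    n = region_mask.shape[0]
    conc_h = np.zeros((n, n))
    conc_e = np.zeros((n, n))
    for name in tax.region_classes:
        code = tax.region_code(name)
        sel = region_mask == code
        conc_e[sel] = _REGION_EOSIN[name]
        if name != "empty":
            conc_h[sel] = 0.04  # faint cytoplasmic hematoxylin
    for iid, ccode in classes.items():
        cname = tax.nucleus_name(ccode)
        conc_h[inst == iid] = _NUCLEUS_HEMATOXYLIN[cname]
    S = params.stain_vectors
    od = conc_h[..., None] * S[:, 0] + conc_e[..., None] * S[:, 1]
    rgb = np.asarray(params.background_rgb, dtype=np.float64) * np.power(10.0, -od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8), conc_h, conc_e


def _box_downsample2(rgb):
    h, w = rgb.shape[:2]
    r = rgb[: h - h % 2, : w - w % 2].astype(np.float64)
    out = (
        r[0::2, 0::2] + r[1::2, 0::2] + r[0::2, 1::2] + r[1::2, 1::2]
    ) / 4.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def generate_roi(
    params: SynthParams,
    render_rgb: bool = True,
    taxonomy: ClassTaxonomy | None = None,
    slide_id: str = "synthetic",
    hospital_id: str = "hospital_0",
    origin_xy: tuple = (0, 0),
) -> RoiSample:
    """Generate one ROI; deterministic for a fixed ``params.seed``."""
    tax = taxonomy or build_default_taxonomy()
    rng = np.random.default_rng(params.seed)
    n = params.roi_size_px
    region_mask = _LAYOUTS[params.region_layout](n, params.tumor_coverage, tax, rng)
    inst, classes = _place_nuclei(region_mask, params, tax, rng)
    if render_rgb:
        rgb, conc_h, conc_e = _render(region_mask, inst, classes, params, tax)
        rgb_10x = _box_downsample2(rgb)
    else:
        rgb = np.full((n, n, 3), 255, dtype=np.uint8)
        rgb_10x = np.full((n // 2, n // 2, 3), 255, dtype=np.uint8)
        conc_h = conc_e = None
    return RoiSample(
        rgb_20x=rgb,
        rgb_10x=rgb_10x,
        region_mask_20x=region_mask,
        region_mask_10x=region_mask[::2, ::2].copy(),
        nucleus_instance_map_20x=inst,
        nucleus_class_per_instance=classes,
        nucleus_annotated_mask_20x=np.ones((n, n), dtype=bool),
        slide_id=slide_id,
        hospital_id=hospital_id,
        origin_xy=origin_xy,
        mpp=params.mpp,
        conc_h=conc_h,
        conc_e=conc_e,
    )


# --- multi-tile slides -------------------------------------------------------

def _grid_shape(n_tiles: int) -> tuple:
    rows = int(np.sqrt(n_tiles))
    while rows > 1 and n_tiles % rows:
        rows -= 1
    return rows, n_tiles // rows


def generate_slide(
    n_tiles: int,
    params: SynthParams,
    tumor_coverage: float = 0.5,
    background_fraction: float = 0.0,
    out_dir: str | Path | None = None,
    slide_id: str = "slide_0",
    hospital_id: str = "hospital_0",
):
    """Generate a grid of tiles forming one synthetic slide.

    ``background_fraction`` of the tiles are pure background (no tissue, no
    nuclei) to exercise informativeness ranking; ``tumor_coverage`` of the
    remaining tissue tiles use a half-plane tumor/stroma layout, the rest are
    all-stroma.  Returns ``(tiles, truth, meta)``: the list of RoiSamples in
    row-major order, the pooled per-nucleus truth table, and slide metadata.
    When ``out_dir`` is given the standard tile-directory layout is written:
    ``slide_<id>/tile_<row>_<col>.png`` + ``tile_<row>_<col>.region.png`` +
    ``nuclei.csv`` + ``slide.json``.
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    tax = build_default_taxonomy()
    rows, cols = _grid_shape(n_tiles)
    rng = np.random.default_rng(params.seed)

    n_bg = int(round(background_fraction * n_tiles))
    n_tissue = n_tiles - n_bg
    n_tumor = int(round(tumor_coverage * n_tissue))
    kinds = ["background"] * n_bg + ["tumor"] * n_tumor + ["stroma"] * (
        n_tissue - n_tumor
    )
    kinds = [kinds[i] for i in rng.permutation(n_tiles)]

    tiles, truth_rows = [], []
    tile_px = params.roi_size_px
    for idx, kind in enumerate(kinds):
        r, c = divmod(idx, cols)
        tile_seed = int((params.seed * 100003 + idx * 7919) % (2**31))
        if kind == "background":
            p = replace(params, seed=tile_seed, region_layout="half_plane",
                        tumor_coverage=0.0)
            tile = generate_roi(p, taxonomy=tax, slide_id=slide_id,
                                hospital_id=hospital_id,
                                origin_xy=(c * tile_px, r * tile_px))
            empty = tax.region_code("empty")
            tile.region_mask_20x[:] = empty
            tile.region_mask_10x[:] = empty
            tile.nucleus_instance_map_20x[:] = 0
            tile.nucleus_class_per_instance = {}
            tile.rgb_20x[:] = 255
            tile.rgb_10x[:] = 255
        else:
            cov = tumor_coverage if kind == "tumor" else 0.0
            p = replace(params, seed=tile_seed, tumor_coverage=cov)
            tile = generate_roi(p, taxonomy=tax, slide_id=slide_id,
                                hospital_id=hospital_id,
                                origin_xy=(c * tile_px, r * tile_px))
        tiles.append(tile)
        tt = tile.truth_table()
        tt.insert(0, "tile", f"tile_{r}_{c}")
        truth_rows.append(tt)

    nonempty = [t for t in truth_rows if not t.empty]
    if nonempty:
        truth = pd.concat(nonempty, ignore_index=True)
    else:
        truth = pd.DataFrame(
            columns=["tile", "instance_id", "x", "y", "class", "region", "pixel_count"]
        )
    meta = {
        "slide_id": slide_id,
        "hospital_id": hospital_id,
        "mpp": params.mpp,
        "grid": [rows, cols],
        "tile_px": tile_px,
        "seed": params.seed,
        "n_tiles": n_tiles,
    }

    if out_dir is not None:
        sdir = Path(out_dir) / slide_id
        try:
            sdir.mkdir(parents=True, exist_ok=True)
            for idx, tile in enumerate(tiles):
                r, c = divmod(idx, cols)
                Image.fromarray(tile.rgb_20x).save(sdir / f"tile_{r}_{c}.png")
                Image.fromarray(
                    tile.region_mask_20x.astype(np.uint8), mode="L"
                ).save(sdir / f"tile_{r}_{c}.region.png")
            truth.to_csv(sdir / "nuclei.csv", index=False)
            (sdir / "slide.json").write_text(json.dumps(meta, indent=1))
        except OSError as exc:
            raise OSError(f"writing synthetic slide under {sdir}: {exc}") from exc

    return tiles, truth, meta


# --- calibration cohorts -----------------------------------------------------

def generate_cohort(
    n_slides: int,
    true_scores,
    visual_noise_sd: float,
    scale: float,
    n_outliers: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort of paired computational/visual scores for calibration tests.

    ``computational_score`` is the true score; ``visual_score`` is
    ``scale * true + N(0, visual_noise_sd)``.  ``n_outliers`` rows get their
    visual score displaced far enough that the 1.96-SD z-disagreement rule
    flags exactly those rows (the displacement is searched deterministically).
    """
    true_scores = np.asarray(list(true_scores), dtype=np.float64)
    if len(true_scores) != n_slides:
        raise ValueError("true_scores length must equal n_slides")
    if n_outliers >= n_slides:
        raise ValueError("n_outliers must be < n_slides")
    rng = np.random.default_rng(seed)
    comp = true_scores.copy()
    vis = scale * comp + rng.normal(0.0, visual_noise_sd, size=n_slides)
    outlier_idx = rng.choice(n_slides, size=n_outliers, replace=False)

    def flagged(v):
        zc = (comp - comp.mean()) / comp.std(ddof=1)
        zv = (v - v.mean()) / v.std(ddof=1)
        d = zv - zc
        return set(np.flatnonzero(np.abs(d / d.std(ddof=1)) > 1.96))

    if n_outliers > 0:
        base = max(scale * comp.std(ddof=1), visual_noise_sd, 1e-3)
        signs = np.where(rng.random(n_outliers) < 0.5, -1.0, 1.0)
        for mult in np.arange(0.5, 50.0, 0.5):
            trial = vis.copy()
            trial[outlier_idx] += signs * mult * base
            if flagged(trial) == set(outlier_idx):
                vis = trial
                break
        else:
            raise RuntimeError("could not construct the requested outliers")

    return pd.DataFrame(
        {
            "slide_id": [f"slide_{i}" for i in range(n_slides)],
            "computational_score": comp,
            "visual_score": vis,
            "is_injected_outlier": np.isin(np.arange(n_slides), outlier_idx),
        }
    )


def default_kernel_violations(sample: RoiSample, taxonomy: ClassTaxonomy | None = None):
    """Instances whose class is prohibited in their centroid's region."""
    tax = taxonomy or build_default_taxonomy()
    K = build_default_kernel(tax).K
    bad = []
    for _, row in sample.truth_table().iterrows():
        if row["region"] == 0:
            continue
        if K[int(row["region"]) - 1, int(row["class"]) - 1] == 0:
            bad.append(int(row["instance_id"]))
    return bad
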