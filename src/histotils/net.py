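"""Two-resolution panoptic segmentation network with region-constrained nuclei.

Two parallel U-Nets segment tissue regions at 10x objective (1.0 micron/px)
and cell nuclei at 20x (0.5 micron/px).  The high-power field (HPF) processed
by the nucleus branch covers the central half-footprint of the region branch's
field of view, so both branches output grids of the same pixel size.  Context
flows between branches two ways:

* a feature hook: the region decoder's feature map at a chosen decoder level
  is center-cropped to the HPF footprint, nearest-upsampled, and concatenated
  onto the nucleus decoder at the same level;
* class-specific attention maps: upsampled region probabilities are mixed
  with a hard compatibility kernel and learned row-stochastic priors to give,
  at every pixel, a distribution over nucleus classes, which multiplicatively
  constrains the nucleus softmax.

Training uses a multi-task loss giving equal weight to four components:
full-field region prediction, HPF region prediction, unconstrained nucleus
prediction, and region-constrained nucleus prediction.  Each component is
categorical cross-entropy plus (1 - soft-DICE) averaged over classes, with
unannotated pixels ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from .synthetic import RoiSample
from .taxonomy import (
    ClassTaxonomy,
    CompatibilityKernel,
    PriorMatrix,
    build_default_kernel,
    build_default_taxonomy,
)

logger = logging.getLogger(__name__)

ATTENTION_EPS = 1e-8


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The HPF must cover the central half of the ROI footprint:
    ``hpf_input_px * hpf_mpp == roi_input_px * roi_mpp / 2``.  With the
    default 1.0 / 0.5 micron-per-pixel pair this forces
    ``hpf_input_px == roi_input_px`` and both branches share a grid size.
    """

    depth: int = 5
    base_channels: int = 32
    roi_input_px: int = 512   # at roi_mpp
    hpf_input_px: int = 512   # at hpf_mpp
    roi_mpp: float = 1.0
    hpf_mpp: float = 0.5
    n_region_classes: int = 6
    n_nucleus_classes: int = 6
    hook_level: int = 2       # decoder level counted from the bottleneck

    def __post_init__(self):
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if not np.isclose(self.hpf_input_px * self.hpf_mpp,
                          self.roi_input_px * self.roi_mpp / 2):
            raise ConfigurationError(
                "HPF footprint must equal half the ROI footprint: "
                f"{self.hpf_input_px}px * {self.hpf_mpp} MPP != "
                f"{self.roi_input_px}px * {self.roi_mpp} MPP / 2"
            )
        if not 1 <= self.hook_level <= self.depth - 1:
            raise ConfigurationError("hook_level must be in [1, depth-1]")
        step = 2 ** (self.depth - 1)
        if self.roi_input_px % step or self.hpf_input_px % step:
            raise ConfigurationError(
                f"input sizes must be divisible by 2**(depth-1) = {step}"
            )

    @staticmethod
    def toy(roi_input_px: int = 64, depth: int = 3, base_channels: int = 8,
            hook_level: int = 1) -> "NetworkConfig":
        return NetworkConfig(depth=depth, base_channels=base_channels,
                             roi_input_px=roi_input_px, hpf_input_px=roi_input_px,
                             hook_level=hook_level)


@dataclass
class RawOutputs:
    """One forward pass: region logits plus nucleus maps before/after constraint."""

    roi_region_logits: Tensor          # (N, R, roi, roi) at roi_mpp
    hpf_region_probs: Tensor           # (N, R, hpf, hpf) at hpf_mpp
    nucleus_logits_unconstrained: Tensor  # (N, 1+C, hpf, hpf)
    nucleus_probs_constrained: Tensor     # (N, 1+C, hpf, hpf)
    attention: Tensor                  # (N, C, hpf, hpf)


@dataclass
class NucleusInstance:
    instance_id: int
    pixel_count: int
    centroid_xy: tuple            # (x, y) in 0.5 MPP pixels
    class_probs: np.ndarray       # over nucleus classes, sums to 1
    class_code: int               # argmax, ties to lower code
    region_code: int = 0          # region argmax at the centroid


@dataclass
class PanopticPrediction:
    """Per-pixel region probabilities plus classified nucleus instances."""

    region_probs: np.ndarray      # (R, H, W) on the HPF grid at hpf_mpp
    nucleus_probs: np.ndarray     # (1+C, H, W) constrained
    instances: list
    mpp: float = 0.5
    origin_xy: tuple = (0, 0)

    @property
    def region_map(self) -> np.ndarray:
        return self.region_probs.argmax(axis=0) + 1


# --- building blocks ---------------------------------------------------------

class _Conv:
    def __init__(self, cin, cout, k, rng):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)

    @property
    def params(self):
        return [self.w, self.b]


class _Block:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1 = _Conv(cin, cout, 3, rng)
        self.c2 = _Conv(cout, cout, 3, rng)

    def __call__(self, x):
        return ad.relu(self.c2(ad.relu(self.c1(x))))

    @property
    def params(self):
        return self.c1.params + self.c2.params


class UNet:
    """Plain U-Net encoder-decoder returning logits and decoder features.

    ``extra_at_level`` adds input channels to one decoder block so that
    cross-branch features can be concatenated there; decoder levels count
    upward from the bottleneck (level 1 = first upsample).
    """

    def __init__(self, depth, base, n_in, n_out, rng, extra_at_level=None,
                 extra_channels=0):
        self.depth = depth
        chans = [base * 2 ** i for i in range(depth)]
        self.enc = []
        cin = n_in
        for c in chans:
            self.enc.append(_Block(cin, c, rng))
            cin = c
        self.dec = []
        for lvl in range(1, depth):  # level above bottleneck
            cout = chans[depth - 1 - lvl]
            cin_dec = chans[depth - lvl] + cout  # upsampled + skip
            if extra_at_level == lvl:
                cin_dec += extra_channels
            self.dec.append(_Block(cin_dec, cout, rng))
        self.head = _Conv(chans[0], n_out, 1, rng)
        self.extra_at_level = extra_at_level

    def forward(self, x, extra=None):
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            h = block(h)
            if i < self.depth - 1:
                skips.append(h)
                h = ad.maxpool2(h)
        feats = {0: h}
        for lvl, block in enumerate(self.dec, start=1):
            h = ad.upsample2(h)
            parts = [h, skips[self.depth - 1 - lvl]]
            if self.extra_at_level == lvl:
                if extra is None:
                    raise ConfigurationError("hook features expected but missing")
                parts.append(extra)
            h = block(ad.concat(parts, axis=1))
            feats[lvl] = h
        return self.head(h), feats

    @property
    def params(self):
        out = []
        for b in self.enc + self.dec:
            out += b.params
        return out + self.head.params

    def feature_channels(self, level):
        chans = [self.enc[i].c2.w.data.shape[0] for i in range(self.depth)]
        return chans[self.depth - 1 - level] if level > 0 else chans[-1]


class PanopticNet:
    """The full two-branch network with learned priors."""

    def __init__(self, config: NetworkConfig, taxonomy: ClassTaxonomy | None = None,
                 kernel: CompatibilityKernel | None = None, seed: int = 0):
        self.config = config
        self.taxonomy = taxonomy or build_default_taxonomy()
        self.kernel = kernel or build_default_kernel(self.taxonomy)
        rng = np.random.default_rng(seed)
        self.region_unet = UNet(config.depth, config.base_channels, 3,
                                config.n_region_classes, rng)
        hook_ch = self.region_unet.feature_channels(config.hook_level)
        self.nucleus_unet = UNet(config.depth, config.base_channels, 3,
                                 config.n_nucleus_classes + 1, rng,
                                 extra_at_level=config.hook_level,
                                 extra_channels=hook_ch)
        # learned priors: free logits, masked row-softmax over allowed classes
        self.prior_logits = Tensor(
            np.zeros((config.n_region_classes, config.n_nucleus_classes)),
            requires_grad=True,
        )

    @property
    def params(self):
        return self.region_unet.params + self.nucleus_unet.params + [self.prior_logits]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def prior_tensor(self) -> Tensor:
        """Row-stochastic priors over kernel-allowed classes (differentiable)."""
        k = Tensor(self.kernel.K)
        e = ad.mul(ad.exp(self.prior_logits), k)
        return ad.div(e, ad.tsum(e, axis=1, keepdims=True))

    def prior(self) -> PriorMatrix:
        return PriorMatrix(self.prior_tensor().data)

    def forward(self, rgb_10x: np.ndarray, rgb_20x_hpf: np.ndarray) -> RawOutputs:
        """rgb_10x: (N,3,roi,roi) in [0,255]; rgb_20x_hpf: (N,3,hpf,hpf)."""
        cfg = self.config
        x_roi = Tensor(1.0 - np.asarray(rgb_10x, dtype=np.float64) / 255.0)
        x_hpf = Tensor(1.0 - np.asarray(rgb_20x_hpf, dtype=np.float64) / 255.0)
        region_logits, region_feats = self.region_unet.forward(x_roi)

        # region probabilities on the HPF grid (central half, 2x nearest)
        region_probs = ad.softmax(region_logits, axis=1)
        half = cfg.roi_input_px // 2
        hpf_region_probs = ad.upsample2(ad.crop_center(region_probs, half, half))

        # feature hook: crop central half at the hook level, 2x nearest upsample
        feat = region_feats[cfg.hook_level]
        fh = feat.data.shape[-1]
        hook = ad.upsample2(ad.crop_center(feat, fh // 2, fh // 2))
        # hook grid must match the nucleus decoder grid at the same level
        nucleus_logits, _ = self.nucleus_unet.forward(x_hpf, extra=hook)

        attention = attention_graph(hpf_region_probs, self.kernel, self.prior_tensor())
        constrained = constrain_graph(nucleus_logits, attention)
        return RawOutputs(region_logits, hpf_region_probs, nucleus_logits,
                          constrained, attention)


def build_network(config: NetworkConfig, taxonomy=None, kernel=None, seed=0) -> PanopticNet:
    return PanopticNet(config, taxonomy=taxonomy, kernel=kernel, seed=seed)


# --- attention + constraint --------------------------------------------------

def attention_graph(hpf_region_probs, kernel: CompatibilityKernel, prior) -> Tensor:
    """Differentiable class-specific attention: mix, floor at eps, renormalize."""
    probs = ad.astensor(hpf_region_probs)
    m = ad.mul(ad.astensor(prior.P if isinstance(prior, PriorMatrix) else prior),
               Tensor(kernel.K))
    raw = ad.channel_mix(probs, m)
    floored = ad.add(raw, ATTENTION_EPS)
    return ad.div(floored, ad.tsum(floored, axis=1, keepdims=True))


def compute_attention(hpf_region_probs: np.ndarray, kernel: CompatibilityKernel,
                      prior: PriorMatrix) -> np.ndarray:
    """Class-specific attention maps from region probabilities.

    ``A_c(x) = sum_r probs_r(x) K[r,c] P[r,c]``, floored at 1e-8 and
    renormalized over classes.  Pixels where every class is prohibited fall
    back to a uniform distribution over the classes allowed by the region
    argmax (or over all classes, with a warning, if none are allowed).
    Accepts (R, H, W) or (N, R, H, W); returns the matching class-axis shape.
    """
    probs = np.asarray(hpf_region_probs, dtype=np.float64)
    squeeze = probs.ndim == 3
    if squeeze:
        probs = probs[None]
    m = kernel.K * prior.P
    raw = np.einsum("nrhw,rc->nchw", probs, m, optimize=True)
    dead = raw.sum(axis=1) < ATTENTION_EPS  # all classes prohibited
    if dead.any():
        argmax_r = probs.argmax(axis=1)
        allowed = kernel.K[argmax_r]  # (n, h, w, C)
        allowed = np.moveaxis(allowed, -1, 1)
        none_allowed = allowed.sum(axis=1) == 0
        if none_allowed.any():
            logger.warning(
                "attention fallback: %d pixels allow no nucleus class; "
                "using uniform over all classes", int(none_allowed.sum())
            )
            allowed[:, :, :, :][np.broadcast_to(none_allowed[:, None], allowed.shape)] = 1.0
        fallback = allowed / allowed.sum(axis=1, keepdims=True)
        raw = np.where(dead[:, None], fallback, raw)
    floored = np.maximum(raw, ATTENTION_EPS)
    att = floored / floored.sum(axis=1, keepdims=True)
    return att[0] if squeeze else att


def constrain_graph(nucleus_logits, attention) -> Tensor:
    """Constrained probabilities with the background channel passed through.

    The background probability is kept exactly as the softmax produced it;
    the foreground mass ``1 - p_bg`` is redistributed over classes in
    proportion to ``p_c * A_c``.  With uniform attention this is the identity.
    Attention values at the numerical floor mark hard-prohibited classes and
    are zeroed outright (a constant mask, so no gradient flows through the
    prohibition), making the kernel constraint exact under one-hot regions.
    """
    logits = ad.astensor(nucleus_logits)
    att = ad.astensor(attention)
    probs = ad.softmax(logits, axis=1)
    n_ch = probs.data.shape[1]
    bg = _channel_slice(probs, 0, 1)
    fg = _channel_slice(probs, 1, n_ch)
    prohibited = (att.data <= ATTENTION_EPS * 1.5).astype(np.float64)
    weighted = ad.mul(ad.mul(fg, att), Tensor(1.0 - prohibited))
    denom = ad.add(ad.tsum(weighted, axis=1, keepdims=True), 1e-30)
    fg_mass = ad.tsum(fg, axis=1, keepdims=True)
    fg_out = ad.mul(ad.div(weighted, denom), fg_mass)
    return ad.concat([bg, fg_out], axis=1)


def _channel_slice(a: Tensor, lo: int, hi: int) -> Tensor:
    def back(g):
        full = np.zeros(a.data.shape)
        full[:, lo:hi] = g
        return (full,)

    return Tensor(a.data[:, lo:hi].copy(), parents=(a,), backward=back)


def constrain_nuclei(nucleus_logits: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """NumPy-facing constraint; see :func:`constrain_graph`.

    Accepts (1+C, H, W) or (N, 1+C, H, W) logits with a leading background
    channel and matching attention over the C foreground classes.
    """
    logits = np.asarray(nucleus_logits, dtype=np.float64)
    if np.isnan(logits).any():
        raise ValueError("NaN nucleus logits")
    squeeze = logits.ndim == 3
    if squeeze:
        logits = logits[None]
        attention = np.asarray(attention)[None]
    out = constrain_graph(Tensor(logits), Tensor(attention)).data
    return out[0] if squeeze else out


# --- loss --------------------------------------------------------------------

def _onehot(mask: np.ndarray, n_channels: int, offset: int) -> np.ndarray:
    """(N,H,W) int mask -> (N,n_channels,H,W) one-hot of ``code - offset``."""
    out = np.zeros((mask.shape[0], n_channels) + mask.shape[1:])
    for ch in range(n_channels):
        out[:, ch] = mask == ch + offset
    return out


def _component_loss(log_probs: Tensor, probs: Tensor, onehot: np.ndarray,
                    valid: np.ndarray) -> Tensor:
    """Cross-entropy + (1 - soft-DICE) over classes, ignoring invalid pixels."""
    n_valid = float(valid.sum())
    if n_valid == 0:
        warnings.warn("loss component has an all-ignore target; contributing 0")
        return Tensor(0.0)
    v = valid[:, None].astype(np.float64)
    target = onehot * v
    ce = ad.mul(ad.tsum(ad.mul(log_probs, Tensor(target))), -1.0 / n_valid)
    dice_terms = []
    for ch in range(onehot.shape[1]):
        t = target[:, ch : ch + 1]
        if t.sum() == 0:
            continue
        p = _channel_slice(probs, ch, ch + 1)
        pv = ad.mul(p, Tensor(v))
        inter = ad.tsum(ad.mul(pv, Tensor(t)))
        denom = ad.add(ad.tsum(pv), float(t.sum()))
        dice_terms.append(ad.div(ad.mul(inter, 2.0), denom))
    if not dice_terms:
        return ce
    dice = dice_terms[0]
    for t in dice_terms[1:]:
        dice = ad.add(dice, t)
    dice = ad.mul(dice, 1.0 / len(dice_terms))
    return ad.add(ce, ad.add(ad.mul(dice, -1.0), 1.0))


def multitask_loss(outputs: RawOutputs, targets: dict):
    """Equal-weight four-component loss.

    ``targets`` carries integer masks (NHW): ``region_10x`` (codes, 0=ignore),
    ``region_20x_hpf``, ``nucleus_20x_hpf`` (0=background channel), and a
    boolean ``nucleus_valid`` marking annotated nucleus pixels.
    Returns ``(total, [roi_region, hpf_region, nucleus_unconstrained,
    nucleus_constrained])`` as graph Tensors.
    """
    n_region = outputs.roi_region_logits.data.shape[1]
    n_nuc_ch = outputs.nucleus_logits_unconstrained.data.shape[1]

    reg10 = np.asarray(targets["region_10x"])
    comp1 = _component_loss(
        ad.log_softmax(outputs.roi_region_logits, axis=1),
        ad.softmax(outputs.roi_region_logits, axis=1),
        _onehot(reg10, n_region, offset=1),
        reg10 > 0,
    )
    reg20 = np.asarray(targets["region_20x_hpf"])
    hpf_probs = outputs.hpf_region_probs
    comp2 = _component_loss(
        ad.log(hpf_probs, eps=1e-12), hpf_probs,
        _onehot(reg20, n_region, offset=1),
        reg20 > 0,
    )
    nuc = np.asarray(targets["nucleus_20x_hpf"])
    nvalid = np.asarray(targets["nucleus_valid"], dtype=bool)
    nuc_onehot = _onehot(nuc, n_nuc_ch, offset=0)  # channel 0 = background
    comp3 = _component_loss(
        ad.log_softmax(outputs.nucleus_logits_unconstrained, axis=1),
        ad.softmax(outputs.nucleus_logits_unconstrained, axis=1),
        nuc_onehot, nvalid,
    )
    comp4 = _component_loss(
        ad.log(outputs.nucleus_probs_constrained, eps=1e-12),
        outputs.nucleus_probs_constrained,
        nuc_onehot, nvalid,
    )
    comps = [comp1, comp2, comp3, comp4]
    total = comps[0]
    for c in comps[1:]:
        total = ad.add(total, c)
    return ad.mul(total, 0.25), comps


# --- instance extraction -----------------------------------------------------

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def extract_instances(nucleus_probs_constrained: np.ndarray, min_size_px: int = 10,
                      region_probs: np.ndarray | None = None) -> list:
    """Connected-component instance extraction from constrained probabilities.

    Foreground is where the argmax channel is not background; 4-connected
    components smaller than ``min_size_px`` are dropped.  Instance class
    probabilities are the mean constrained foreground probabilities over the
    component, renormalized; ties in the argmax break toward the lower code.
    """
    probs = np.asarray(nucleus_probs_constrained, dtype=np.float64)
    fg = probs.argmax(axis=0) != 0
    labels, n = ndimage.label(fg, structure=_FOUR_CONNECTED)
    instances = []
    next_id = 1
    for comp in range(1, n + 1):
        ys, xs = np.nonzero(labels == comp)
        if len(ys) < min_size_px:
            continue
        mean_probs = probs[1:, ys, xs].mean(axis=1)
        s = mean_probs.sum()
        class_probs = mean_probs / s if s > 0 else np.full(len(mean_probs),
                                                           1.0 / len(mean_probs))
        cy, cx = float(ys.mean()), float(xs.mean())
        region_code = 0
        if region_probs is not None:
            region_code = int(
                region_probs[:, int(round(cy)), int(round(cx))].argmax() + 1
            )
        instances.append(
            NucleusInstance(
                instance_id=next_id,
                pixel_count=len(ys),
                centroid_xy=(cx, cy),
                class_probs=class_probs,
                class_code=int(class_probs.argmax() + 1),
                region_code=region_code,
            )
        )
        next_id += 1
    return instances


# --- training ----------------------------------------------------------------

def sample_to_arrays(sample: RoiSample, config: NetworkConfig):
    """Convert a ROI sample into network inputs and loss targets."""
    hpf = config.hpf_input_px
    rgb10 = np.moveaxis(sample.rgb_10x, -1, 0)[None]
    full = sample.rgb_20x.shape[0]
    y0 = (full - hpf) // 2
    sl = slice(y0, y0 + hpf)
    rgb20 = np.moveaxis(sample.rgb_20x[sl, sl], -1, 0)[None]
    targets = {
        "region_10x": sample.region_mask_10x[None],
        "region_20x_hpf": sample.region_mask_20x[sl, sl][None],
        "nucleus_20x_hpf": sample.nucleus_class_mask_20x[sl, sl][None],
        "nucleus_valid": sample.nucleus_annotated_mask_20x[sl, sl][None],
    }
    return rgb10, rgb20, targets


def train_toy(dataset: list, config: NetworkConfig, lr: float = 5e-3,
              steps: int = 300, seed: int = 0,
              taxonomy=None, kernel=None, decay_at: float = 0.7):
    """Desk-scale training loop: one ROI per step, Adam, seeded throughout.

    One step = one ROI, visited round-robin in a seeded random order per
    epoch; gradients are clipped to a global norm of 5 and the learning rate
    drops by 10x after ``decay_at`` of the steps to settle late training.
    Returns ``(net, trace)`` where ``trace`` is a DataFrame of the four loss
    components per step.  Raises on divergence with the trace attached.
    """
    if not dataset:
        raise ValueError("dataset must contain at least one sample")
    net = PanopticNet(config, taxonomy=taxonomy, kernel=kernel, seed=seed)
    rng = np.random.default_rng(seed + 1)
    opt = ad.Adam(net.params, lr=lr)
    prepared = [sample_to_arrays(s, config) for s in dataset]
    rows = []
    order: list = []
    for step in range(steps):
        if step == int(decay_at * steps):
            opt.lr = lr * 0.1
        if not order:
            order = [int(i) for i in rng.permutation(len(prepared))]
        rgb10, rgb20, targets = prepared[order.pop()]
        out = net.forward(rgb10, rgb20)
        total, comps = multitask_loss(out, targets)
        if not np.isfinite(total.data):
            trace = pd.DataFrame(rows)
            raise RuntimeError(f"training diverged at step {step}; trace:\n{trace}")
        opt.zero_grad()
        total.backward()
        gnorm = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in net.params if p.grad is not None))
        if gnorm > 5.0:
            for p in net.params:
                if p.grad is not None:
                    p.grad *= 5.0 / gnorm
        opt.step()
        rows.append(
            {"step": step,
             "roi_region": float(comps[0].data),
             "hpf_region": float(comps[1].data),
             "nucleus_unconstrained": float(comps[2].data),
             "nucleus_constrained": float(comps[3].data),
             "total": float(total.data)}
        )
    trace = pd.DataFrame(
        rows, columns=["step", "roi_region", "hpf_region",
                       "nucleus_unconstrained", "nucleus_constrained", "total"]
    )
    return net, trace


def prediction_from_truth(sample: RoiSample,
                          taxonomy: ClassTaxonomy | None = None) -> PanopticPrediction:
    """Oracle panoptic prediction assembled from generator ground truth.

    Useful for isolating the scoring stages from the network: region and
    nucleus probability maps are one-hot on the true masks and instances
    carry their true classes and centroid regions.
    """
    tax = taxonomy or build_default_taxonomy()
    region = sample.region_mask_20x
    region_probs = np.stack(
        [(region == c).astype(float) for c in range(1, tax.n_regions + 1)]
    )
    class_mask = sample.nucleus_class_mask_20x
    nucleus_probs = np.stack(
        [(class_mask == c).astype(float) for c in range(tax.n_nuclei + 1)]
    )
    instances = []
    for row in sample.truth_table().itertuples(index=False):
        code = int(row[3])  # class column
        probs = np.zeros(tax.n_nuclei)
        probs[code - 1] = 1.0
        instances.append(
            NucleusInstance(
                instance_id=int(row.instance_id),
                pixel_count=int(row.pixel_count),
                centroid_xy=(float(row.x), float(row.y)),
                class_probs=probs,
                class_code=code,
                region_code=int(row.region),
            )
        )
    return PanopticPrediction(region_probs=region_probs,
                              nucleus_probs=nucleus_probs,
                              instances=instances, mpp=sample.mpp)


def predict_sample(net: PanopticNet, sample: RoiSample,
                   min_size_px: int = 10) -> PanopticPrediction:
    rgb10, rgb20, _ = sample_to_arrays(sample, net.config)
    out = net.forward(rgb10, rgb20)
    region_probs = out.hpf_region_probs.data[0]
    nucleus_probs = out.nucleus_probs_constrained.data[0]
    instances = extract_instances(nucleus_probs, min_size_px=min_size_px,
                                  region_probs=region_probs)
    return PanopticPrediction(region_probs=region_probs,
                              nucleus_probs=nucleus_probs,
                              instances=instances,
                              mpp=net.config.hpf_mpp,
                              origin_xy=sample.origin_xy)


class PanopticSegmenter:
    """sklearn-style estimator facade over the two-branch network.

    ``fit(samples)`` trains on a list of ROI samples; ``predict(sample)``
    returns a :class:`PanopticPrediction`.  Fitted attributes: ``net_``,
    ``loss_trace_``, ``prior_``.
    """

    def __init__(self, depth=3, base_channels=8, roi_input_px=64, hook_level=1,
                 lr=3e-3, steps=300, min_size_px=10, seed=0):
        self.depth = depth
        self.base_channels = base_channels
        self.roi_input_px = roi_input_px
        self.hook_level = hook_level
        self.lr = lr
        self.steps = steps
        self.min_size_px = min_size_px
        self.seed = seed

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("depth", "base_channels", "roi_input_px", "hook_level",
                 "lr", "steps", "min_size_px", "seed")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self):
        return NetworkConfig.toy(roi_input_px=self.roi_input_px, depth=self.depth,
                                 base_channels=self.base_channels,
                                 hook_level=self.hook_level)

    def fit(self, samples, y=None):
        self.net_, self.loss_trace_ = train_toy(
            list(samples), self._config(), lr=self.lr, steps=self.steps,
            seed=self.seed,
        )
        self.prior_ = self.net_.prior()
        return self

    def predict(self, sample) -> PanopticPrediction:
        return predict_sample(self.net_, sample, min_size_px=self.min_size_px)
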