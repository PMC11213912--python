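"""Shared fixtures: toy ROIs, a trained toy network, oracle predictions."""

from __future__ import annotations

import numpy as np
import pytest

from histotils import synthetic as syn
from histotils.net import (
    NetworkConfig,
    PanopticPrediction,
    prediction_from_truth,
    train_toy,
)
from histotils.taxonomy import build_default_taxonomy

TOY_ROI_PX = 128  # 20x pixels; the network sees 64 px at each branch


def toy_roi_params(seed: int, layout: str = "half_plane", tumor_coverage: float = 0.5):
    return syn.SynthParams(
        roi_size_px=TOY_ROI_PX,
        seed=seed,
        region_layout=layout,
        til_fraction=0.4,
        stromal_cellularity=8000.0,
        nucleus_radius_px=(4.0, 0.8),
        tumor_coverage=tumor_coverage,
    )


@pytest.fixture(scope="session")
def taxonomy():
    return build_default_taxonomy()


@pytest.fixture(scope="session")
def toy_rois():
    specs = [
        ("half_plane", 0.5),
        ("half_plane", 0.3),
        ("blobs", 0.3),
        ("rings", 0.3),
        ("half_plane", 0.7),
    ]
    return [
        syn.generate_roi(toy_roi_params(seed, layout, cov))
        for seed, (layout, cov) in enumerate(specs)
    ]


@pytest.fixture(scope="session")
def toy_config():
    return NetworkConfig.toy(roi_input_px=TOY_ROI_PX // 2, depth=3,
                             base_channels=8, hook_level=1)


@pytest.fixture(scope="session")
def trained_toy(toy_rois, toy_config):
    """A toy network overfit on the 5 synthetic ROIs (session-wide)."""
    net, trace = train_toy(toy_rois, toy_config, steps=500, seed=0)
    return net, trace


def oracle_prediction(sample, taxonomy=None) -> PanopticPrediction:
    """Panoptic prediction built from generator ground truth (no network)."""
    return prediction_from_truth(sample, taxonomy)
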