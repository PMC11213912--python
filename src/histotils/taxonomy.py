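"""Class vocabularies, region/nucleus compatibility constraints, and priors.

Every other module indexes tissue-region and nucleus classes through the
:class:`ClassTaxonomy` defined here.  Region classes are segmented at 10x
objective (1.0 micron/pixel), nucleus classes at 20x (0.5 micron/pixel).
Integer code 0 is reserved in both vocabularies for background / unannotated
pixels so that masks double as loss-weight masks.

The compatibility kernel encodes hard biological constraints on which nucleus
classes may occur inside which tissue regions (e.g. no fibroblast nuclei
inside an epithelial tumor nest); the prior matrix carries soft, learnable
region-nucleus association strengths.  Both feed the class-specific attention
maps used to constrain nucleus classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

REGION_CLASSES = (
    "cancer",
    "normal_epithelium",
    "stroma",
    "tils_dense",
    "necrosis_debris",
    "empty",
)

NUCLEUS_CLASSES = (
    "cancer",
    "normal_epithelium",
    "fibroblast",
    "lymphocyte",
    "plasma_cell",
    "debris",
)

SUPERCLASSES = ("epithelium", "stroma", "TILs", "other")

_REGION_GROUPING = {
    "cancer": "epithelium",
    "normal_epithelium": "epithelium",
    "stroma": "stroma",
    "tils_dense": "stroma",
    "necrosis_debris": "other",
    "empty": "other",
}

_NUCLEUS_GROUPING = {
    "cancer": "epithelium",
    "normal_epithelium": "epithelium",
    "fibroblast": "stroma",
    "lymphocyte": "TILs",
    "plasma_cell": "TILs",
    "debris": "other",
}


class TaxonomyError(ValueError):
    """Raised when a taxonomy, kernel or prior configuration is invalid."""


@dataclass(frozen=True)
class ClassTaxonomy:
    """Fixed region and nucleus vocabularies with integer codes 1..6.

    Code 0 means unannotated/ignore for regions and background for nuclei.
    ``region_grouping`` / ``nucleus_grouping`` map each class onto the
    simplified superclasses {epithelium, stroma, TILs, other} used for
    reliable evaluation and for TIL-score compartments.
    """

    region_classes: tuple = REGION_CLASSES
    nucleus_classes: tuple = NUCLEUS_CLASSES
    region_grouping: dict = field(default_factory=lambda: dict(_REGION_GROUPING))
    nucleus_grouping: dict = field(default_factory=lambda: dict(_NUCLEUS_GROUPING))

    def __post_init__(self):
        if len(set(self.region_classes)) != len(self.region_classes):
            raise TaxonomyError("duplicate region class names")
        if len(set(self.nucleus_classes)) != len(self.nucleus_classes):
            raise TaxonomyError("duplicate nucleus class names")
        for c in self.region_classes:
            if self.region_grouping.get(c) not in SUPERCLASSES:
                raise TaxonomyError(f"region class {c!r} lacks a valid superclass")
        for c in self.nucleus_classes:
            if self.nucleus_grouping.get(c) not in SUPERCLASSES:
                raise TaxonomyError(f"nucleus class {c!r} lacks a valid superclass")

    # --- code lookups (codes are 1-based; 0 = background/ignore) ---

    @property
    def n_regions(self) -> int:
        return len(self.region_classes)

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_classes)

    def region_code(self, name: str) -> int:
        return self.region_classes.index(name) + 1

    def nucleus_code(self, name: str) -> int:
        return self.nucleus_classes.index(name) + 1

    def region_name(self, code: int) -> str:
        return self.region_classes[code - 1]

    def nucleus_name(self, code: int) -> str:
        return self.nucleus_classes[code - 1]

    def group_region(self, name: str) -> str:
        return self.region_grouping[name]

    def group_nucleus(self, name: str) -> str:
        return self.nucleus_grouping[name]

    def region_codes_in_group(self, superclass: str) -> list:
        return [
            i + 1
            for i, c in enumerate(self.region_classes)
            if self.region_grouping[c] == superclass
        ]

    def nucleus_codes_in_group(self, superclass: str) -> list:
        return [
            i + 1
            for i, c in enumerate(self.nucleus_classes)
            if self.nucleus_grouping[c] == superclass
        ]

    def grouped_region_mask(self, mask: np.ndarray) -> np.ndarray:
        """Relabel a region-code mask to superclass codes.

        Output codes: 0 ignore, then 1..4 following ``SUPERCLASSES`` order.
        """
        out = np.zeros_like(mask)
        for i, name in enumerate(self.region_classes):
            out[mask == i + 1] = SUPERCLASSES.index(self.region_grouping[name]) + 1
        return out


@dataclass(frozen=True)
class CompatibilityKernel:
    """Binary region x nucleus matrix; 1 = nucleus class allowed in region."""

    K: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K)
        if not np.isin(K, (0, 1)).all():
            raise TaxonomyError("kernel entries must be exactly 0 or 1")
        if (K.sum(axis=1) < 1).any():
            raise TaxonomyError("every region row must allow >= 1 nucleus class")
        object.__setattr__(self, "K", K.astype(np.float64))


@dataclass(frozen=True)
class PriorMatrix:
    """Row-stochastic region x nucleus association matrix."""

    P: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.float64)
        if (P < 0).any():
            raise TaxonomyError("prior entries must be nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
            raise TaxonomyError("prior rows must sum to 1 within 1e-6")
        object.__setattr__(self, "P", P)


def build_default_taxonomy() -> ClassTaxonomy:
    """The default 6-region / 6-nucleus vocabulary with its grouping map."""
    return ClassTaxonomy()


def build_default_kernel(taxonomy: ClassTaxonomy) -> CompatibilityKernel:
    """Default hard constraints on nucleus classes per region.

    Epithelial regions prohibit fibroblast and debris nuclei; stromal
    compartments (stroma, TILs-dense) prohibit epithelial nuclei;
    necrosis/debris allows debris plus mononuclear immune cells; the empty
    region allows everything (no evidence to constrain).
    """
    nr, nc = taxonomy.n_regions, taxonomy.n_nuclei
    K = np.ones((nr, nc))

    def forbid(region, nucleus):
        K[taxonomy.region_code(region) - 1, taxonomy.nucleus_code(nucleus) - 1] = 0

    for region in ("cancer", "normal_epithelium"):
        forbid(region, "fibroblast")
        forbid(region, "debris")
    for region in ("stroma", "tils_dense"):
        forbid(region, "cancer")
        forbid(region, "normal_epithelium")
    for nucleus in ("cancer", "normal_epithelium", "fibroblast"):
        forbid("necrosis_debris", nucleus)
    return CompatibilityKernel(K)


def uniform_prior(taxonomy: ClassTaxonomy, kernel: CompatibilityKernel | None = None) -> PriorMatrix:
    """Uniform prior over the classes each region allows."""
    K = kernel.K if kernel is not None else np.ones((taxonomy.n_regions, taxonomy.n_nuclei))
    P = K / K.sum(axis=1, keepdims=True)
    return PriorMatrix(P)


def validate_prior(P: PriorMatrix, K: CompatibilityKernel, taxonomy: ClassTaxonomy | None = None) -> PriorMatrix:
    """Mask a prior by the kernel and renormalize rows.

    Raises :class:`TaxonomyError` naming the offending region class if
    masking zeroes out an entire row.
    """
    masked = P.P * K.K
    sums = masked.sum(axis=1)
    if (sums <= 0).any():
        idx = int(np.flatnonzero(sums <= 0)[0])
        name = taxonomy.region_name(idx + 1) if taxonomy is not None else str(idx)
        raise TaxonomyError(
            f"prior row for region {name!r} is all-zero after kernel masking"
        )
    return PriorMatrix(masked / sums[:, None])


# --- serialization -----------------------------------------------------------

def taxonomy_config(taxonomy: ClassTaxonomy, kernel: CompatibilityKernel, prior: PriorMatrix) -> dict:
    return {
        "region_classes": list(taxonomy.region_classes),
        "nucleus_classes": list(taxonomy.nucleus_classes),
        "region_grouping": dict(taxonomy.region_grouping),
        "nucleus_grouping": dict(taxonomy.nucleus_grouping),
        "kernel": kernel.K.astype(int).tolist(),
        "prior": prior.P.tolist(),
    }


def save_taxonomy(path, taxonomy, kernel, prior):
    with open(path, "w") as fh:
        yaml.safe_dump(taxonomy_config(taxonomy, kernel, prior), fh, sort_keys=False)


def load_taxonomy(path):
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    tax = ClassTaxonomy(
        region_classes=tuple(cfg["region_classes"]),
        nucleus_classes=tuple(cfg["nucleus_classes"]),
        region_grouping=dict(cfg["region_grouping"]),
        nucleus_grouping=dict(cfg["nucleus_grouping"]),
    )
    kernel = CompatibilityKernel(np.array(cfg["kernel"]))
    prior = validate_prior(PriorMatrix(np.array(cfg["prior"])), kernel, tax)
    return tax, kernel, prior
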