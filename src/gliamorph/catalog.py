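"""Catalog of microglial morphometry features exported by filament-tracing software.

Each reconstructed microglia carries two kinds of geometric measurements:

* **scalar** features — one value per cell (soma geometry, whole-filament
  totals such as the number of branch points), and
* **distributed** features — one value per process segment (e.g. the length
  or branching angle of every segment), so each cell contributes a vector.

The catalog records, for every feature, its compartment (soma vs. process),
units, whether it is distributed, the annotated feature-set label where one
exists (fs1 ramification, fs2 soma size/shape, fs3 process shape, fs4 process
size), and the sampling family the synthetic generator uses for it.  Two soma
shape parameters (oblate ellipticity and sphericity) carry no feature-set
annotation and are excluded from the default analysis catalog; they are still
generated so raw exports look complete.

For generation, features are additionally grouped into six sub-blocks nested
inside the four feature sets: the ramification set splits into a core
(whole-filament counts and volume) and a depth/position group, and the
process-size set splits into a cross-section group (area, volume) and a span
group (length, resistance).  The six latent cell states are defined over
these sub-blocks, which makes each state a distinct direction in feature
space — recoverable by factorization — while features of one set still share
their temporal response and co-cluster in the basis matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "FeatureDef",
    "FEATURE_CATALOG",
    "SUBBLOCKS",
    "SUBBLOCK_SET",
    "default_catalog",
    "generator_catalog",
    "scalar_features",
    "distributed_features",
]

# Generator sub-blocks and the feature set each belongs to.
SUBBLOCKS = ("fs1a", "fs1b", "fs2", "fs3", "fs4a", "fs4b")
SUBBLOCK_SET = {
    "fs1a": "fs1", "fs1b": "fs1", "fs2": "fs2",
    "fs3": "fs3", "fs4a": "fs4", "fs4b": "fs4",
}

# Sampling families used by the synthetic generator.
LOGNORMAL = "lognormal"  # sizes, lengths, volumes, resistances (long-tailed)
BOUNDED = "bounded"      # angles, straightness, ellipticity (scaled logistic-normal)
COUNT = "count"          # counts (Poisson-lognormal)


@dataclass(frozen=True)
class FeatureDef:
    """Static definition of one base morphological feature.

    ``feature_set`` is the annotated label ("fs1".."fs4", possibly a
    comma-joined pair for features shared between sets) or ``None`` when
    unannotated.  ``block`` is the single generator block the feature belongs
    to (first annotated set; unannotated soma-shape features default to the
    soma block).  ``base`` and ``sigma`` parameterize the generator on the
    latent (log or logit) scale; ``bounds`` applies to the bounded family.
    """

    name: str
    compartment: str  # "soma" | "process"
    units: str
    distributed: bool
    feature_set: Optional[str]
    block: str
    family: str
    base: float
    sigma: float = 0.25
    bounds: tuple[float, float] = (0.0, 1.0)

    @property
    def in_default_catalog(self) -> bool:
        return self.feature_set is not None


def _ln(name, compartment, units, distributed, fs, block, base, sigma=0.25):
    return FeatureDef(name, compartment, units, distributed, fs, block, LOGNORMAL, base, sigma)


def _ct(name, compartment, distributed, fs, block, base, sigma=0.25):
    return FeatureDef(name, compartment, "count", distributed, fs, block, COUNT, base, sigma)


def _bd(name, compartment, units, distributed, fs, block, base, lo, hi, sigma=0.5):
    return FeatureDef(name, compartment, units, distributed, fs, block, BOUNDED, base, sigma, (lo, hi))


# The 28 base features: 16 scalar (11 soma + 5 whole-filament) and 12
# distributed per-process features.  Latent ``base`` values are log means
# (lognormal/count) or logits (bounded family), chosen to give realistic
# magnitudes for spinal-cord microglia reconstructions.
FEATURE_CATALOG: tuple[FeatureDef, ...] = (
    # --- soma scalars -----------------------------------------------------
    _ln("Soma area", "soma", "um^2", False, "fs2", "fs2", 5.0),
    _ln("Soma ellipsoid length A", "soma", "um", False, "fs2", "fs2", 2.3, 0.2),
    _ln("Soma ellipsoid length B", "soma", "um", False, "fs2", "fs2", 2.0, 0.2),
    _ln("Soma ellipsoid length C", "soma", "um", False, "fs2", "fs2", 1.7, 0.2),
    _bd("Ellipticity oblate", "soma", "NA", False, None, "fs2", -0.4, 0.0, 1.0),
    _bd("Ellipticity prolate", "soma", "NA", False, "fs2", "fs2", 0.0, 0.0, 1.0),
    _ct("Number triangles", "soma", False, "fs2", "fs2", 7.0),
    _ct("Number vertices", "soma", False, "fs2", "fs2", 6.3),
    _ct("Number voxels", "soma", False, "fs2", "fs2", 8.0),
    _bd("Soma sphericity", "soma", "NA", False, None, "fs2", 1.4, 0.0, 1.0),
    _ln("Soma volume", "soma", "um^3", False, "fs2", "fs2", 5.5),
    # --- whole-filament scalars ------------------------------------------
    _ct("Process branches", "process", False, "fs1", "fs1a", 3.2),
    _ct("Process segments", "process", False, "fs1", "fs1a", 3.9),
    _ct("Process terminals", "process", False, "fs1", "fs1a", 3.3),
    _ct("Filament edges", "process", False, "fs1", "fs1a", 6.4),
    _ln("Filament volume", "process", "um^3", False, "fs1", "fs1a", 6.0),
    # --- distributed per-process features ---------------------------------
    _ln("Process area", "process", "um^2", True, "fs4", "fs4a", 3.4, 0.2),
    _ct("Branch depth", "process", True, "fs1", "fs1b", 1.6, 0.2),
    _ln("Branch level", "process", "NA", True, "fs1", "fs1b", 1.4, 0.2),
    _bd("Branch angle", "process", "degrees", True, "fs3", "fs3", -0.2, 0.0, 180.0),
    _bd("Branch angle B", "process", "degrees", True, "fs3", "fs3", -0.7, 0.0, 180.0),
    _ln("Process length", "process", "um", True, "fs4", "fs4b", 2.7, 0.2),
    _ln("Process diameter", "process", "um", True, "fs3", "fs3", -0.3, 0.15),
    _bd("Process orientation angle", "process", "degrees", True, "fs3,fs4", "fs3", -0.5, 0.0, 90.0),
    _ln("Process position", "process", "um", True, "fs1,fs4", "fs1b", 3.0, 0.2),
    _ln("Process resistance", "process", "um^-1", True, "fs4", "fs4b", 3.3, 0.2),
    _bd("Process straightness", "process", "NA", True, "fs3,fs4", "fs3", 1.5, 0.0, 1.0),
    _ln("Process volume", "process", "um^3", True, "fs4", "fs4a", 2.1, 0.2),
)

_BY_NAME = {f.name: f for f in FEATURE_CATALOG}


def get_feature(name: str) -> FeatureDef:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown morphological feature: {name!r}") from None


def default_catalog() -> list[FeatureDef]:
    """Features entering the analysis matrix (annotated features only)."""
    return [f for f in FEATURE_CATALOG if f.in_default_catalog]


def generator_catalog() -> list[FeatureDef]:
    """All base features the synthetic generator emits."""
    return list(FEATURE_CATALOG)


def scalar_features(catalog=None) -> list[FeatureDef]:
    cat = FEATURE_CATALOG if catalog is None else catalog
    return [f for f in cat if not f.distributed]


def distributed_features(catalog=None) -> list[FeatureDef]:
    cat = FEATURE_CATALOG if catalog is None else catalog
    return [f for f in cat if f.distributed]
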