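"""Seed-reproducible synthetic morphometry and qPCR data.

The generator emulates a two-genotype (wild-type vs. IL-10 knockout) LPS
challenge study: mice are sampled at 0, 1, 3 and 5 days post-injection and
every reconstructed microglia yields the scalar and per-process distributed
features of :mod:`gliamorph.catalog`.  The statistical structure the
downstream analyses rely on is planted explicitly:

* features are generated on a latent log/logit scale, giving the long-tailed
  lognormal-like marginals seen in real morphometry exports;
* each cell carries one of six latent morphological states defined by
  intensity profiles over six feature sub-blocks nested in the four feature
  sets (fs1 ramification, fs2 soma size/shape, fs3 process shape, fs4 process
  size); knockout animals are enriched for the large-soma state;
* LPS perturbs each block with a genotype-specific deflection-over-time curve
  whose recovery by day 5 is more complete in the knockout for the fs2 and
  fs3 blocks — the effect the adaptation analysis is designed to detect;
* small mouse-level random effects nest cells within animals.

All randomness flows from a single integer seed; identical seeds give
byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import (
    COUNT,
    LOGNORMAL,
    SUBBLOCK_SET,
    SUBBLOCKS,
    FeatureDef,
    generator_catalog,
)

__all__ = [
    "StudyDesign",
    "EffectProfile",
    "MorphologyGeneratorConfig",
    "CellRecord",
    "QpcrTemplate",
    "generate_cells",
    "generate_qpcr",
    "default_design",
    "default_config",
    "block_structured_config",
    "null_config",
    "default_qpcr_templates",
    "write_cells_csv",
    "write_processes_csv",
    "write_qpcr_csv",
    "write_data_dictionary",
    "cells_to_frames",
]

GENOTYPES = ("WT", "KO")
TIMEPOINTS = (0.0, 1.0, 3.0, 5.0)
FEATURE_SETS = ("fs1", "fs2", "fs3", "fs4")


class ConfigurationError(ValueError):
    """Raised when a study design or generator configuration is inconsistent."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the inflammation time course.

    ``n_mice`` maps genotype to the number of animals per time point; the
    default (4 wild-type, 3 knockout per time point) gives 28 mice, and the
    default ``total_cells`` of 218 is allocated across them round-robin.  Set
    ``total_cells`` to ``None`` to instead draw per-mouse cell counts
    uniformly from ``cells_per_mouse``.
    """

    genotypes: tuple[str, ...] = GENOTYPES
    timepoints_days: tuple[float, ...] = TIMEPOINTS
    n_mice: Mapping[str, int] = field(default_factory=lambda: {"WT": 4, "KO": 3})
    total_cells: Optional[int] = 218
    cells_per_mouse: tuple[int, int] = (5, 12)
    seed: int = 0

    def __post_init__(self):
        tp = tuple(float(t) for t in self.timepoints_days)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if len(tp) < 2:
            raise ConfigurationError("need at least two timepoints")
        for g in self.genotypes:
            if self.n_mice.get(g, 0) < 1:
                raise ConfigurationError(f"n_mice missing or < 1 for genotype {g!r}")
        if self.total_cells is not None and self.total_cells < 1:
            raise ConfigurationError("total_cells must be positive")

    @property
    def mouse_count(self) -> int:
        return len(self.timepoints_days) * sum(self.n_mice[g] for g in self.genotypes)


@dataclass(frozen=True)
class EffectProfile:
    """Deflection-over-time curve for one feature block in one genotype.

    The deflection is 0 at baseline, ramps linearly to ``amplitude`` (latent
    log/logit units) at ``peak_day`` and relaxes linearly so that the final
    time point retains ``amplitude * (1 - recovery)``.
    """

    peak_day: float = 1.0
    amplitude: float = 0.0
    recovery: float = 1.0

    def deflection(self, t: float, t0: float, t_final: float) -> float:
        if t <= t0 or self.amplitude == 0.0:
            return 0.0
        if t <= self.peak_day:
            return self.amplitude * (t - t0) / (self.peak_day - t0)
        if t >= t_final:
            return self.amplitude * (1.0 - self.recovery)
        frac = (t - self.peak_day) / (t_final - self.peak_day)
        return self.amplitude * (1.0 - self.recovery * frac)


def _default_effects() -> dict[str, dict[str, EffectProfile]]:
    # fs1 ramification retracts after LPS; fs2 soma size peaks late in WT but
    # early (and recovers almost fully) in the knockout; fs3 recovery is also
    # more complete in the knockout; fs4 shows a modest shared response.
    # Amplitudes are latent (log/logit) units.
    return {
        "fs1": {
            "WT": EffectProfile(1.0, -0.9, 0.6),
            "KO": EffectProfile(1.0, -0.6, 0.9),
        },
        "fs2": {
            "WT": EffectProfile(3.0, 0.8, 0.5),
            "KO": EffectProfile(1.0, 1.2, 0.95),
        },
        "fs3": {
            "WT": EffectProfile(1.0, 1.1, 0.6),
            "KO": EffectProfile(1.0, 0.7, 0.95),
        },
        "fs4": {
            "WT": EffectProfile(1.0, 0.6, 0.55),
            "KO": EffectProfile(1.0, 0.45, 0.8),
        },
    }


# Latent-state intensity over the six sub-blocks (fs1a, fs1b, fs2, fs3,
# fs4a, fs4b), one row per state c1..c6.  Each state peaks on its own
# sub-block, so the six centroids are distinct directions in feature space:
# c1 ramified (filament counts dominant), c2 large-soma, c3 complex process
# shape, c4 thick processes (area/volume), c5 deep arbors (depth/position
# dominant), c6 long processes (length/resistance dominant).  States sharing
# a feature set (c1/c5, c4/c6) stay correlated so basis rows still group into
# the four sets.
_STATE_AMP = 2.2
_STATE_PROFILES = _STATE_AMP * np.array(
    [
        # fs1a  fs1b  fs2   fs3   fs4a  fs4b
        [1.0,  0.5,  0.0,  0.0,  0.0,  0.0],   # c1
        [0.0,  0.0,  1.0,  0.0,  0.0,  0.0],   # c2
        [0.0,  0.0,  0.0,  1.0,  0.0,  0.0],   # c3
        [0.0,  0.0,  0.0,  0.0,  1.0,  0.5],   # c4
        [0.5,  1.0,  0.0,  0.0,  0.0,  0.0],   # c5
        [0.0,  0.0,  0.0,  0.0,  0.5,  1.0],   # c6
    ]
)

_STATE_FREQS = {
    # The large-soma state c2 is enriched in the knockout.
    "WT": (0.26, 0.07, 0.17, 0.15, 0.13, 0.22),
    "KO": (0.18, 0.22, 0.15, 0.14, 0.13, 0.18),
}


def _default_state_weight_effects() -> dict[int, dict[str, EffectProfile]]:
    """LPS shifts the state composition, not just per-feature levels.

    Log-weight deflections applied to the baseline state frequencies: after
    LPS the ramified state c1 is depleted, the activated large-soma state c2
    is enriched (earlier and with fuller recovery in the knockout, echoing
    the per-feature fs2 kinetics) and the process-shape state c3 is enriched
    transiently.  Keys are 0-based state indices.
    """
    return {
        0: {"WT": EffectProfile(1.0, -0.8, 0.6), "KO": EffectProfile(1.0, -0.8, 0.9)},
        1: {"WT": EffectProfile(3.0, 1.0, 0.4), "KO": EffectProfile(1.0, 1.4, 0.95)},
        2: {"WT": EffectProfile(1.0, 0.8, 0.55), "KO": EffectProfile(1.0, 0.8, 0.95)},
    }


@dataclass(frozen=True)
class MorphologyGeneratorConfig:
    """Parameters of the latent-state morphology generator."""

    catalog: tuple[FeatureDef, ...] = field(default_factory=lambda: tuple(generator_catalog()))
    n_states: int = 6
    state_block_profiles: np.ndarray = field(default_factory=lambda: _STATE_PROFILES.copy())
    state_frequencies: Mapping[str, Sequence[float]] = field(default_factory=lambda: dict(_STATE_FREQS))
    effect_profiles: Mapping[str, Mapping[str, EffectProfile]] = field(default_factory=_default_effects)
    block_feature_map: Optional[Mapping[str, str]] = None  # feature name -> block
    state_weight_effects: Mapping[int, Mapping[str, EffectProfile]] = field(
        default_factory=_default_state_weight_effects
    )
    processes_per_cell: tuple[int, int] = (5, 60)
    sigma_process: float = 0.35
    dispersion_coupling: float = 0.15
    sigma_mouse: float = 0.08

    def resolved_block_map(self) -> dict[str, str]:
        if self.block_feature_map is not None:
            bmap = dict(self.block_feature_map)
        else:
            bmap = {f.name: f.block for f in self.catalog}
        names = [f.name for f in self.catalog]
        missing = [n for n in names if n not in bmap]
        extra = [n for n in bmap if n not in names]
        if missing:
            raise ConfigurationError(f"features unassigned to a block: {missing}")
        if extra:
            raise ConfigurationError(f"block map names unknown features: {extra}")
        bad = [n for n, b in bmap.items() if b not in SUBBLOCKS]
        if bad:
            raise ConfigurationError(f"unknown block label for features: {bad}")
        return bmap

    def validate(self) -> None:
        profiles = np.asarray(self.state_block_profiles, dtype=float)
        if profiles.shape != (self.n_states, len(SUBBLOCKS)):
            raise ConfigurationError(
                f"state_block_profiles must be {self.n_states}x{len(SUBBLOCKS)}"
            )
        for g, freqs in self.state_frequencies.items():
            fr = np.asarray(freqs, dtype=float)
            if fr.shape != (self.n_states,) or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
                raise ConfigurationError(f"state frequencies for {g!r} must be a length-{self.n_states} simplex")
        for s_idx in self.state_weight_effects:
            if not (0 <= s_idx < self.n_states):
                raise ConfigurationError(f"state_weight_effects key {s_idx} out of range")
        lo, hi = self.processes_per_cell
        if not (1 <= lo <= hi):
            raise ConfigurationError("processes_per_cell range invalid")
        if self.sigma_process <= 0 or self.sigma_mouse < 0:
            raise ConfigurationError("noise scales must be positive")
        self.resolved_block_map()
        # The planted contrast the pipeline must recover: knockout recovery is
        # at least as complete as wild-type for the fs2 and fs3 blocks.
        for block in ("fs2", "fs3"):
            eff = self.effect_profiles.get(block, {})
            wt, ko = eff.get("WT"), eff.get("KO")
            if wt is not None and ko is not None and wt.amplitude != 0 and ko.recovery < wt.recovery:
                raise ConfigurationError(
                    f"knockout recovery must be >= wild-type for block {block}"
                )


@dataclass
class CellRecord:
    """All measurements of one reconstructed microglia."""

    cell_id: str
    mouse_id: str
    genotype: str
    time_days: float
    scalar_features: dict[str, float]
    distributed_features: dict[str, np.ndarray]
    latent_state: int = -1  # generator ground truth (1-based state index)
    n_processes: int = 0

    def __post_init__(self):
        lengths = {len(v) for v in self.distributed_features.values()}
        if self.distributed_features:
            if len(lengths) != 1:
                raise ValueError(f"inconsistent distributed vector lengths in {self.cell_id}")
            (n,) = lengths
            if n < 1:
                raise ValueError(f"empty distributed vectors in {self.cell_id}")
            if self.n_processes == 0:
                self.n_processes = n

    @property
    def is_degenerate(self) -> bool:
        """True for single-process cells (spread statistics are conventions)."""
        return self.n_processes <= 1


def default_design(seed: int = 0) -> StudyDesign:
    return StudyDesign(seed=seed)


def default_config() -> MorphologyGeneratorConfig:
    return MorphologyGeneratorConfig()


def block_structured_config() -> MorphologyGeneratorConfig:
    """Four-block configuration: four pure states, one per feature set.

    Both sub-blocks of a set carry identical intensity, so the planted
    structure has exactly four blocks (fs1-fs4) and four cell states.  This
    configuration exists to validate feature-set recovery: clustering the
    rows of the NMF basis fitted to such data must recover the four sets.
    (The default six-state design instead optimizes cell-state
    identifiability; its basis resolves the six sub-blocks.)
    """
    profiles = 3.0 * np.array(
        [
            # fs1a fs1b  fs2   fs3   fs4a  fs4b
            [1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0, 1.0],
        ]
    )
    freqs = {"WT": (0.28, 0.22, 0.26, 0.24), "KO": (0.22, 0.30, 0.24, 0.24)}
    effects = {
        b: {g: EffectProfile(p.peak_day, 0.0, p.recovery) for g, p in gd.items()}
        for b, gd in _default_effects().items()
    }
    return MorphologyGeneratorConfig(
        n_states=4, state_block_profiles=profiles, state_frequencies=freqs,
        effect_profiles=effects, state_weight_effects={},
        dispersion_coupling=0.25,
    )


def null_config() -> MorphologyGeneratorConfig:
    """Generator with every LPS effect amplitude set to zero (type-I checks).

    State frequencies stay genotype-specific but constant in time, so feature
    temporal profiles are flat up to sampling noise in both genotypes.
    """
    effects = {
        b: {g: EffectProfile(p.peak_day, 0.0, p.recovery) for g, p in gd.items()}
        for b, gd in _default_effects().items()
    }
    return MorphologyGeneratorConfig(effect_profiles=effects, state_weight_effects={})


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _allocate_cells(design: StudyDesign, rng: np.random.Generator, n_mice_total: int) -> list[int]:
    if design.total_cells is not None:
        base, rem = divmod(design.total_cells, n_mice_total)
        if base < 1:
            raise ConfigurationError("fewer cells than mice")
        return [base + (1 if i < rem else 0) for i in range(n_mice_total)]
    lo, hi = design.cells_per_mouse
    return list(rng.integers(lo, hi + 1, size=n_mice_total))


def generate_cells(
    design: StudyDesign, config: Optional[MorphologyGeneratorConfig] = None
) -> list[CellRecord]:
    """Sample one synthetic study's worth of reconstructed microglia."""
    config = config or default_config()
    config.validate()
    bmap = config.resolved_block_map()
    block_idx = {b: i for i, b in enumerate(SUBBLOCKS)}
    rng = np.random.default_rng(design.seed)
    t0, t_final = design.timepoints_days[0], design.timepoints_days[-1]
    profiles = np.asarray(config.state_block_profiles, dtype=float)

    # Enumerate mice in a fixed order: genotype, then time, then replicate.
    mice = []
    for genotype in design.genotypes:
        for t in design.timepoints_days:
            for rep in range(design.n_mice[genotype]):
                mice.append((genotype, float(t)))
    counts = _allocate_cells(design, rng, len(mice))

    cells: list[CellRecord] = []
    cell_no = 0
    for mouse_no, ((genotype, t), n_cells) in enumerate(zip(mice, counts), start=1):
        mouse_id = f"m{mouse_no:02d}"
        mouse_effect = rng.normal(0.0, config.sigma_mouse, size=len(SUBBLOCKS))
        deflect = np.array(
            [
                config.effect_profiles[fs][genotype].deflection(t, t0, t_final)
                if fs in config.effect_profiles and genotype in config.effect_profiles[fs]
                else 0.0
                for fs in (SUBBLOCK_SET[sb] for sb in SUBBLOCKS)
            ]
        )
        base_w = np.asarray(config.state_frequencies[genotype], dtype=float)
        logw = np.zeros_like(base_w)
        for s_idx, per_gt in config.state_weight_effects.items():
            if genotype in per_gt:
                logw[s_idx] = per_gt[genotype].deflection(t, t0, t_final)
        freqs = base_w * np.exp(logw)
        freqs = freqs / freqs.sum()
        for _ in range(n_cells):
            cell_no += 1
            state = int(rng.choice(config.n_states, p=freqs))
            shift = profiles[state] + deflect + mouse_effect
            lo_p, hi_p = config.processes_per_cell
            n_proc = max(int(rng.integers(lo_p, hi_p + 1)), 1)
            scalars: dict[str, float] = {}
            dists: dict[str, np.ndarray] = {}
            for f in config.catalog:
                latent = f.base + shift[block_idx[bmap[f.name]]]
                if not f.distributed:
                    z = latent + rng.normal(0.0, f.sigma)
                    if f.family == LOGNORMAL:
                        scalars[f.name] = float(np.exp(z))
                    elif f.family == COUNT:
                        scalars[f.name] = float(rng.poisson(np.exp(z)))
                    else:
                        lo, hi = f.bounds
                        scalars[f.name] = float(lo + (hi - lo) * _sigmoid(z))
                else:
                    mu = latent + rng.normal(0.0, f.sigma)
                    # LPS and high-intensity states visibly widen the
                    # per-process distributions, so the within-cell spread
                    # scales with the latent deflection.
                    sigma_p = config.sigma_process * float(
                        np.exp(config.dispersion_coupling
                               * shift[block_idx[bmap[f.name]]])
                    )
                    draws = rng.normal(mu, sigma_p, size=n_proc)
                    if f.family == LOGNORMAL:
                        vals = np.exp(draws)
                    elif f.family == COUNT:
                        vals = rng.poisson(np.exp(draws)).astype(float)
                    else:
                        lo, hi = f.bounds
                        vals = lo + (hi - lo) * _sigmoid(draws)
                    dists[f.name] = vals
            cells.append(
                CellRecord(
                    cell_id=f"c{cell_no:04d}",
                    mouse_id=mouse_id,
                    genotype=genotype,
                    time_days=t,
                    scalar_features=scalars,
                    distributed_features=dists,
                    latent_state=state + 1,
                    n_processes=n_proc,
                )
            )
    return cells


# ---------------------------------------------------------------------------
# qPCR fold-change tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrTemplate:
    """Per-gene kinetic template: target fold changes per genotype and time."""

    gene: str
    fold: Mapping[str, Sequence[float]]  # genotype -> fold change per timepoint


def default_qpcr_templates() -> list[QpcrTemplate]:
    """Peak-and-recovery templates for the four assayed cytokine genes.

    Tnf and Il6 peak a day after LPS and recover quickly (the knockout peak is
    larger for Tnf), Il1b decays rapidly after an early rise, and Tgfb1 shows
    sustained partial recovery.
    """
    return [
        QpcrTemplate("Tnf", {"WT": (1.0, 6.0, 1.3, 1.0), "KO": (1.0, 12.0, 1.2, 1.0)}),
        QpcrTemplate("Il6", {"WT": (1.0, 5.0, 1.2, 1.0), "KO": (1.0, 7.0, 1.2, 1.0)}),
        QpcrTemplate("Il1b", {"WT": (1.0, 4.0, 1.6, 1.1), "KO": (1.0, 5.0, 1.5, 1.1)}),
        QpcrTemplate("Tgfb1", {"WT": (1.0, 2.6, 2.2, 1.8), "KO": (1.0, 2.4, 2.0, 1.7)}),
    ]


def generate_qpcr(
    design: StudyDesign,
    templates: Optional[Sequence[QpcrTemplate]] = None,
    ct_noise_sd: float = 0.12,
    reference_ct: float = 20.0,
    baseline_target_ct: float = 24.0,
) -> "pd.DataFrame":
    """Emit per-mouse Ct values whose 2^-ddCt fold changes match the templates.

    The reference gene (a housekeeping control) is held at ``reference_ct``
    with small technical noise; the target Ct is offset by -log2(fold) so that
    inverting the 2^-ddCt mapping recovers the template curve within noise.
    """
    import pandas as pd

    templates = list(templates) if templates is not None else default_qpcr_templates()
    rng = np.random.default_rng(design.seed + 104729)  # independent stream
    rows = []
    for tmpl in templates:
        for genotype in design.genotypes:
            folds = np.asarray(tmpl.fold[genotype], dtype=float)
            if folds.shape != (len(design.timepoints_days),):
                raise ConfigurationError(
                    f"template {tmpl.gene}/{genotype} must give one fold per timepoint"
                )
            for t, fold in zip(design.timepoints_days, folds):
                for rep in range(design.n_mice[genotype]):
                    ct_ref = reference_ct + rng.normal(0.0, ct_noise_sd)
                    ct_tgt = (
                        baseline_target_ct
                        - np.log2(fold)
                        + rng.normal(0.0, ct_noise_sd)
                    )
                    rows.append(
                        {
                            "gene": tmpl.gene,
                            "genotype": genotype,
                            "time_days": float(t),
                            "replicate": rep + 1,
                            "Ct_target": round(float(ct_tgt), 4),
                            "Ct_reference": round(float(ct_ref), 4),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def cells_to_frames(cells: Sequence[CellRecord]):
    """Return (cells, processes) DataFrames: wide scalars + long distributed."""
    import pandas as pd

    scalar_names = sorted(cells[0].scalar_features) if cells else []
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "mouse_id": c.mouse_id,
            "genotype": c.genotype,
            "time_days": c.time_days,
            "latent_state": c.latent_state,
            "n_processes": c.n_processes,
        }
        row.update({n: c.scalar_features[n] for n in scalar_names})
        rows.append(row)
    cells_df = pd.DataFrame(rows)

    long_rows = []
    for c in cells:
        for name in sorted(c.distributed_features):
            for v in c.distributed_features[name]:
                long_rows.append((c.cell_id, name, float(v)))
    proc_df = pd.DataFrame(long_rows, columns=["cell_id", "feature", "value"])
    return cells_df, proc_df


def _write_df(df, path: Path, header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def write_cells_csv(cells, path, header_lines=()):
    cells_df, _ = cells_to_frames(cells)
    _write_df(cells_df, path, header_lines)


def write_processes_csv(cells, path, header_lines=()):
    _, proc_df = cells_to_frames(cells)
    _write_df(proc_df, path, header_lines)


def write_qpcr_csv(qpcr_df, path, header_lines=()):
    _write_df(qpcr_df, path, header_lines)


def write_data_dictionary(path, catalog=None):
    """Write the column/feature dictionary for the emitted CSV files."""
    import pandas as pd

    cat = catalog or generator_catalog()
    rows = [
        {
            "feature": f.name,
            "compartment": f.compartment,
            "units": f.units,
            "distributed": "yes" if f.distributed else "no",
            "feature_set": f.feature_set or "unassigned",
            "family": f.family,
        }
        for f in cat
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
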