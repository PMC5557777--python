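"""Pipeline orchestration, configuration and file I/O.

``run_pipeline`` chains the full analysis — synthetic data generation,
feature-matrix assembly, time-course testing, PCA-based feature selection,
offset-NMF clustering with NMDS validation, adaptation analysis, and the
cytokine network simulation — writing every stage's tables as TSV/CSV files
with provenance headers (seed, package version, configuration hash).  Reruns
with an identical configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import adaptation_table, featureset_dynamics
from .cytokines import (
    StimulusSpec,
    default_network,
    dose_response,
    knockout,
    simulate,
)
from .features import build_feature_matrix, select_features, shift_nonnegative, zscore
from .multivariate import (
    assign_feature_sets,
    cluster_enrichment,
    nmds,
    nmf,
    pca,
    spearman_distance,
)
from .odp import odp_test
from .synthetic import (
    StudyDesign,
    default_config,
    generate_cells,
    generate_qpcr,
    write_cells_csv,
    write_data_dictionary,
    write_processes_csv,
    write_qpcr_csv,
)

__all__ = ["PipelineConfig", "fold_change", "run_pipeline", "read_table"]

log = logging.getLogger("gliamorph")

STAGES = ("generate", "features", "odp", "nmf", "mds", "adaptation", "simulate")


def fold_change(
    ct_target: float,
    ct_reference: float,
    ct_target_baseline: float,
    ct_reference_baseline: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) - (Ct_target_baseline -
    Ct_reference_baseline); the fold change is 2 to the power -ddCt.
    """
    ddct = (ct_target - ct_reference) - (ct_target_baseline - ct_reference_baseline)
    return float(2.0 ** (-ddct))


def qpcr_fold_changes(qpcr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-genotype mean fold-change curves from a Ct table."""
    rows = []
    for (gene, gt), grp in qpcr.groupby(["gene", "genotype"]):
        t0 = grp["time_days"].min()
        base = grp[grp["time_days"] == t0]
        ct_t0 = base["Ct_target"].mean()
        ct_ref0 = base["Ct_reference"].mean()
        for t, sub in grp.groupby("time_days"):
            folds = [
                fold_change(r.Ct_target, r.Ct_reference, ct_t0, ct_ref0)
                for r in sub.itertuples()
            ]
            rows.append(
                {"gene": gene, "genotype": gt, "time_days": float(t),
                 "fold_change": float(np.mean(folds))}
            )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis."""

    seed: int = 0
    outdir: str = "results"
    n_boot: int = 500
    spline_df: int = 3
    fdr_method: str = "storey"
    odp_alpha: float = 0.05
    loading_cutoff: float = 0.2
    nmf_rank: int = 6
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-7
    mds_dims: int = 3
    mds_restarts: int = 4
    sem_mode: str = "sd_over_n"
    adaptation_min: float = 0.5
    adaptation_lower: float = -0.2
    adaptation_upper: float = 1.2
    doses: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
    sim_t_end: float = 120.0
    stim_duration: float = 16.0
    null_effects: bool = False

    def __post_init__(self):
        if not (0 < self.odp_alpha < 1):
            raise ValueError("odp_alpha must lie in (0, 1)")
        if self.loading_cutoff < 0:
            raise ValueError("loading_cutoff must be non-negative")
        if self.nmf_rank < 1:
            raise ValueError("nmf_rank must be positive")
        if not (self.adaptation_lower < self.adaptation_min < self.adaptation_upper):
            raise ValueError("adaptation thresholds out of order")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "doses" in raw:
            raw["doses"] = tuple(raw["doses"])
        return cls(**raw)

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d.pop("outdir")  # where results land is not part of what they are
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"gliamorph {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.config_hash()}",
    ]


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, index=True, sep="\t"):
    with open(path, "w", newline="") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=index, float_format="%.8g")
    log.info("wrote %s", path)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read back any table written by the pipeline (skips provenance lines)."""
    return pd.read_csv(path, sep=None, engine="python", comment="#", **kwargs)


def run_pipeline(config: PipelineConfig, stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the analysis end to end and write each stage's outputs.

    ``stages`` limits which outputs are written (dependencies are still
    computed in memory).  Returns a dict of the in-memory stage results.
    """
    wanted = set(stages) if stages is not None else set(STAGES)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # computation dependencies: generate -> features -> odp/pca -> nmf ->
    # mds/adaptation; the simulation stage stands alone
    morph = ("features", "odp", "nmf", "mds", "adaptation")
    need_features = bool(wanted & set(morph))
    need_odp = bool(wanted & set(morph[1:]))
    need_nmf = bool(wanted & set(morph[2:]))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    header = _header(config)

    # --- generate ---------------------------------------------------------
    design = StudyDesign(seed=config.seed)
    from .synthetic import null_config

    gen_cfg = null_config() if config.null_effects else default_config()
    cells = generate_cells(design, gen_cfg)
    qpcr = generate_qpcr(design)
    results["cells"], results["qpcr"] = cells, qpcr
    if "generate" in wanted:
        write_cells_csv(cells, out / "cells.csv", header)
        write_processes_csv(cells, out / "processes.csv", header)
        write_qpcr_csv(qpcr, out / "qpcr.csv", header)
        write_data_dictionary(out / "data_dictionary.tsv")
        _write(qpcr_fold_changes(qpcr), out / "qpcr_fold_changes.tsv", config, index=False)

    if not need_features:
        if "simulate" not in wanted:
            return results
        return _simulate_stage(config, out, results, wanted)

    # --- features ----------------------------------------------------------
    fm = build_feature_matrix(cells)
    zfm = zscore(fm)
    results["feature_matrix"], results["zscores"] = fm, zfm
    if "features" in wanted:
        wide = zfm.values.copy()
        stat = zfm.col_meta.set_index("name")["statistic"]
        wide.columns = pd.MultiIndex.from_arrays(
            [wide.columns, [stat[c] for c in wide.columns]], names=["feature", "statistic"]
        )
        with open(out / "feature_matrix.tsv", "w", newline="") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            wide.to_csv(fh, sep="\t", float_format="%.8g")
        _write(zfm.col_meta, out / "feature_dictionary.tsv", config, index=False)

    if not need_odp:
        if "simulate" not in wanted:
            return results
        return _simulate_stage(config, out, results, wanted)

    # --- odp + pca + selection ---------------------------------------------
    odp_res = odp_test(zfm, n_boot=config.n_boot, seed=config.seed,
                       df=config.spline_df, fdr_method=config.fdr_method)
    pca_res = pca(zfm)
    selected = select_features(
        pca_res.loadings, odp_res["p"],
        loading_cutoff=config.loading_cutoff, alpha=config.odp_alpha,
    )
    results["odp"], results["pca"], results["selected"] = odp_res, pca_res, selected
    if "odp" in wanted:
        _write(odp_res, out / "odp_results.tsv", config)
        _write(pca_res.loadings, out / "pca_loadings.tsv", config)
        _write(
            pd.DataFrame({"feature": selected}), out / "selected_features.tsv",
            config, index=False,
        )

    if not need_nmf:
        if "simulate" not in wanted:
            return results
        return _simulate_stage(config, out, results, wanted)

    # --- nmf -----------------------------------------------------------------
    zsel = zfm.subset(selected) if selected else zfm
    D = shift_nonnegative(zsel)
    decomp = nmf(D, rank=config.nmf_rank, seed=config.seed,
                 max_iter=config.nmf_max_iter, tol=config.nmf_tol)
    decomp.feature_sets = assign_feature_sets(decomp.W, decomp.H)
    enrich = cluster_enrichment(
        decomp.cell_clusters, zsel.row_meta["genotype"].to_numpy()
    )
    results["nmf"], results["enrichment"] = decomp, enrich
    if "nmf" in wanted:
        _write(decomp.W, out / "nmf_W.tsv", config)
        _write(decomp.H, out / "nmf_H.tsv", config)
        _write(decomp.cell_clusters.to_frame(), out / "cell_clusters.tsv", config)
        _write(decomp.feature_sets.to_frame(), out / "feature_sets.tsv", config)
        _write(enrich, out / "cluster_enrichment.tsv", config, index=False)

    # --- mds -----------------------------------------------------------------
    if "mds" in wanted:
        dist = spearman_distance(zsel)
        coords, stress = nmds(
            dist, dims=config.mds_dims, seed=config.seed, n_restarts=config.mds_restarts
        )
        results["mds"] = (coords, stress)
        coords_out = coords.copy()
        coords_out["stress"] = stress
        _write(coords_out, out / "mds_coords.tsv", config)

    # --- adaptation ----------------------------------------------------------
    if "adaptation" in wanted:
        indices, comparisons = adaptation_table(zsel, sem_mode=config.sem_mode)
        fs_dyn = featureset_dynamics(zsel, decomp.feature_sets)
        results["adaptation"] = (indices, comparisons)
        results["featureset_dynamics"] = fs_dyn
        _write(indices, out / "adaptation_indices.tsv", config, index=False)
        _write(comparisons, out / "adaptation_comparisons.tsv", config, index=False)
        post = pd.concat(
            {fs: v["posthoc"] for fs, v in fs_dyn.items()}, names=["feature_set"]
        ).reset_index(level=0)
        _write(post, out / "featureset_posthoc.tsv", config, index=False)

    return _simulate_stage(config, out, results, wanted)


def _simulate_stage(config: PipelineConfig, out: Path, results: dict, wanted) -> dict:
    if "simulate" not in wanted:
        return results
    net = default_network()
    stim = StimulusSpec(magnitude=1.0, duration=config.stim_duration)
    traj_wt = simulate(net, stim, t_end=config.sim_t_end, report_dt=0.5)
    traj_ko = simulate(knockout(net, "IL10"), stim, t_end=config.sim_t_end, report_dt=0.5)
    dr = dose_response(net, config.doses, t_end=config.sim_t_end,
                       duration=config.stim_duration)
    results["trajectories"] = {"wt": traj_wt, "ko": traj_ko}
    results["dose_response"] = dr
    _write(traj_wt.data, out / "trajectory_wt.tsv", config)
    _write(traj_ko.data, out / "trajectory_ko.tsv", config)
    _write(dr, out / "dose_response.tsv", config, index=False)
    return results
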