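"""Configuration-driven orchestration of the full SCN analysis.

A single config (YAML file or :class:`PipelineConfig`) names either input
CSVs (GMV table + covariates) or a synthetic cohort spec, and the run
produces, per group: the covariance network, binary graphs over the
density grid, global metric curves with AUCs, small-world indices, nodal
metrics, hubs, a truncated power-law degree-distribution fit, and
random/targeted robustness curves — plus pairwise permutation contrasts
and pairwise log-rank degree comparisons, all written as CSV/JSON with a
machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attack import random_failure, targeted_attack
from .cohort import CovariateTable, GMVTable, assign_groups_by_psqi
from .degreestruct import (DegreeDistributionFit, HubSet,
                           fit_truncated_powerlaw, grid_averaged_degrees,
                           identify_hubs, pairwise_logrank)
from .inference import permutation_test
from .metrics import (GLOBAL_STATISTICS, MetricCurve, NodalMetrics,
                      compute_nodal_metrics, degrees, metric_curve,
                      small_world)
from .netbuild import (correlation_network, residualize, sparsity_grid,
                       threshold_over_grid)
from .syndata import SyntheticSpec, generate_cohort

log = logging.getLogger("scnkit")


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the standard protocol
    (16-density grid, 1000 permutations, 1000 attack simulations)."""

    gmv_csv: str | None = None
    covariate_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    group_column: str = "group"
    psqi_column: str | None = None
    psqi_cutoff: float = 5.0
    sparsity_lo: float = 0.19
    sparsity_hi: float = 0.49
    sparsity_step: float = 0.02
    ranking: str = "signed"
    n_perm: int = 1000
    n_null: int = 100
    n_sim: int = 1000
    degree_fit_density: float = 0.33
    compare_metrics: tuple[str, ...] = (
        "clustering", "transitivity", "path_length",
        "global_efficiency", "local_efficiency")
    seed: int = 0
    out_dir: str = "scn_results"

    def __post_init__(self) -> None:
        if self.gmv_csv is None and self.synthetic is None:
            raise ValueError("config needs input CSVs or a synthetic spec")
        for name in ("n_perm", "n_null", "n_sim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def grid(self):
        return sparsity_grid(self.sparsity_lo, self.sparsity_hi,
                             self.sparsity_step)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in ("module_sizes", "group_names", "covariate_betas"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "group_effects" in syn and syn["group_effects"] is not None:
                syn["group_effects"] = tuple(
                    tuple(e) for e in syn["group_effects"])
            raw["synthetic"] = SyntheticSpec(**syn)
        if "compare_metrics" in raw:
            raw["compare_metrics"] = tuple(raw["compare_metrics"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_cohort(config: PipelineConfig) -> tuple[GMVTable, CovariateTable]:
    """Load (or simulate) the cohort and attach group labels.

    When ``psqi_column`` is set, group labels come from the sleep-quality
    rule (score > cutoff → sleep-disorder group) applied to that column
    of the covariate CSV; otherwise the GMV CSV's group column is used.
    """
    if config.synthetic is not None:
        return generate_cohort(config.synthetic, seed=config.seed)
    gmv_df = pd.read_csv(config.gmv_csv, index_col="subject_id")
    cov_df = pd.read_csv(config.covariate_csv, index_col="subject_id")
    if gmv_df.index.duplicated().any():
        raise ValueError("duplicated subject id in GMV table")
    groups = None
    if config.psqi_column is not None:
        if config.psqi_column not in cov_df.columns:
            raise ValueError(f"missing PSQI column {config.psqi_column!r}")
        cov_df = cov_df.reindex(gmv_df.index)
        groups = assign_groups_by_psqi(
            cov_df[config.psqi_column].to_numpy(float), config.psqi_cutoff)
    elif config.group_column in gmv_df.columns:
        groups = tuple(gmv_df.pop(config.group_column).astype(str))
    for col in gmv_df.columns:
        bad = pd.to_numeric(gmv_df[col], errors="coerce").isna()
        if bad.any():
            row = gmv_df.index[bad][0]
            raise ValueError(f"non-numeric cell at row {row!r}, "
                             f"column {col!r}")
    gmv = GMVTable(gmv_df.to_numpy(float), tuple(map(str, gmv_df.index)),
                   tuple(gmv_df.columns), groups)
    cov_df = cov_df.reindex(list(gmv.subject_ids))
    cov = CovariateTable(gmv.subject_ids, cov_df["age"].to_numpy(float),
                         cov_df["sex"].to_numpy(float),
                         cov_df["tiv"].to_numpy(float))
    return gmv, cov


def export_brainnet(nodal: NodalMetrics, hubs: HubSet, out_prefix,
                    adjacency=None, coords=None) -> list[Path]:
    """Write BrainNet Viewer .node (and optionally .edge) files.

    .node: six whitespace-separated columns x, y, z, color code (2 for
    hubs, 1 otherwise), size (degree), label. Missing coordinates become
    zeros with a warning. .edge: the N×N adjacency matrix.
    """
    out_prefix = Path(out_prefix)
    n = len(nodal.region_labels)
    if coords is None:
        warnings.warn("no region coordinates supplied; writing zeros",
                      stacklevel=2)
        coords = np.zeros((n, 3))
    coords = np.asarray(coords, dtype=float)
    hub_set = set(hubs.hub_regions)
    lines = []
    for i, label in enumerate(nodal.region_labels):
        color = 2 if label in hub_set else 1
        x, y, z = coords[i]
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t{color}\t"
                     f"{nodal.degree[i]:g}\t{label}")
    node_path = out_prefix.with_suffix(".node")
    node_path.write_text("\n".join(lines) + "\n")
    written = [node_path]
    if adjacency is not None:
        edge_path = out_prefix.with_suffix(".edge")
        np.savetxt(edge_path, np.asarray(adjacency, dtype=int),
                   fmt="%d", delimiter="\t")
        written.append(edge_path)
    return written


def _fit_to_dict(fit: DegreeDistributionFit) -> dict:
    return {"k": fit.k, "dc": fit.dc, "scale": fit.scale, "r2": fit.r2,
            "success": fit.success, "form": fit.form,
            "fitted_support": list(fit.fitted_support)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every group and pairwise contrast.

    Writes all outputs under ``config.out_dir`` and returns the manifest
    dict (also saved as ``manifest.json``). Stage failures abort with a
    stage-tagged error after writing a FAILED marker, so partial outputs
    remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {"scnkit_version": __version__, "seed": config.seed,
                      "settings": {
                          "n_perm": config.n_perm, "n_null": config.n_null,
                          "n_sim": config.n_sim, "ranking": config.ranking,
                          "degree_fit_density": config.degree_fit_density},
                      "groups": {}, "contrasts": {}}
    stage = "setup"
    try:
        root = np.random.SeedSequence(config.seed)
        seeds = {name: np.random.default_rng(child) for name, child in
                 zip(("smallworld", "attack", "perm"), root.spawn(3))}
        grid = config.grid()
        xs = grid.as_array()

        stage = "load"
        gmv, cov = load_cohort(config)
        if gmv.group_labels is None:
            raise ValueError("no group labels available")
        log.info("cohort: %d subjects, %d regions, groups %s",
                 gmv.n_subjects, gmv.n_regions, gmv.groups())

        stage = "netbuild"
        # pooled residualization once, consistent with permutation on
        # corrected values
        res_all = residualize(gmv, cov)
        groups = gmv.groups()
        group_graphs: dict[str, list] = {}
        group_res = {}
        degree_samples = {}
        tidy_rows = []
        auc_rows = []
        for gname in groups:
            res_g = res_all.subset(gname)
            group_res[gname] = res_g
            net = correlation_network(res_g, gname)
            net.to_tsv(out / f"network_{gname}.tsv")
            graphs = threshold_over_grid(net, grid, config.ranking)
            group_graphs[gname] = graphs

            stage = f"metrics[{gname}]"
            curves: dict[str, MetricCurve] = {}
            for mname in GLOBAL_STATISTICS:
                curves[mname] = metric_curve(graphs, mname, grid)
            sigma_vals = []
            for g in graphs:
                sw = small_world(g, n_null=config.n_null,
                                 seed=seeds["smallworld"])
                sigma_vals.append(sw.sigma)
            for mname, curve in curves.items():
                for s, v in zip(xs, curve.values):
                    tidy_rows.append((gname, s, mname, v))
                auc_rows.append((gname, mname, curve.auc))
            for s, v in zip(xs, sigma_vals):
                tidy_rows.append((gname, s, "sigma", v))

            stage = f"degreestruct[{gname}]"
            mean_deg = grid_averaged_degrees(
                [g.adjacency for g in graphs])
            hubs = identify_hubs(mean_deg, gmv.region_labels)
            fit_idx = int(np.argmin(np.abs(
                xs - config.degree_fit_density)))
            deg_fit_sample = degrees(graphs[fit_idx])
            degree_samples[gname] = deg_fit_sample
            fit = fit_truncated_powerlaw(np.maximum(deg_fit_sample, 1))
            nodal = compute_nodal_metrics(graphs[fit_idx])
            nodal.to_dataframe().to_csv(out / f"nodal_{gname}.csv")
            pd.DataFrame({"region": hubs.hub_regions,
                          "mean_degree": hubs.hub_degrees}).to_csv(
                out / f"hubs_{gname}.csv", index=False)
            export_brainnet(nodal, hubs, out / f"brainnet_{gname}",
                            adjacency=graphs[fit_idx].adjacency)

            stage = f"attack[{gname}]"
            rob_rows = []
            rob_auc = {}
            for g, s in zip(graphs, xs):
                rand = random_failure(g, n_sim=config.n_sim,
                                      seed=seeds["attack"])
                targ = targeted_attack(g)
                rob_auc[float(s)] = {"random": rand.auc,
                                     "targeted": targ.auc}
                for f, v in zip(rand.fractions_removed,
                                rand.lcc_relative_size):
                    rob_rows.append(("random", s, f, v))
                for f, v in zip(targ.fractions_removed,
                                targ.lcc_relative_size):
                    rob_rows.append(("targeted", s, f, v))
            pd.DataFrame(rob_rows, columns=[
                "attack_type", "density", "fraction_removed",
                "mean_lcc"]).to_csv(out / f"robustness_{gname}.csv",
                                    index=False)

            manifest["groups"][gname] = {
                "n_subjects": res_g.n_subjects,
                "n_densities": len(grid),
                "metric_auc": {m: c.auc for m, c in curves.items()},
                "sigma_min": float(min(sigma_vals)),
                "hubs": list(hubs.hub_regions),
                "hub_threshold": hubs.threshold,
                "degree_fit": _fit_to_dict(fit),
                "robustness_auc": rob_auc,
            }

        pd.DataFrame(tidy_rows, columns=[
            "group", "density", "metric", "value"]).to_csv(
            out / "global_metrics.csv", index=False)
        pd.DataFrame(auc_rows, columns=["group", "metric", "auc"]).to_csv(
            out / "metric_auc.csv", index=False)

        stage = "inference"
        if config.n_perm < 100:
            log.warning("n_perm=%d is low; p-values will be coarse",
                        config.n_perm)
        logrank = pairwise_logrank(degree_samples)
        for (a, b), (stat, p) in logrank.items():
            manifest["contrasts"].setdefault(f"{a}_vs_{b}", {})[
                "logrank_degree"] = {"statistic": stat, "p": p}
        diff_rows = []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                key = f"{a}_vs_{b}"
                entry = manifest["contrasts"].setdefault(key, {})
                for mname in config.compare_metrics:
                    r = permutation_test(
                        group_res[a], group_res[b], mname, grid,
                        n_perm=config.n_perm, seed=seeds["perm"],
                        ranking=config.ranking)
                    entry[mname] = {
                        "observed_auc_diff": r.observed_diff,
                        "p": r.p_two_tailed, "n_perm": r.n_perm,
                        "exact": r.exact}
                    d = r.observed_curve_a - r.observed_curve_b
                    for s, v, lo, hi in zip(xs, d, r.ci95_low,
                                            r.ci95_high):
                        diff_rows.append((key, mname, s, v, lo, hi))
        pd.DataFrame(diff_rows, columns=[
            "contrast", "metric", "density", "difference",
            "null_2.5pct", "null_97.5pct"]).to_csv(
            out / "contrast_curves.csv", index=False)

        stage = "write"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") \
            from err
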