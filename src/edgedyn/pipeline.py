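"""End-to-end orchestration: cohort -> ETS -> dynamics -> state networks ->
graph metrics -> NBS -> harmonization and group statistics.

All stages draw randomness from one master seed (simulation, rewired nulls,
NBS permutations), so a rerun with an identical config reproduces every
output file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import event_profile, summarize_dynamics
from .ets import ets_pipeline, matrix_to_edges, edge_pairs
from .frames import DEFAULT_SPARSITY_GRID, build_frame_network, split_frames
from .io import read_metadata, read_roi_series
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    auc_over_grid,
    global_metrics,
    nodal_metrics,
    null_normalize,
)
from .nbs import NbsConfig, permutation_p, result_to_dict
from .stats import combat_fit_apply, fdr_bh, spearman, two_sample_t
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

STATES = ("high", "low")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    output_dir: str
    input_dir: str | None = None
    simulate_spec: CohortSpec | None = None
    top_fraction: float = 0.10
    sparsity_grid: tuple = DEFAULT_SPARSITY_GRID
    fc_method: str = "mean_cofluctuation"
    nbs: NbsConfig = dataclasses.field(default_factory=NbsConfig)
    n_nulls: int = 20
    rewires_per_edge: int = 5
    seed: int = 0
    units: str = "frames"
    tr_seconds: float = 3.0
    alpha: float = 0.05

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulate_spec is None):
            raise ValueError("exactly one of input_dir or simulate_spec is required")
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must lie in (0, 1)")
        if self.units not in ("frames", "seconds"):
            raise ValueError("units must be 'frames' or 'seconds'")
        if self.fc_method not in ("mean_cofluctuation", "frame_pearson"):
            raise ValueError(f"unknown fc_method {self.fc_method!r}")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir {self.input_dir} does not exist")


def config_from_json(path) -> RunConfig:
    with open(path) as fh:
        raw = json.load(fh)
    if "simulate_spec" in raw and raw["simulate_spec"] is not None:
        from .synthetic import CohortSpec as _CS

        tuple_fields = {
            "event_rate_per_group",
            "event_amplitude_per_group",
            "group_labels",
            "event_kernel",
            "apoe_probs",
        }
        raw["simulate_spec"] = _CS(
            **{
                k: (tuple(v) if k in tuple_fields else v)
                for k, v in raw["simulate_spec"].items()
            }
        )
    if "nbs" in raw and raw["nbs"] is not None:
        raw["nbs"] = NbsConfig(**raw["nbs"])
    if "sparsity_grid" in raw:
        raw["sparsity_grid"] = tuple(raw["sparsity_grid"])
    return RunConfig(**raw)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sparsity_grid"] = list(config.sparsity_grid)
    return d


def load_cohort(config: RunConfig):
    """(series list, metadata DataFrame); validated before any computation."""
    if config.simulate_spec is not None:
        cohort = generate_cohort(config.simulate_spec)
        return cohort.series, cohort.metadata
    meta = read_metadata(Path(config.input_dir) / "metadata.csv")
    series = []
    for sid in meta["subject_id"]:
        path = Path(config.input_dir) / f"{sid}.csv"
        if not path.exists():
            raise FileNotFoundError(f"series file missing for subject {sid}: {path}")
        series.append(read_roi_series(path, tr_seconds=config.tr_seconds, subject_id=str(sid)))
    return series, meta


def compute_dynamics(series_list, units: str = "frames") -> pd.DataFrame:
    """Per-subject RSS event summary table."""
    rows = []
    for series in series_list:
        t0 = time.perf_counter()
        _, ets, rss = ets_pipeline(series)
        profile = event_profile(rss)
        amp, ttd_frames = summarize_dynamics(profile, units="frames")
        _, ttd_seconds = summarize_dynamics(profile, units="seconds")
        rows.append(
            {
                "subject_id": series.subject_id,
                "n_troughs": profile.n_troughs,
                "n_peaks": profile.n_peaks,
                "mean_peak_amplitude": amp,
                "mean_ttd_frames": ttd_frames,
                "mean_ttd_seconds": ttd_seconds,
            }
        )
        logger.info(
            "stage=dynamics subject=%s wall=%.3fs troughs=%d",
            series.subject_id,
            time.perf_counter() - t0,
            profile.n_troughs,
        )
    return pd.DataFrame(rows)


def compute_state_networks(series_list, config: RunConfig):
    """Per-subject high/low FrameFcNetwork plus stacked FC edge vectors."""
    networks: dict = {s: [] for s in STATES}
    stacks: dict = {}
    for series in series_list:
        t0 = time.perf_counter()
        _, ets, rss = ets_pipeline(series)
        high, low = split_frames(rss, fraction=config.top_fraction)
        for mask in (high, low):
            net = build_frame_network(
                ets,
                mask,
                sparsity_grid=config.sparsity_grid,
                method=config.fc_method,
                raw_data=series.data,
            )
            networks[mask.state].append(net)
        logger.info(
            "stage=networks subject=%s wall=%.3fs method=%s",
            series.subject_id,
            time.perf_counter() - t0,
            config.fc_method,
        )
    for state in STATES:
        stacks[state] = np.vstack([matrix_to_edges(n.fc) for n in networks[state]])
    return networks, stacks


def compute_metric_tables(networks, series_list, config: RunConfig):
    """(global long table, nodal long table); AUC rows use sparsity = 'AUC'."""
    grid = [float(s) for s in config.sparsity_grid]
    master = np.random.SeedSequence(config.seed)
    subj_seeds = master.spawn(len(series_list))
    global_rows = []
    nodal_rows = []
    for si, series in enumerate(series_list):
        rng = np.random.default_rng(subj_seeds[si])
        for state in STATES:
            t0 = time.perf_counter()
            net = networks[state][si]
            per_s = {m: [] for m in GLOBAL_METRIC_NAMES}
            nodal_per_s = {m: [] for m in NODAL_METRIC_NAMES}
            for s in grid:
                adj = net.graphs[s]
                gm = global_metrics(adj)
                if adj.sum() >= 4:  # >= 2 edges
                    sw, _ = null_normalize(
                        adj,
                        n_nulls=config.n_nulls,
                        rewires_per_edge=config.rewires_per_edge,
                        rng=rng,
                    )
                else:
                    sw = {"gamma": 0.0, "lambda": 0.0, "sigma": 0.0}
                nm = nodal_metrics(adj)
                vals = {**gm, **sw}
                global_rows.append(
                    {
                        "subject_id": series.subject_id,
                        "state": state,
                        "sparsity": s,
                        **{m: vals[m] for m in GLOBAL_METRIC_NAMES},
                    }
                )
                for m in GLOBAL_METRIC_NAMES:
                    per_s[m].append(vals[m])
                for m in NODAL_METRIC_NAMES:
                    nodal_per_s[m].append(nm[m])
                for ri, roi in enumerate(series.roi_labels):
                    nodal_rows.append(
                        {
                            "subject_id": series.subject_id,
                            "state": state,
                            "sparsity": s,
                            "roi": roi,
                            **{m: float(nm[m][ri]) for m in NODAL_METRIC_NAMES},
                        }
                    )
            global_rows.append(
                {
                    "subject_id": series.subject_id,
                    "state": state,
                    "sparsity": "AUC",
                    **{m: auc_over_grid(per_s[m], grid) for m in GLOBAL_METRIC_NAMES},
                }
            )
            nodal_auc = {
                m: np.trapezoid(np.column_stack(nodal_per_s[m]), np.asarray(grid), axis=1)
                for m in NODAL_METRIC_NAMES
            }
            for ri, roi in enumerate(series.roi_labels):
                nodal_rows.append(
                    {
                        "subject_id": series.subject_id,
                        "state": state,
                        "sparsity": "AUC",
                        "roi": roi,
                        **{m: float(nodal_auc[m][ri]) for m in NODAL_METRIC_NAMES},
                    }
                )
            logger.info(
                "stage=metrics subject=%s state=%s wall=%.3fs",
                series.subject_id,
                state,
                time.perf_counter() - t0,
            )
    return pd.DataFrame(global_rows), pd.DataFrame(nodal_rows)


def _group_split(metadata: pd.DataFrame):
    groups = list(dict.fromkeys(metadata["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    # convention: the second-listed group (e.g. the patient group) minus the first
    ga, gb = groups[1], groups[0]
    idx_a = np.asarray(metadata["group"] == ga)
    idx_b = np.asarray(metadata["group"] == gb)
    return ga, gb, idx_a, idx_b


def harmonize_features(
    features: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """ComBat across sites with group membership as a retained covariate.

    Skipped (identity, logged) when there is a single site or any site has
    fewer than 2 subjects.
    """
    sites = metadata["site"].to_numpy()
    unique, counts = np.unique(sites, return_counts=True)
    if len(unique) < 2 or counts.min() < 2:
        logger.info("harmonization skipped: insufficient site structure")
        return features.copy()
    group_ind = (metadata["group"] == metadata["group"].iloc[-1]).to_numpy(dtype=float)
    harmonized, _ = combat_fit_apply(
        features.to_numpy(dtype=float), sites, covariates=group_ind[:, None]
    )
    return pd.DataFrame(harmonized, columns=features.columns, index=features.index)


def group_statistics(features: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Pooled-t group comparison per feature column, mirroring a summary table."""
    ga, gb, idx_a, idx_b = _group_split(metadata)
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        cmp = two_sample_t(vals[idx_a], vals[idx_b], metric_name=str(col))
        rows.append(
            {
                "metric": col,
                "group_a": ga,
                "mean_a": cmp.mean_a,
                "sd_a": cmp.sd_a,
                "n_a": cmp.n_a,
                "group_b": gb,
                "mean_b": cmp.mean_b,
                "sd_b": cmp.sd_b,
                "n_b": cmp.n_b,
                "t": cmp.t_statistic,
                "df": cmp.df,
                "p": cmp.p_value,
                "cohens_d": cmp.cohens_d,
                "ci95_low": cmp.ci95[0],
                "ci95_high": cmp.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def nodal_group_statistics(
    nodal: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-ROI group tests on nodal AUC values, BH-FDR within state x metric."""
    auc = nodal[nodal["sparsity"] == "AUC"]
    meta_idx = metadata.set_index("subject_id")
    out = []
    for state in STATES:
        sub = auc[auc["state"] == state]
        wide = {m: sub.pivot(index="subject_id", columns="roi", values=m) for m in NODAL_METRIC_NAMES}
        for m in NODAL_METRIC_NAMES:
            table = wide[m]
            meta = meta_idx.loc[table.index].reset_index()
            stats_df = group_statistics(table, meta)
            stats_df.insert(0, "state", state)
            stats_df.insert(1, "nodal_metric", m)
            adj, rej = fdr_bh(stats_df["p"].to_numpy(), alpha=alpha)
            stats_df["p_fdr"] = adj
            stats_df["significant_fdr"] = rej
            out.append(stats_df)
    result = pd.concat(out, ignore_index=True)
    return result.rename(columns={"metric": "roi"})


def clinical_correlations(
    features: pd.DataFrame, metadata: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman correlations of derived metrics with clinical variables.

    Pools both groups; raw and BH-adjusted p-values are both reported.
    """
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        for clin in ("mmse", "moca", "apoe4_count"):
            y = metadata[clin].to_numpy(dtype=float)
            try:
                res = spearman(x, y, pair=(str(col), clin))
            except ValueError as exc:
                logger.warning("correlation %s vs %s skipped: %s", col, clin, exc)
                continue
            rows.append(
                {
                    "metric": col,
                    "clinical": clin,
                    "rho": res.rho,
                    "p": res.p_value,
                    "n": res.n,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        adj, rej = fdr_bh(df["p"].to_numpy(), alpha=alpha)
        df["p_fdr"] = adj
        df["significant_fdr"] = rej
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle under output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    series, metadata = load_cohort(config)
    logger.info("stage=load n_subjects=%d", len(series))

    dyn = compute_dynamics(series, units=config.units)
    dyn = metadata.merge(dyn, on="subject_id")
    dyn.to_csv(out / "dynamics.csv", index=False)

    networks, stacks = compute_state_networks(series, config)
    glob, nodal = compute_metric_tables(networks, series, config)
    glob = glob.merge(metadata[["subject_id", "group", "site"]], on="subject_id")
    glob.to_csv(out / "global_metrics.csv", index=False)
    nodal.to_csv(out / "nodal_metrics.csv", index=False)

    ga, gb, idx_a, idx_b = _group_split(metadata)
    pairs = edge_pairs(series[0].n_roi)
    nbs_out = {}
    for state in STATES:
        cfg = dataclasses.replace(config.nbs, seed=config.nbs.seed + config.seed)
        result = permutation_p(stacks[state][idx_a], stacks[state][idx_b], pairs, cfg)
        nbs_out[state] = result
        with open(out / f"nbs_{state}.json", "w") as fh:
            json.dump(result_to_dict(result, series[0].roi_labels), fh, indent=2)
        logger.info(
            "stage=nbs state=%s components=%d", state, len(result.components)
        )

    # harmonized group stats: dynamics + global AUC metrics per state
    feat = dyn.set_index("subject_id")[["mean_peak_amplitude", "mean_ttd_frames"]].rename(
        columns={"mean_peak_amplitude": "peak_amplitude", "mean_ttd_frames": "ttd"}
    )
    auc = glob[glob["sparsity"] == "AUC"]
    for state in STATES:
        sub = auc[auc["state"] == state].set_index("subject_id")
        for m in GLOBAL_METRIC_NAMES:
            feat[f"{state}_{m}"] = sub[m]
    feat = feat.loc[metadata["subject_id"]]
    complete = feat.notna().all(axis=1)
    if not complete.all():
        logger.warning("%d subjects dropped from group stats (empty profiles)", (~complete).sum())
    meta_c = metadata[complete.to_numpy()].reset_index(drop=True)
    feat_c = feat[complete.to_numpy()]
    harmonized = harmonize_features(feat_c, meta_c)
    stats_table = group_statistics(harmonized, meta_c)
    stats_table.to_csv(out / "group_stats.csv", index=False)

    nodal_stats = nodal_group_statistics(nodal, metadata, alpha=config.alpha)
    nodal_stats.to_csv(out / "nodal_stats.csv", index=False)

    correlations = clinical_correlations(harmonized, meta_c, alpha=config.alpha)
    correlations.to_csv(out / "correlations.csv", index=False)

    cfg_dict = _config_dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "edgedyn_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_subjects": len(series),
        "groups": {ga: int(idx_a.sum()), gb: int(idx_b.sum())},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "dynamics": dyn,
        "global_metrics": glob,
        "nodal_metrics": nodal,
        "nbs": nbs_out,
        "group_stats": stats_table,
        "nodal_stats": nodal_stats,
        "correlations": correlations,
        "manifest": manifest,
    }
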