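"""Metric table assembly, direction-aware normalization and composite ranking.

The long-format report carries one row per (method, dataset, task, metric)
with the raw value, a direction tag, the higher-is-better transformed value
and the per-(dataset, metric) normalized value. The composite score is the
unweighted mean of normalized values per method; ranking is by descending
composite with alphabetical tie-breaking.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "method",
    "dataset",
    "task",
    "metric",
    "raw_value",
    "direction",
    "transformed_value",
    "normalized_value",
]

#: metrics whose raw orientation is lower-is-better. All library metrics are
#: already emitted higher-is-better (1-C / 1-CHAOS / 1-PAS applied upstream);
#: residual lower-is-better quantities (e.g. L2 error) are negated here.
LOWER_IS_BETTER = {"l2", "model_l2_mean", "additive_l2_mean", "chaos_raw", "pas_raw"}


def make_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble a long-format metric table from result dicts."""
    df = pd.DataFrame(rows)
    if "direction" not in df:
        df["direction"] = np.where(
            df["metric"].isin(LOWER_IS_BETTER), "lower", "higher"
        )
    df["transformed_value"] = np.where(
        df["direction"] == "lower", -df["raw_value"], df["raw_value"]
    )
    df["normalized_value"] = np.nan
    return df[[c for c in REPORT_COLUMNS if c in df.columns]]


def normalize_and_rank(report: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per (dataset, metric) column and rank methods by composite.

    Columns are divided by their maximum transformed value when that maximum
    is positive; columns whose maximum is <= 0 are min-max rescaled and
    flagged. All-missing metric columns are dropped with a warning.
    """
    df = report.copy()
    if df.empty:
        raise ValueError("empty report")
    keep = []
    for (dataset, metric), grp in df.groupby(["dataset", "metric"], sort=False):
        vals = grp["transformed_value"].astype(float)
        if vals.isna().all():
            warnings.warn(f"metric {metric!r} on {dataset!r} all-missing; dropped", stacklevel=2)
            continue
        vmax = vals.max()
        if vmax > 0:
            norm = vals / vmax
        else:
            span = vals.max() - vals.min()
            norm = (vals - vals.min()) / span if span > 0 else pd.Series(1.0, index=vals.index)
            logger.warning("column (%s, %s) max <= 0; min-max rescaled", dataset, metric)
        sub = grp.copy()
        sub["normalized_value"] = norm
        keep.append(sub)
    df = pd.concat(keep, ignore_index=True)

    composite = (
        df.groupby("method")["normalized_value"].mean().rename("composite_score")
    )
    ranking = composite.reset_index().sort_values(
        ["composite_score", "method"], ascending=[False, True], ignore_index=True
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return df, ranking


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(
    outdir: str | Path, report: pd.DataFrame, ranking: pd.DataFrame, config: dict
) -> dict[str, Path]:
    """Write TSV + JSON report files plus a provenance log (timestamp-free)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report_tsv": outdir / "metric_report.tsv",
        "ranking_tsv": outdir / "ranking.tsv",
        "report_json": outdir / "metric_report.json",
        "run_log": outdir / "run_log.json",
    }
    report = report.copy()
    for col in ("raw_value", "transformed_value", "normalized_value"):
        report[col] = report[col].map(lambda v: f"{v:.10g}" if pd.notna(v) else "NA")
    report.to_csv(paths["report_tsv"], sep="\t", index=False)
    ranking.to_csv(
        paths["ranking_tsv"], sep="\t", index=False, float_format="%.10g"
    )
    paths["report_json"].write_text(report.to_json(orient="records", indent=1))
    from scembed_eval import __version__

    paths["run_log"].write_text(
        json.dumps(
            {"config": config, "config_hash": config_hash(config), "version": __version__},
            indent=1,
            sort_keys=True,
            default=str,
        )
    )
    return paths


# ---------------------------------------------------------------------------
# One-command benchmark
# ---------------------------------------------------------------------------


def run_benchmark(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages and write the metric report.

    Config schema (all optional except ``datasets``)::

        datasets:                 # list of fixture specs or h5ad paths
          - name: mix
            fixture: mixture     # or: path: data.h5ad
            n_cells: 600
            ...
        methods: [embedding]     # obsm-style embedding sources
        tasks: [zero_shot, spatial, few_shot]
        seed: 0

    Failures are recorded per (method, dataset, task); the run continues.
    """
    from scembed_eval import synthetic
    from scembed_eval.clustering import build_neighbor_graph, unified_clustering, Partition, partition_agreement
    from scembed_eval.datamodel import load_dataset
    from scembed_eval.embedding_metrics import BatchMetricConfig, embedding_metric_suite
    from scembed_eval.fewshot import run_episode, sample_episodes
    from scembed_eval.prediction import PredictionSet, episode_reports
    from scembed_eval.spatial import SpatialConfig, spatial_metric_suite

    seed = int(config.get("seed", 0))
    tasks = config.get("tasks", ["zero_shot", "spatial", "few_shot"])
    rows: list[dict] = []
    failures: list[dict] = []

    for ds_cfg in config["datasets"]:
        name = ds_cfg.get("name", "dataset")
        emb, counts, ann = _resolve_dataset(ds_cfg, synthetic, seed)
        methods = config.get("methods") or ["embedding"]
        for method in methods:
            emb_m = emb  # single-embedding containers: method name is cosmetic
            if emb_m is None:
                failures.append({"method": method, "dataset": name, "task": "all", "error": "no embedding"})
                continue
            if "zero_shot" in tasks:
                try:
                    cfg = BatchMetricConfig(seed=seed, **config.get("batch_metric_config", {}))
                    n_target = len(set(ann.cell_type.tolist()))
                    graph = build_neighbor_graph(emb_m, k=min(15, emb_m.n_cells - 1))
                    part = unified_clustering(graph, n_target, seed=seed)
                    agreement = partition_agreement(Partition(ann.cell_type), part)
                    suite = embedding_metric_suite(emb_m, ann, cfg)
                    for metric, value in {**agreement, **suite}.items():
                        rows.append(
                            {"method": method, "dataset": name, "task": "zero_shot", "metric": metric, "raw_value": value}
                        )
                except Exception as e:  # noqa: BLE001 - stage isolation
                    failures.append({"method": method, "dataset": name, "task": "zero_shot", "error": str(e)})
            if "few_shot" in tasks:
                try:
                    fs = config.get("few_shot", {})
                    episodes = sample_episodes(
                        ann,
                        n_way=int(fs.get("n_way", min(5, len(set(ann.cell_type.tolist()))))),
                        k_shot=int(fs.get("k_shot", 1)),
                        n_trials=int(fs.get("trials", 20)),
                        query_per_class=int(fs.get("query_per_class", 20)),
                        seed=seed,
                    )
                    preds = []
                    for ep in episodes:
                        p, probs, levels, truth = run_episode(emb_m, ep)
                        preds.append(
                            PredictionSet(ep.query_ids, truth, p, probs, levels)
                        )
                    for metric, value in episode_reports(preds).items():
                        rows.append(
                            {"method": method, "dataset": name, "task": "few_shot", "metric": metric, "raw_value": value}
                        )
                except Exception as e:  # noqa: BLE001
                    failures.append({"method": method, "dataset": name, "task": "few_shot", "error": str(e)})
            if "spatial" in tasks:
                if ann.spatial_xy is None:
                    logger.info("dataset %s has no spatial coordinates; spatial task skipped", name)
                    continue
                try:
                    scfg = SpatialConfig(seed=seed, **config.get("spatial_config", {}))
                    suite = spatial_metric_suite(counts, ann.cell_type, ann.spatial_xy, scfg)
                    for metric, value in suite.items():
                        rows.append(
                            {"method": method, "dataset": name, "task": "spatial", "metric": metric, "raw_value": value}
                        )
                except Exception as e:  # noqa: BLE001
                    failures.append({"method": method, "dataset": name, "task": "spatial", "error": str(e)})

    if not rows:
        raise RuntimeError(f"no metrics produced; failures: {failures}")
    report = make_report(rows)
    normalized, ranking = normalize_and_rank(report)
    paths = write_report(outdir, normalized, ranking, config)
    if failures:
        (Path(outdir) / "failures.json").write_text(json.dumps(failures, indent=1))
    return {"report": normalized, "ranking": ranking, "paths": paths, "failures": failures}


def _resolve_dataset(ds_cfg: dict, synthetic, seed: int):
    if "path" in ds_cfg:
        from scembed_eval.datamodel import load_dataset

        return load_dataset(ds_cfg["path"], keys=ds_cfg.get("keys"))
    fixture = ds_cfg.get("fixture", "mixture")
    if fixture == "mixture":
        spec = synthetic.MixtureSpec(
            n_cells=int(ds_cfg.get("n_cells", 600)),
            n_types=int(ds_cfg.get("n_types", 3)),
            n_batches=int(ds_cfg.get("n_batches", 1)),
            dim=int(ds_cfg.get("dim", 10)),
            type_separation=float(ds_cfg.get("type_separation", 6.0)),
            batch_shift=float(ds_cfg.get("batch_shift", 0.0)),
            seed=int(ds_cfg.get("seed", seed)),
        )
        emb, ann = synthetic.make_mixture_embeddings(spec)
        return emb, None, ann
    if fixture == "spatial":
        counts, ann = synthetic.make_spatial_fixture(
            grid_rows=int(ds_cfg.get("grid_rows", 12)),
            grid_cols=int(ds_cfg.get("grid_cols", 12)),
            domain_layout=ds_cfg.get("domain_layout", "stripes"),
            n_domains=int(ds_cfg.get("n_domains", 2)),
            noise=float(ds_cfg.get("noise", 0.0)),
            seed=int(ds_cfg.get("seed", seed)),
        )
        # expression-space embedding stands in when no model embedding exists
        from scembed_eval.datamodel import EmbeddingSet
        from scembed_eval.spatial import lognormalize

        emb = EmbeddingSet(list(counts.cell_ids), lognormalize(counts.counts))
        return emb, counts, ann
    raise ValueError(f"unknown fixture kind {ds_cfg.get('fixture')!r}")
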