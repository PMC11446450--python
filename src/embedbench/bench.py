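"""Full benchmark: simulate, embed with every method across seeds, score, report.

The run protocol follows the five-run convention: stochastic embedders
(t-SNE, UMAP, the shape autoencoder) are run once per seed in the seed
list, the deterministic PCA embedding is computed once and reused, and
aggregates report (mean, min, max) across runs. kNN accuracy and
silhouette are additionally evaluated directly in the high-dimensional
gene space as dotted-line baselines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from embedbench.data import (
    CountMatrix,
    ExpressionMatrix,
    NBSimConfig,
    preprocess,
    read_counts,
    simulate_nb_counts,
    write_counts,
)
from embedbench.embedders import (
    Embedding2D,
    ShapeEmbedConfig,
    ShapeSpec,
    embed_pca2,
    embed_tsne,
    embed_umap,
    fit_shape_embedding,
    make_shape,
)
from embedbench.metrics import (
    DEFAULT_HDBSCAN_GRID,
    MetricValue,
    ami_max_hdbscan,
    hd_baselines,
    interclass_corr,
    intraclass_corr,
    knn_accuracy,
    knn_graph,
    knn_recall,
    silhouette,
)

logger = logging.getLogger(__name__)

ALL_EMBEDDERS = ("pca", "tsne", "umap", "shape")
DETERMINISTIC_EMBEDDERS = ("pca",)
BASELINE_METRICS = ("knn_accuracy", "silhouette")


class BenchError(RuntimeError):
    pass


@dataclass
class BenchConfig:
    """Configuration of a full benchmark run.

    Either ``sim`` (a simulator configuration) or ``data_path`` (an
    on-disk labeled count matrix) provides the input. ``pca_dim`` sets the
    PCA representation fed to t-SNE/UMAP/shape (None = gene space); the
    high-dimensional reference for metrics is the normalized log gene
    space unless ``hd_space="pca"``.
    """

    sim: NBSimConfig = field(default_factory=NBSimConfig)
    data_path: str | None = None
    data_format: str = "mtx"
    embedders: tuple[str, ...] = ALL_EMBEDDERS
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    k: int = 10
    hdbscan_grid: tuple[dict, ...] = DEFAULT_HDBSCAN_GRID
    corr_flavor: str = "pearson"
    shape_name: str = "elephant"
    shape_points: int = 100
    shape_config: ShapeEmbedConfig = field(default_factory=ShapeEmbedConfig)
    pca_dim: int | None = 50
    hd_space: str = "gene"
    dataset_name: str = "nb_sim"
    tsne_params: dict = field(default_factory=dict)
    umap_params: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.seeds or len(set(self.seeds)) != len(self.seeds):
            raise BenchError("seeds must be non-empty and distinct")
        unknown = set(self.embedders) - set(ALL_EMBEDDERS)
        if unknown:
            raise BenchError(f"unknown embedders {sorted(unknown)}; choose from {ALL_EMBEDDERS}")


@dataclass
class MetricReport:
    """Long-format metric records plus per-(method, metric) aggregates."""

    records: list[MetricValue]
    aggregates: dict[tuple[str, str], tuple[float, float, float]]
    hd_baseline: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "dataset": self.provenance.get("dataset", ""),
                    "method": r.method,
                    "seed": r.details.get("seed", ""),
                    "run": r.run_index,
                    "metric": r.metric,
                    "value": r.value,
                    "baseline_hd": self.hd_baseline.get(r.metric, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def aggregate_frame(self) -> pd.DataFrame:
        rows = [
            {"method": m, "metric": met, "mean": a, "min": lo, "max": hi}
            for (m, met), (a, lo, hi) in sorted(self.aggregates.items())
        ]
        return pd.DataFrame(rows)

    def value(self, method: str, metric: str, stat: str = "mean") -> float:
        agg = self.aggregates[(method, metric)]
        return agg[{"mean": 0, "min": 1, "max": 2}[stat]]


def aggregate_runs(values) -> tuple[float, float, float]:
    """Arithmetic mean, minimum and maximum across runs."""
    values = list(values)
    if not values:
        raise BenchError("cannot aggregate an empty list of runs")
    return float(np.mean(values)), float(np.min(values)), float(np.max(values))


def _log_stage(stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "wall_s": round(time.time() - t0, 2), **info}
    logger.info("%s", json.dumps(entry))
    print(json.dumps(entry), file=sys.stderr)


def _config_hash(config: BenchConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = asdict(config)
    payload.pop("out_dir", None)  # hash must describe the experiment, not its location
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _embed_one(method: str, x: ExpressionMatrix, config: BenchConfig, seed: int,
               run_index: int, shape: ShapeSpec) -> Embedding2D:
    if method == "pca":
        emb = embed_pca2(x)
    elif method == "tsne":
        emb = embed_tsne(x, seed=seed, run_index=run_index, **config.tsne_params)
    elif method == "umap":
        emb = embed_umap(x, seed=seed, run_index=run_index, **config.umap_params)
    elif method == "shape":
        from dataclasses import replace

        emb = fit_shape_embedding(x, shape, replace(config.shape_config, seed=seed))
    else:  # pragma: no cover - guarded by BenchConfig
        raise BenchError(f"unknown embedder {method}")
    emb.run_index = run_index
    return emb


def score_embedding(emb: Embedding2D, hd: np.ndarray, labels, *, k: int = 10,
                    hd_graph=None, grid=None, corr_flavor: str = "pearson") -> list[MetricValue]:
    """All six metrics for one embedding against the HD reference."""
    coords = emb.coords
    emb_graph = knn_graph(coords, k)
    out = [
        interclass_corr(hd, coords, labels, flavor=corr_flavor),
        intraclass_corr(hd, coords, labels, flavor=corr_flavor),
        knn_accuracy(coords, labels, k=k, graph=emb_graph),
        knn_recall(hd, coords, k=k, hd_graph=hd_graph, emb_graph=emb_graph),
        silhouette(coords, labels),
        ami_max_hdbscan(coords, labels, grid=grid),
    ]
    for mv in out:
        mv.method = emb.method
        mv.run_index = emb.run_index
        mv.details["seed"] = emb.seed
    return out


def _load_or_simulate(config: BenchConfig):
    if config.data_path is not None:
        counts = read_counts(config.data_path, format=config.data_format)
        if counts.labels is None:
            raise BenchError("user-supplied data must include per-cell labels")
        return counts
    return simulate_nb_counts(config.sim)


def run_benchmark(config: BenchConfig) -> MetricReport:
    """Execute the full pipeline and return (and optionally write) the report.

    Stages: simulate (or load) -> preprocess -> each embedder x each seed
    (deterministic embedders once) -> all six metrics per embedding plus
    HD baselines -> aggregates. With ``config.out_dir`` set, counts,
    embeddings and report TSVs are written as they are produced, so a
    failed run preserves partial artifacts.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    stage = "simulate"
    try:
        counts = _load_or_simulate(config)
        _log_stage(stage, t0, n_cells=counts.n_cells, n_genes=counts.n_genes)
        if out_dir:
            write_counts(counts, out_dir / "counts", format="mtx")

        t0 = time.time()
        stage = "preprocess"
        hd_expr = preprocess(counts, pca_dim=None)
        embed_input = (
            preprocess(counts, pca_dim=config.pca_dim) if config.pca_dim else hd_expr
        )
        hd = embed_input.values if config.hd_space == "pca" else hd_expr.values
        labels = np.asarray(counts.labels)
        _log_stage(stage, t0, hd_dim=hd.shape[1], embed_dim=embed_input.values.shape[1])

        t0 = time.time()
        stage = "hd_reference"
        hd_graph = knn_graph(hd, config.k, space_tag="HD")
        acc_hd, sil_hd = hd_baselines(hd, labels, k=config.k, graph=hd_graph)
        hd_baseline = {"knn_accuracy": acc_hd, "silhouette": sil_hd}
        _log_stage(stage, t0, knn_accuracy_hd=round(acc_hd, 4), silhouette_hd=round(sil_hd, 4))

        shape = make_shape(config.shape_name, config.shape_points)
        records: list[MetricValue] = []
        embeddings: list[Embedding2D] = []
        for method in config.embedders:
            seeds = (config.seeds[0],) if method in DETERMINISTIC_EMBEDDERS else config.seeds
            for run_index, seed in enumerate(seeds):
                t0 = time.time()
                stage = f"embed:{method}:seed{seed}"
                emb = _embed_one(method, embed_input, config, seed, run_index, shape)
                _log_stage(stage, t0, fingerprint=emb.source_fingerprint)
                if out_dir:
                    _write_embedding(emb, counts.cell_ids, out_dir)
                embeddings.append(emb)

                t0 = time.time()
                stage = f"score:{method}:seed{seed}"
                records.extend(
                    score_embedding(
                        emb, hd, labels, k=config.k, hd_graph=hd_graph,
                        grid=[dict(g) for g in config.hdbscan_grid],
                        corr_flavor=config.corr_flavor,
                    )
                )
                _log_stage(stage, t0)
    except Exception as exc:
        raise BenchError(f"benchmark failed at stage {stage!r}: {exc}") from exc

    aggregates: dict[tuple[str, str], tuple[float, float, float]] = {}
    for method in config.embedders:
        for metric in ("interclass_corr", "intraclass_corr", "knn_accuracy",
                       "knn_recall", "silhouette", "ami_max"):
            vals = [r.value for r in records if r.method == method and r.metric == metric]
            if method in DETERMINISTIC_EMBEDDERS:
                vals = vals * len(config.seeds)  # single run reused across the aggregate
            aggregates[(method, metric)] = aggregate_runs(vals)

    shape_extras = [e.extras for e in embeddings if e.method == "shape"]
    report = MetricReport(
        records=records,
        aggregates=aggregates,
        hd_baseline=hd_baseline,
        provenance={
            "dataset": config.dataset_name,
            "config_hash": _config_hash(config),
            "seeds": list(config.seeds),
            "k": config.k,
            "corr_flavor": config.corr_flavor,
            "pca_dim": config.pca_dim,
            "hd_space": config.hd_space,
            "shape_runs": [
                {k: v for k, v in ex.items() if k != "training_log"} for ex in shape_extras
            ],
        },
    )
    if out_dir:
        write_report(report, out_dir)
    return report


def _write_embedding(emb: Embedding2D, cell_ids, out_dir: Path) -> None:
    df = pd.DataFrame({"cell_id": cell_ids, "x": emb.coords[:, 0], "y": emb.coords[:, 1]})
    df.to_csv(out_dir / f"embedding_{emb.method}_seed{emb.seed}.tsv", sep="\t", index=False)


def write_report(report: MetricReport, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out_dir / "report.tsv", sep="\t", index=False)
    report.aggregate_frame().to_csv(out_dir / "aggregates.tsv", sep="\t", index=False)
    (out_dir / "provenance.json").write_text(json.dumps(report.provenance, indent=2) + "\n")


def read_report_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def render_report(report: MetricReport | pd.DataFrame, out_dir: str | Path):
    """One panel per metric, one marker per method with min-max error bars.

    Dotted horizontal lines mark the high-dimensional baselines for kNN
    accuracy and silhouette. Writes ``metrics.png`` and ``aggregates.tsv``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(report, MetricReport):
        frame = report.to_frame()
        baselines = report.hd_baseline
    else:
        frame = report
        baselines = {}
        for metric in BASELINE_METRICS:
            sub = frame[frame["metric"] == metric]
            if len(sub) and sub["baseline_hd"].notna().any():
                baselines[metric] = float(sub["baseline_hd"].dropna().iloc[0])

    metrics = [m for m in ("interclass_corr", "intraclass_corr", "knn_accuracy",
                           "knn_recall", "silhouette", "ami_max")
               if m in set(frame["metric"])]
    methods = list(dict.fromkeys(frame["method"]))
    colors = {m: c for m, c in zip(methods, plt.rcParams["axes.prop_cycle"].by_key()["color"])}

    fig, axes = plt.subplots(1, len(metrics), figsize=(2.2 * len(metrics), 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        sub = frame[frame["metric"] == metric]
        for i, method in enumerate(methods):
            vals = sub[sub["method"] == method]["value"].to_numpy()
            if not len(vals):
                continue
            mean, lo, hi = aggregate_runs(vals)
            ax.errorbar(
                [i], [mean], yerr=[[mean - lo], [hi - mean]],
                fmt="o", color=colors[method], capsize=3, label=method,
            )
        if metric in baselines:
            ax.axhline(baselines[metric], ls=":", color="gray", lw=1)
        ax.set_title(metric, fontsize=9)
        ax.set_xticks(range(len(methods)))
        ax.set_xticklabels(methods, rotation=45, fontsize=7)
    axes[0][0].set_ylabel("metric value")
    fig.tight_layout()
    fig_path = out_dir / "metrics.png"
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)

    agg_rows = []
    for metric in metrics:
        sub = frame[frame["metric"] == metric]
        for method in methods:
            vals = sub[sub["method"] == method]["value"].to_numpy()
            if len(vals):
                mean, lo, hi = aggregate_runs(vals)
                agg_rows.append({"method": method, "metric": metric,
                                 "mean": mean, "min": lo, "max": hi})
    table_path = out_dir / "aggregates.tsv"
    pd.DataFrame(agg_rows).to_csv(table_path, sep="\t", index=False)
    return fig_path, table_path
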