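"""Synthetic scRNA-seq counts, preprocessing, and on-disk formats.

The simulator draws counts from a negative binomial distribution with a
mean/size parameterization (variance = mu + mu^2/theta, the standard
scRNA-seq convention). Each class up-shifts a disjoint block of marker
genes by a fixed log2 fold change, so ground-truth class structure is
identifiable by construction. Gene baseline means are log-normal across
genes, mimicking the long-tailed mean-expression distribution of real
droplet data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ConfigurationError(ValueError):
    """Invalid simulator or preprocessing configuration."""


class FormatError(ValueError):
    """Malformed on-disk data (bad dimensions, negative counts, ...)."""


@dataclass(frozen=True)
class NBSimConfig:
    """Parameters of the negative-binomial class-structure simulator.

    Defaults produce ten classes that are cleanly separable in the
    high-dimensional gene space but strongly overlap under a 2D linear
    projection -- the regime in which neighborhood-preservation and
    distance-preservation metrics disagree.

    Parameters
    ----------
    n_classes, cells_per_class, n_genes
        Dataset geometry. Total cells = ``n_classes * cells_per_class``.
    baseline_log_mean, baseline_log_sd
        Natural-log mean and sd of the per-gene log-normal baseline mean.
    marker_fraction
        Fraction of genes up-shifted per class, in (0, 1). Marker blocks
        are disjoint across classes, so
        ``n_classes * round(marker_fraction * n_genes) <= n_genes``.
    marker_log2_fc
        log2 fold change applied to a class's marker genes.
    dispersion
        NB size parameter theta > 0; variance = mu + mu^2 / theta.
    seed
        Seed for the simulator's generator; same config => identical output.
    """

    n_classes: int = 10
    cells_per_class: int = 500
    n_genes: int = 1000
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.0
    marker_fraction: float = 0.05
    marker_log2_fc: float = 2.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.cells_per_class < 1 or self.n_genes < 1:
            raise ConfigurationError("n_classes, cells_per_class, n_genes must be positive")
        if not (0.0 < self.marker_fraction < 1.0):
            raise ConfigurationError("marker_fraction must be in (0, 1)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion (NB size theta) must be > 0")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be >= 0")
        if self.n_markers_per_class < 1:
            raise ConfigurationError("marker_fraction * n_genes must be >= 1")
        if self.n_classes * self.n_markers_per_class > self.n_genes:
            raise ConfigurationError(
                "disjoint marker blocks need n_classes * markers_per_class <= n_genes"
            )

    @property
    def n_markers_per_class(self) -> int:
        return int(round(self.marker_fraction * self.n_genes))

    @property
    def n_cells(self) -> int:
        return self.n_classes * self.cells_per_class


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer counts with identifiers.

    ``labels`` (optional) holds the per-cell ground-truth class; when
    present, every class must have at least two members.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2D matrix")
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise FormatError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise FormatError(f"{len(self.gene_ids)} gene ids for {g} matrix columns")
        if self.labels is not None:
            if len(self.labels) != n:
                raise FormatError(f"{len(self.labels)} labels for {n} cells")
            _, counts_per_class = np.unique(self.labels, return_counts=True)
            if np.any(counts_per_class < 2):
                raise FormatError("every class must have >= 2 member cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """Processed high-dimensional representation fed to embedders.

    ``provenance`` records each preprocessing step applied (normalization
    target, log transform, optional PCA reduction dimension), so any
    representation is self-describing. Cell ids and labels are carried
    through from the source counts.
    """

    values: np.ndarray
    provenance: tuple[dict, ...] = field(default_factory=tuple)
    cell_ids: list[str] | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


def simulate_nb_counts(config: NBSimConfig) -> CountMatrix:
    """Draw a labeled count matrix from the NB class-structure model.

    Gene ``g`` has a log-normal baseline mean ``m_g``; in class ``c`` its
    mean is ``m_g * 2**marker_log2_fc`` iff ``g`` lies in the marker block
    of ``c``, else ``m_g``. Counts are NB(mean mu, size theta). Identical
    config (including seed) gives bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes))

    m = config.n_markers_per_class
    theta = config.dispersion
    fc = 2.0 ** config.marker_log2_fc

    blocks = []
    labels: list[str] = []
    for c in range(config.n_classes):
        mu = base.copy()
        mu[c * m : (c + 1) * m] *= fc
        # numpy's negative_binomial takes (n, p) with n = size, p = n/(n+mu)
        p = theta / (theta + mu)
        blocks.append(
            rng.negative_binomial(theta, p[None, :], size=(config.cells_per_class, config.n_genes))
        )
        labels.extend([f"class_{c:02d}"] * config.cells_per_class)

    counts = np.vstack(blocks)
    width = max(4, len(str(config.n_cells - 1)))
    cell_ids = [f"cell_{i:0{width}d}" for i in range(config.n_cells)]
    gene_ids = [f"gene_{j:04d}" for j in range(config.n_genes)]
    return CountMatrix(counts=counts, cell_ids=cell_ids, gene_ids=gene_ids, labels=labels)


def class_marker_genes(config: NBSimConfig) -> dict[str, list[str]]:
    """Ground-truth marker gene ids per class for a given config."""
    m = config.n_markers_per_class
    return {
        f"class_{c:02d}": [f"gene_{j:04d}" for j in range(c * m, (c + 1) * m)]
        for c in range(config.n_classes)
    }


def preprocess(
    counts: CountMatrix,
    normalize_target: str | float = "median_depth",
    log1p: bool = True,
    pca_dim: int | None = None,
) -> ExpressionMatrix:
    """Depth-normalize, log-transform and optionally PCA-reduce counts.

    Each cell's counts are scaled so its total equals the target depth
    (``"median_depth"`` for the median total count across cells, or an
    explicit number), then ``log(1+x)`` is applied if ``log1p``, then an
    optional PCA projection to ``pca_dim`` components. Every step is
    recorded in the provenance.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ConfigurationError("empty count matrix")
    x = counts.counts.astype(float)
    depths = x.sum(axis=1)
    zero = np.flatnonzero(depths == 0)
    if zero.size:
        raise ConfigurationError(
            f"cell(s) with zero total count: {', '.join(counts.cell_ids[i] for i in zero[:5])}"
        )
    if normalize_target == "median_depth":
        target = float(np.median(depths))
    else:
        target = float(normalize_target)
        if target <= 0:
            raise ConfigurationError("normalization target must be positive")

    x = x * (target / depths)[:, None]
    prov: list[dict] = [{"step": "normalize", "target": target}]
    if log1p:
        x = np.log1p(x)
        prov.append({"step": "log1p", "base": "e"})
    if pca_dim is not None:
        if not 0 < pca_dim < min(x.shape):
            raise ConfigurationError("pca_dim must satisfy 0 < pca_dim < min(n_cells, n_genes)")
        x = _pca_project(x, pca_dim)
        prov.append({"step": "pca", "dim": int(pca_dim)})
    return ExpressionMatrix(
        values=x, provenance=tuple(prov), cell_ids=list(counts.cell_ids), labels=counts.labels
    )


def _pca_project(x: np.ndarray, dim: int) -> np.ndarray:
    """Deterministic PCA projection via eigendecomposition of the Gram form."""
    xc = x - x.mean(axis=0)
    n, d = xc.shape
    if d <= n:
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        comps = v[:, ::-1][:, :dim]  # eigh returns ascending order
        # sign convention: largest-|loading| entry positive
        for j in range(comps.shape[1]):
            i = int(np.argmax(np.abs(comps[:, j])))
            if comps[i, j] < 0:
                comps[:, j] = -comps[:, j]
        return xc @ comps
    gram = xc @ xc.T
    w, u = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:dim]
    scores = u[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


# ---------------------------------------------------------------------------
# On-disk formats
#
# MTX layout: <prefix>.mtx (cells x genes sparse), <prefix>.cells.tsv
# (columns cell_id [label]), <prefix>.genes.tsv (column gene_id).
# Dense layout: one TSV, header row = gene ids, first column cell_id,
# optional companion label file with one label per cell line.
# ---------------------------------------------------------------------------


def write_counts(counts: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(counts.counts)
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, sparse, field="integer")
        path.with_suffix(".mtx").write_bytes(buf.getvalue())
        cells = pd.DataFrame({"cell_id": counts.cell_ids})
        if counts.labels is not None:
            cells["label"] = counts.labels
        cells.to_csv(path.with_suffix(".cells.tsv"), sep="\t", index=False)
        pd.DataFrame({"gene_id": counts.gene_ids}).to_csv(
            path.with_suffix(".genes.tsv"), sep="\t", index=False
        )
    elif format == "tsv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(counts.counts, index=counts.cell_ids, columns=counts.gene_ids)
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")
        if counts.labels is not None:
            Path(str(path) + ".labels").write_text("\n".join(counts.labels) + "\n")
    else:
        raise FormatError(f"unknown format {format!r}; use 'mtx' or 'tsv'")


def read_counts(path: str | Path, format: str = "mtx") -> CountMatrix:
    path = Path(path)
    if format == "mtx":
        mat = scipy.io.mmread(path.with_suffix(".mtx"))
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        if np.any(dense < 0):
            bad = np.argwhere(dense < 0)[0]
            raise FormatError(
                f"negative count at cell {bad[0] + 1}, gene {bad[1] + 1} in {path.with_suffix('.mtx')}"
            )
        dense = dense.astype(np.int64)
        cells = pd.read_csv(path.with_suffix(".cells.tsv"), sep="\t", dtype=str)
        genes = pd.read_csv(path.with_suffix(".genes.tsv"), sep="\t", dtype=str)
        if len(cells) != dense.shape[0]:
            raise FormatError(
                f"{path.with_suffix('.cells.tsv')}: {len(cells)} cells listed "
                f"(lines 2-{len(cells) + 1}) but matrix has {dense.shape[0]} rows"
            )
        if len(genes) != dense.shape[1]:
            raise FormatError(
                f"{path.with_suffix('.genes.tsv')}: {len(genes)} genes listed "
                f"(lines 2-{len(genes) + 1}) but matrix has {dense.shape[1]} columns"
            )
        labels = cells["label"].tolist() if "label" in cells.columns else None
        return CountMatrix(
            counts=dense,
            cell_ids=cells["cell_id"].tolist(),
            gene_ids=genes["gene_id"].tolist(),
            labels=labels,
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(f"negative count at line {i + 2}, column {j + 2} in {path}")
        labels = None
        label_path = Path(str(path) + ".labels")
        if label_path.exists():
            labels = label_path.read_text().splitlines()
            if len(labels) != len(df):
                raise FormatError(
                    f"{label_path}: {len(labels)} label lines for {len(df)} cells"
                )
        return CountMatrix(
            counts=values.astype(np.int64),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
            labels=labels,
        )
    raise FormatError(f"unknown format {format!r}; use 'mtx' or 'tsv'")


def with_labels(counts: CountMatrix, labels: list[str]) -> CountMatrix:
    """Return a copy of ``counts`` with per-cell labels attached."""
    return replace(counts, labels=list(labels))
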