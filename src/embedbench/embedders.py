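"""The four compared 2D embeddings: PCA, t-SNE, UMAP, and a shape embedder.

PCA is computed in closed form with a fixed sign convention. t-SNE and
UMAP delegate to scikit-learn and umap-learn with library-default
hyperparameters and a caller-supplied seed. The shape-constrained
embedder is an adversarial baseline: an autoencoder whose 2D bottleneck
codes are pulled onto an arbitrary target contour (circle, two moons, or
an elephant outline) by a symmetric Chamfer loss, regardless of the data's
actual structure. It exists to show that a visually striking 2D layout can
score well on distance-preservation metrics while carrying almost no class
information.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from embedbench.data import ExpressionMatrix


class EmbeddingError(ValueError):
    pass


@dataclass
class Embedding2D:
    """n x 2 coordinates tagged with method, seed and run index.

    Row ``i`` always corresponds to input cell ``i``. ``source_fingerprint``
    is a SHA-1 of the input expression values, so an embedding can be
    matched to the representation it was computed from.
    """

    coords: np.ndarray
    method: str
    seed: int = 0
    run_index: int = 0
    source_fingerprint: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise EmbeddingError("coords must be n x 2")
        if not np.all(np.isfinite(self.coords)):
            raise EmbeddingError("coords must be finite")


@dataclass
class ShapeSpec:
    """Ordered 2D contour samples with a cached diameter."""

    points: np.ndarray
    name: str = "shape"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or self.points.shape[0] < 1:
            raise EmbeddingError("shape points must be m x 2 with m >= 1")
        if not np.all(np.isfinite(self.points)):
            raise EmbeddingError("shape points must be finite")
        self._diameter = None

    @property
    def diameter(self) -> float:
        """Maximum pairwise distance between contour points."""
        if self._diameter is None:
            if len(self.points) < 2:
                self._diameter = 0.0
            else:
                d2 = ((self.points[:, None, :] - self.points[None, :, :]) ** 2).sum(-1)
                self._diameter = float(np.sqrt(d2.max()))
        return self._diameter


@dataclass(frozen=True)
class ShapeEmbedConfig:
    """Training configuration for the shape-constrained autoencoder.

    ``shape_weight`` balances the symmetric Chamfer shape loss against the
    mean-squared reconstruction error; larger values collapse the codes
    onto the contour more aggressively.
    """

    hidden_widths: tuple[int, ...] = (128, 32)
    shape_weight: float = 20.0
    epochs: int = 150
    learning_rate: float = 3e-3
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise EmbeddingError("epochs must be >= 1")
        if self.shape_weight <= 0 or self.learning_rate <= 0 or self.batch_size < 1:
            raise EmbeddingError("shape_weight, learning_rate, batch_size must be positive")


def _fingerprint(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(x, dtype=np.float64).tobytes()).hexdigest()[:16]


def _values(x: ExpressionMatrix | np.ndarray) -> np.ndarray:
    v = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(v)):
        raise EmbeddingError("non-finite values in embedder input")
    return v


def embed_pca2(x: ExpressionMatrix | np.ndarray) -> Embedding2D:
    """Project onto the top-2 principal axes of the mean-centered data.

    Deterministic: each axis is oriented so that its largest-magnitude
    loading is positive. Raises on inputs with fewer than two nonzero
    directions of variance.
    """
    v = _values(x)
    n, d = v.shape
    if n < 3 or d < 2:
        raise EmbeddingError("PCA needs >= 3 cells and >= 2 features")
    vc = v - v.mean(axis=0)
    cov = vc.T @ vc if d <= n else None
    if cov is not None:
        w, vecs = np.linalg.eigh(cov)
        w, vecs = w[::-1], vecs[:, ::-1]
        if w[1] <= max(n, d) * np.finfo(float).eps * max(w[0], 1.0):
            raise EmbeddingError("input has < 2 nonzero singular values")
        comps = vecs[:, :2]
        for j in range(2):
            i = int(np.argmax(np.abs(comps[:, j])))
            if comps[i, j] < 0:
                comps[:, j] = -comps[:, j]
        coords = vc @ comps
    else:
        u, s, vt = np.linalg.svd(vc, full_matrices=False)
        if s[1] <= max(n, d) * np.finfo(float).eps * max(s[0], 1.0):
            raise EmbeddingError("input has < 2 nonzero singular values")
        comps = vt[:2].T
        for j in range(2):
            i = int(np.argmax(np.abs(comps[:, j])))
            if comps[i, j] < 0:
                comps[:, j] = -comps[:, j]
        coords = vc @ comps
    return Embedding2D(coords=coords, method="pca", seed=0, source_fingerprint=_fingerprint(v))


def embed_tsne(x: ExpressionMatrix | np.ndarray, seed: int = 0, run_index: int = 0, **kwargs) -> Embedding2D:
    """t-SNE via scikit-learn with default hyperparameters unless overridden."""
    v = _values(x)
    if v.shape[0] < 10:
        raise EmbeddingError("t-SNE needs >= 10 cells")
    from sklearn.manifold import TSNE

    params = dict(n_components=2, random_state=seed, n_jobs=1)
    params.update(kwargs)
    coords = TSNE(**params).fit_transform(v)
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        method="tsne",
        seed=seed,
        run_index=run_index,
        source_fingerprint=_fingerprint(v),
    )


def embed_umap(x: ExpressionMatrix | np.ndarray, seed: int = 0, run_index: int = 0, **kwargs) -> Embedding2D:
    """UMAP via umap-learn with default hyperparameters unless overridden."""
    v = _values(x)
    if v.shape[0] < 10:
        raise EmbeddingError("UMAP needs >= 10 cells")
    import umap

    params = dict(n_components=2, random_state=seed)
    params.update(kwargs)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs value.*")
        coords = umap.UMAP(**params).fit_transform(v)
    return Embedding2D(
        coords=np.asarray(coords, dtype=float),
        method="umap",
        seed=seed,
        run_index=run_index,
        source_fingerprint=_fingerprint(v),
    )


# ---------------------------------------------------------------------------
# Target shapes
# ---------------------------------------------------------------------------

# Truncated-Fourier elephant outline (the classic four-parameter contour),
# scaled to roughly unit size. Versioned fixture: v1.
_ELEPHANT_SCALE = 0.01


def _elephant_xy(t: np.ndarray) -> np.ndarray:
    x = -60.0 * np.cos(t) + 30.0 * np.sin(t) - 8.0 * np.sin(2 * t) + 10.0 * np.sin(3 * t)
    y = 50.0 * np.sin(t) + 18.0 * np.sin(2 * t) - 12.0 * np.cos(3 * t) + 14.0 * np.cos(5 * t)
    return _ELEPHANT_SCALE * np.stack([x, y], axis=-1)


def make_shape(name: str, m: int = 100) -> ShapeSpec:
    """Return ``m`` ordered contour points for a named target shape.

    Available: ``circle`` (unit circle), ``two_moons`` (two interleaved
    half-circles), ``elephant`` (fixed truncated-Fourier outline).
    """
    if m < 3:
        raise EmbeddingError("need m >= 3 contour points")
    if name == "circle":
        t = 2 * np.pi * np.arange(m) / m
        pts = np.stack([np.cos(t), np.sin(t)], axis=1)
    elif name == "two_moons":
        m1 = m // 2
        m2 = m - m1
        t1 = np.pi * np.arange(m1) / max(m1 - 1, 1)
        t2 = np.pi * np.arange(m2) / max(m2 - 1, 1)
        outer = np.stack([np.cos(t1), np.sin(t1)], axis=1)
        inner = np.stack([1.0 - np.cos(t2), 0.5 - np.sin(t2)], axis=1)
        pts = np.vstack([outer, inner])
    elif name == "elephant":
        t = 2 * np.pi * np.arange(m) / m
        pts = _elephant_xy(t)
    else:
        raise EmbeddingError(
            f"unknown shape {name!r}; available: circle, two_moons, elephant"
        )
    return ShapeSpec(points=pts, name=name)


# ---------------------------------------------------------------------------
# Shape-constrained autoencoder
# ---------------------------------------------------------------------------


class _AdamMLP:
    """Tanh MLP autoencoder with a 2D bottleneck, trained by hand with Adam.

    Layers: d -> hidden_widths -> 2 -> reversed(hidden_widths) -> d; the
    bottleneck and output layers are linear, all others tanh.
    """

    def __init__(self, d: int, hidden: tuple[int, ...], rng: np.random.Generator):
        widths = [d, *hidden, 2, *reversed(hidden), d]
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-scale, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.code_layer = len(hidden)  # index of the layer producing the 2D code
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]
        self._t = 0

    def forward(self, x: np.ndarray):
        acts = [x]
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i not in (self.code_layer, last):
                h = np.tanh(h)
            acts.append(h)
        return acts  # acts[code_layer + 1] is the 2D code, acts[-1] the reconstruction

    def backward(self, acts, d_out: np.ndarray, d_code: np.ndarray):
        """Backprop given gradients w.r.t. reconstruction and code."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        last = len(self.W) - 1
        delta = d_out
        for i in range(last, -1, -1):
            if i not in (self.code_layer, last):
                delta = delta * (1.0 - acts[i + 1] ** 2)  # tanh'
            if i == self.code_layer:
                delta = delta + d_code
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return gW, gb

    def step(self, gW, gb, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        params = self.W + self.b
        grads = gW + gb
        for k, (p, g) in enumerate(zip(params, grads)):
            self._m[k] = beta1 * self._m[k] + (1 - beta1) * g
            self._v[k] = beta2 * self._v[k] + (1 - beta2) * g * g
            mhat = self._m[k] / (1 - beta1**self._t)
            vhat = self._v[k] / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[self.code_layer + 1]


def _chamfer_sq(codes: np.ndarray, shape_pts: np.ndarray):
    """Squared symmetric Chamfer distance and its gradient w.r.t. codes.

    codes->shape attracts every code to the contour; shape->codes forces
    the codes to cover the whole contour.
    """
    diff = codes[:, None, :] - shape_pts[None, :, :]  # (n, m, 2)
    d2 = (diff**2).sum(-1)
    nearest_shape = d2.argmin(axis=1)  # per code
    nearest_code = d2.argmin(axis=0)  # per shape point
    n, m = d2.shape
    fwd = d2[np.arange(n), nearest_shape].mean()
    bwd = d2[nearest_code, np.arange(m)].mean()
    grad = 2.0 * (codes - shape_pts[nearest_shape]) / n
    np.add.at(grad, nearest_code, 2.0 * (codes[nearest_code] - shape_pts) / m)
    return fwd + bwd, grad


def fit_shape_embedding(
    x: ExpressionMatrix | np.ndarray,
    shape: ShapeSpec,
    config: ShapeEmbedConfig | None = None,
) -> Embedding2D:
    """Train the shape-constrained autoencoder and return the final codes.

    Minimizes ``MSE(x, reconstruction) + shape_weight * Chamfer(codes,
    shape.points)`` by mini-batch Adam. Seeded: same input, shape and
    config give identical coordinates. If the final mean nearest-contour
    distance exceeds 5% of the shape diameter a non-convergence warning is
    recorded (in ``extras`` and as a Python warning), not a hard failure.
    """
    config = config or ShapeEmbedConfig()
    v = _values(x)
    n, d = v.shape
    if n < config.batch_size:
        raise EmbeddingError("need n cells >= batch_size")
    # standardize features so the reconstruction term is scale-free
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (v - mu) / sd

    rng = np.random.default_rng(config.seed)
    net = _AdamMLP(d, tuple(config.hidden_widths), rng)
    shape_pts = shape.points
    log: list[dict] = []
    for epoch in range(config.epochs):
        # cosine decay damps late-training Adam jitter so codes settle on the contour
        lr = config.learning_rate * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * epoch / config.epochs)))
        order = rng.permutation(n)
        recon_sum = 0.0
        chamfer_sum = 0.0
        n_batches = 0
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = xs[idx]
            acts = net.forward(xb)
            codes = acts[net.code_layer + 1]
            xhat = acts[-1]
            resid = xhat - xb
            recon = float((resid**2).mean())
            d_out = 2.0 * resid / resid.size
            if len(shape_pts) == 1:
                delta = codes - shape_pts[0]
                chamfer = float((delta**2).sum(-1).mean())
                d_code = config.shape_weight * 2.0 * delta / len(codes)
            else:
                chamfer, grad = _chamfer_sq(codes, shape_pts)
                d_code = config.shape_weight * grad
            gW, gb = net.backward(acts, d_out, d_code)
            net.step(gW, gb, lr)
            recon_sum += recon
            chamfer_sum += chamfer
            n_batches += 1
        log.append(
            {
                "epoch": epoch,
                "recon": recon_sum / n_batches,
                "chamfer": chamfer_sum / n_batches,
            }
        )

    codes = net.encode(xs)
    diff = codes[:, None, :] - shape_pts[None, :, :]
    nearest = np.sqrt((diff**2).sum(-1)).min(axis=1)
    mean_dist = float(nearest.mean())
    scale = shape.diameter if shape.diameter > 0 else float(np.sqrt((xs**2).mean()))
    converged = mean_dist <= 0.05 * scale
    if not converged:
        warnings.warn(
            f"shape embedding did not converge: mean nearest-contour distance "
            f"{mean_dist:.4f} > 5% of shape diameter {scale:.4f}",
            stacklevel=2,
        )
    return Embedding2D(
        coords=codes,
        method="shape",
        seed=config.seed,
        source_fingerprint=_fingerprint(v),
        extras={
            "shape_name": shape.name,
            "mean_nearest_shape_distance": mean_dist,
            "shape_diameter": shape.diameter,
            "converged": converged,
            "training_log": log,
        },
    )
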