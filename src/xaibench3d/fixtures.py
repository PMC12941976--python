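"""Synthetic 3D data with known class-relevant structure, plus tiny
deterministic model adapters.

The generators emulate the three benchmark modalities at desk scale: noisy
volumes with a class-specific Gaussian blob, binary occupancy grids of
geometric primitives (cube, sphere shell, cross), and clustered point
clouds inside the unit sphere with uniform clutter.  Every sample comes
with a ground-truth mask of its class-determining region so faithfulness
properties are testable without external datasets.

The adapters are small NumPy models with analytic gradients, validated by
central finite differences: a linear-score oracle (closed-form attribution
targets), a one-layer 3D CNN, a Gaussian-kernel set-abstraction point
model, and an attention-gated CNN exposing two named soft masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression

from .core import ConfigurationError, ModelAdapter, Sample3D, ValidationError


class FixtureError(RuntimeError):
    """A fixture self-test (e.g. finite-difference gradient check) failed."""


@dataclass
class FixtureSpec:
    """Generation parameters for one synthetic dataset.

    Grids default to 16^3 and clouds to 128 points so a full benchmark run
    completes in minutes on one CPU; larger shapes remain configurable.
    """

    modality: str = "volumetric"
    n_classes: int = 3
    samples_per_class: int = 10
    grid_shape: tuple = (16, 16, 16)
    n_points: int = 128
    noise: float = 0.1
    blob_sigma: float = 2.0
    cluster_fraction: float = 0.75
    cluster_std: float = 0.08
    seed: int = 0
    #: seed of the class-defining layout (blob sites, cluster templates);
    #: defaults to ``seed``.  Keep it fixed when drawing train/test sets of
    #: the same classification task with different sampling seeds.
    layout_seed: int | None = None

    @property
    def effective_layout_seed(self) -> int:
        return self.seed if self.layout_seed is None else self.layout_seed


# ---------------------------------------------------------------------------
# generators


def _blob(shape, center, sigma, amplitude=1.0, support=2.5):
    """Compactly supported Gaussian bump: exactly zero beyond support*sigma."""
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    bump = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    bump[d2 > (support * sigma) ** 2] = 0.0
    return bump


def gen_blob_volumes(spec: FixtureSpec):
    """Noisy volumes whose class is a Gaussian blob at a class-specific site.

    The ground-truth mask is the blob support above half maximum.  With
    zero noise, voxels outside the blob support equal the background
    constant exactly.
    """
    shape = tuple(spec.grid_shape)
    if 2 * spec.blob_sigma * 2.5 >= min(shape):
        raise ValidationError(
            f"blob of sigma {spec.blob_sigma} does not fit grid {shape}"
        )
    # keep the half-maximum core inside the grid; the faint outer support
    # may clip at the border without affecting the class-defining region
    margin = spec.blob_sigma * 1.5
    rng_layout = np.random.default_rng(spec.effective_layout_seed)
    # rejection-sample well-separated class sites so classes do not overlap
    min_dist = 2.0 * spec.blob_sigma * np.sqrt(2 * np.log(2)) + 1.0
    centers = []
    for _ in range(10_000):
        cand = rng_layout.uniform(margin, np.array(shape) - 1 - margin, size=3)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        if len(centers) == spec.n_classes:
            break
    else:
        raise ValidationError(
            f"could not place {spec.n_classes} separated blobs in grid {shape}"
        )
    centers = np.array(centers)
    rng = np.random.default_rng(spec.seed + 1)
    samples, masks = [], []
    for c in range(spec.n_classes):
        for i in range(spec.samples_per_class):
            jitter = rng.uniform(-1.0, 1.0, size=3)
            center = np.clip(centers[c] + jitter, margin, np.array(shape) - 1 - margin)
            bump = _blob(shape, center, spec.blob_sigma)
            data = bump + spec.noise * rng.standard_normal(shape)
            mask = bump >= 0.5 * bump.max()
            samples.append(
                Sample3D(f"blob-c{c}-{i:03d}", "volumetric", data, true_label=c)
            )
            masks.append(mask)
    return samples, masks


def _primitive(kind: str, shape, center, rng) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    dx, dy, dz = (g - c for g, c in zip(grids, center))
    if kind == "cube":
        occ = (np.abs(dx) <= 3.5) & (np.abs(dy) <= 3.5) & (np.abs(dz) <= 3.5)
    elif kind == "shell":
        d = np.sqrt(dx**2 + dy**2 + dz**2)
        occ = np.abs(d - 4.0) <= 1.0
    elif kind == "cross":
        bar = 1.5
        occ = (
            ((np.abs(dx) <= 5.0) & (np.abs(dy) <= bar) & (np.abs(dz) <= bar))
            | ((np.abs(dy) <= 5.0) & (np.abs(dx) <= bar) & (np.abs(dz) <= bar))
            | ((np.abs(dz) <= 5.0) & (np.abs(dx) <= bar) & (np.abs(dy) <= bar))
        )
    else:  # pragma: no cover
        raise ValidationError(f"unknown primitive {kind!r}")
    return occ.astype(float)


VOXEL_PRIMITIVES = ("cube", "shell", "cross")


def gen_voxel_objects(spec: FixtureSpec):
    """Binary occupancy grids of geometric primitives with jittered pose.

    Three classes are available (cube, sphere shell, three-bar cross); the
    mask equals the occupancy itself.
    """
    if spec.n_classes > len(VOXEL_PRIMITIVES):
        raise ValidationError(
            f"voxel fixture supports at most {len(VOXEL_PRIMITIVES)} classes"
        )
    shape = tuple(spec.grid_shape)
    if min(shape) < 14:
        raise ValidationError("voxel primitives need a grid of at least 14 per axis")
    rng = np.random.default_rng(spec.seed + 2)
    mid = (np.array(shape) - 1) / 2.0
    samples, masks = [], []
    for c in range(spec.n_classes):
        for i in range(spec.samples_per_class):
            center = mid + rng.integers(-2, 3, size=3)
            occ = _primitive(VOXEL_PRIMITIVES[c], shape, center, rng)
            samples.append(
                Sample3D(f"vox-c{c}-{i:03d}", "voxel", occ, true_label=c)
            )
            masks.append(occ.astype(bool))
    return samples, masks


def gen_point_clusters(spec: FixtureSpec):
    """Clustered point clouds in the unit sphere with uniform clutter.

    Class c places c+1 Gaussian clusters at class-specific template
    locations; a ``cluster_fraction`` of the points belong to clusters and
    the rest are uniform clutter.  Coordinates are normalized so every
    point has norm <= 1.  The mask marks cluster membership.
    """
    rng_layout = np.random.default_rng(spec.effective_layout_seed + 3)
    templates = []
    for c in range(spec.n_classes):
        k = c + 1
        centers = rng_layout.standard_normal((k, 3))
        centers *= 0.6 / np.maximum(np.linalg.norm(centers, axis=1, keepdims=True), 1e-9)
        templates.append(centers)
    rng = np.random.default_rng(spec.seed + 4)
    n = spec.n_points
    n_cluster = round(spec.cluster_fraction * n)
    samples, masks = [], []
    for c in range(spec.n_classes):
        centers = templates[c]
        k = centers.shape[0]
        for i in range(spec.samples_per_class):
            counts = np.full(k, n_cluster // k)
            counts[: n_cluster % k] += 1
            pts = []
            for j in range(k):
                pts.append(
                    centers[j] + spec.cluster_std * rng.standard_normal((counts[j], 3))
                )
            clutter = rng.standard_normal((n - n_cluster, 3))
            radii = rng.uniform(0, 1, size=n - n_cluster) ** (1 / 3)
            clutter = clutter / np.maximum(
                np.linalg.norm(clutter, axis=1, keepdims=True), 1e-9
            ) * radii[:, None]
            pts.append(clutter)
            coords = np.vstack(pts)
            norm_max = np.linalg.norm(coords, axis=1).max()
            if norm_max > 1.0:
                coords = coords / norm_max
            mask = np.zeros(n, dtype=bool)
            mask[:n_cluster] = True
            samples.append(
                Sample3D(f"pts-c{c}-{i:03d}", "pointcloud", coords, true_label=c)
            )
            masks.append(mask)
    return samples, masks


def generate(spec: FixtureSpec):
    """Dispatch to the generator for ``spec.modality``."""
    if spec.modality == "volumetric":
        return gen_blob_volumes(spec)
    if spec.modality == "voxel":
        return gen_voxel_objects(spec)
    if spec.modality == "pointcloud":
        return gen_point_clusters(spec)
    raise ValidationError(f"unknown modality {spec.modality!r}")


# ---------------------------------------------------------------------------
# conv machinery (shared by the grid adapters)


def _conv3d(x, W, b, stride):
    win = sliding_window_view(x, W.shape[1:])[::stride, ::stride, ::stride]
    return np.einsum("dhwxyz,cxyz->cdhw", win, W) + b[:, None, None, None]


def _conv3d_backward_input(go, W, x_shape, stride):
    gx = np.zeros(x_shape)
    C = W.shape[0]
    d, h, w = go.shape[1:]
    for c in range(C):
        for a in range(W.shape[1]):
            for bb in range(W.shape[2]):
                for cc in range(W.shape[3]):
                    gx[
                        a : a + d * stride : stride,
                        bb : bb + h * stride : stride,
                        cc : cc + w * stride : stride,
                    ] += go[c] * W[c, a, bb, cc]
    return gx


def _softmax(z):
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _fit_logreg(features, labels, n_classes):
    """Deterministic linear head fit; returns (W, b) for all n_classes."""
    X = np.asarray(features)
    y = np.asarray(labels)
    clf = LogisticRegression(max_iter=2000, random_state=0, C=10.0)
    clf.fit(X, y)
    W = np.zeros((n_classes, X.shape[1]))
    b = np.zeros(n_classes)
    if len(clf.classes_) == 2 and clf.coef_.shape[0] == 1:
        c0, c1 = (int(v) for v in clf.classes_)
        W[c1] = clf.coef_[0]
        b[c1] = clf.intercept_[0]
    else:
        for row, cls in enumerate(clf.classes_):
            W[int(cls)] = clf.coef_[row]
            b[int(cls)] = clf.intercept_[row]
    return W, b


class LinearAdapter(ModelAdapter):
    """Single-score linear model f(x) = sum(w * x): the closed-form oracle.

    The confidence *is* the raw score, so every linearity identity
    (saliency = |w|, IG = w * x, single-element occlusion = w * x) holds
    exactly on this adapter.
    """

    def __init__(self, weights: np.ndarray):
        self.weights = np.asarray(weights, dtype=float)

    @property
    def n_classes(self) -> int:
        return 1

    def raw_score(self, x):
        return np.array([float(np.sum(self.weights * np.asarray(x, dtype=float)))])

    def score(self, x):
        return self.raw_score(x)

    def gradient(self, x, class_index):
        if class_index != 0:
            raise ConfigurationError("linear adapter has a single output")
        return self.weights.copy()


class TinyConvAdapter(ModelAdapter):
    """One 3D conv layer (seeded random filters), ReLU, linear head.

    ``head="flatten"`` (default) classifies on all spatial activations so
    location-coded classes are separable; ``head="gap"`` uses global average
    pooling, the textbook Grad-CAM topology used in the hand-derived chain
    rule checks.  ``score`` returns softmax probabilities; ``gradient``
    differentiates the raw class logit.
    """

    LAYER = "conv1"

    def __init__(self, input_shape=(16, 16, 16), n_classes=3, channels=8,
                 kernel=3, stride=2, head="flatten", seed=0,
                 head_weights=None, head_bias=None):
        if head not in ("flatten", "gap"):
            raise ValidationError("head must be 'flatten' or 'gap'")
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        self.stride = stride
        self.head = head
        self._n_classes = n_classes
        self.Wc = rng.standard_normal((channels, kernel, kernel, kernel)) / np.sqrt(
            kernel**3
        )
        self.bc = np.zeros(channels)
        self.out_shape = tuple(
            (s - kernel) // stride + 1 for s in self.input_shape
        )
        n_spatial = int(np.prod(self.out_shape))
        n_feat = channels if head == "gap" else channels * n_spatial
        self.Wh = (
            np.asarray(head_weights, dtype=float)
            if head_weights is not None
            else rng.standard_normal((n_classes, n_feat)) / np.sqrt(n_feat)
        )
        self.bh = (
            np.asarray(head_bias, dtype=float)
            if head_bias is not None
            else np.zeros(n_classes)
        )

    @property
    def n_classes(self) -> int:
        return self._n_classes

    def features(self, x):
        act = np.maximum(_conv3d(np.asarray(x, dtype=float), self.Wc, self.bc,
                                 self.stride), 0.0)
        if self.head == "gap":
            return act.mean(axis=(1, 2, 3))
        return act.ravel()

    def raw_score(self, x):
        return self.Wh @ self.features(x) + self.bh

    def score(self, x):
        return _softmax(self.raw_score(x))

    def _backward(self, x, class_index):
        x = np.asarray(x, dtype=float)
        pre = _conv3d(x, self.Wc, self.bc, self.stride)
        act = np.maximum(pre, 0.0)
        if self.head == "gap":
            n_spatial = act[0].size
            g_act = (self.Wh[class_index][:, None, None, None] / n_spatial) * np.ones_like(act)
        else:
            g_act = self.Wh[class_index].reshape(act.shape)
        g_pre = g_act * (pre > 0.0)
        return act, g_act, g_pre

    def gradient(self, x, class_index):
        _, _, g_pre = self._backward(x, class_index)
        return _conv3d_backward_input(g_pre, self.Wc, np.asarray(x).shape, self.stride)

    def layer_forward_backward(self, x, class_index, layer_name):
        if layer_name != self.LAYER:
            raise ConfigurationError(f"no layer named {layer_name!r}")
        act, g_act, _ = self._backward(x, class_index)
        return act, g_act

    def fit(self, datas, labels):
        feats = [self.features(d) for d in datas]
        self.Wh, self.bh = _fit_logreg(feats, labels, self._n_classes)
        return self


class TinyAttentionAdapter(ModelAdapter):
    """Attention-gated CNN exposing two named soft masks.

    Stage masks soft1 (block factor 2) and soft2 (factor 4) are sigmoids of
    block-averaged input intensity; the classifier is a tiny CNN applied to
    the input gated by the repeated soft2 mask.  Gradients account for the
    mask's dependence on the input (full product rule).
    """

    def __init__(self, input_shape=(16, 16, 16), n_classes=3, channels=8,
                 seed=0, gain=(3.0, 3.0), bias=(-1.0, -1.0)):
        if any(s % 4 for s in input_shape):
            raise ValidationError("attention adapter needs dims divisible by 4")
        self.input_shape = tuple(input_shape)
        self.gain = gain
        self.bias = bias
        self.inner = TinyConvAdapter(
            input_shape=input_shape, n_classes=n_classes, channels=channels,
            head="flatten", seed=seed + 17,
        )

    @property
    def n_classes(self) -> int:
        return self.inner.n_classes

    @staticmethod
    def _block_mean(x, f):
        d, h, w = x.shape
        return x.reshape(d // f, f, h // f, f, w // f, f).mean(axis=(1, 3, 5))

    @staticmethod
    def _block_sum(x, f):
        d, h, w = x.shape
        return x.reshape(d // f, f, h // f, f, w // f, f).sum(axis=(1, 3, 5))

    @staticmethod
    def _repeat(x, f):
        return np.repeat(np.repeat(np.repeat(x, f, axis=0), f, axis=1), f, axis=2)

    def attention_masks(self, x):
        x = np.asarray(x, dtype=float)
        s1 = 1.0 / (1.0 + np.exp(-(self.gain[0] * self._block_mean(x, 2) + self.bias[0])))
        s2 = 1.0 / (1.0 + np.exp(-(self.gain[1] * self._block_mean(x, 4) + self.bias[1])))
        return {"soft1": s1, "soft2": s2}

    def _gated(self, x):
        m2 = self.attention_masks(x)["soft2"]
        return x * self._repeat(m2, 4), m2

    def raw_score(self, x):
        gated, _ = self._gated(np.asarray(x, dtype=float))
        return self.inner.raw_score(gated)

    def score(self, x):
        return _softmax(self.raw_score(x))

    def gradient(self, x, class_index):
        x = np.asarray(x, dtype=float)
        gated, m2 = self._gated(x)
        g_gated = self.inner.gradient(gated, class_index)
        # product rule: x' = x * repeat(sigmoid(g * blockmean(x) + h))
        term1 = g_gated * self._repeat(m2, 4)
        inner_sum = self._block_sum(g_gated * x, 4)
        term2 = self._repeat(
            inner_sum * m2 * (1.0 - m2) * self.gain[1] / 64.0, 4
        )
        return term1 + term2

    def layer_forward_backward(self, x, class_index, layer_name):
        gated, _ = self._gated(np.asarray(x, dtype=float))
        return self.inner.layer_forward_backward(gated, class_index, layer_name)

    def fit(self, datas, labels):
        gated = [self._gated(np.asarray(d, dtype=float))[0] for d in datas]
        self.inner.fit(gated, labels)
        return self


class TinyPointAdapter(ModelAdapter):
    """Gaussian-kernel set-abstraction point model.

    M fixed seeded centroids inside the unit sphere; channel ch aggregates
    points with bandwidth tau_ch: A[ch, m] = sum_i exp(-|p_i - c_m|^2 /
    (2 tau_ch^2)).  A linear head on the flattened centroid features gives
    the logits.  The "sa2" layer exposes (A, dlogit/dA) and the centroid
    coordinates for point Grad-CAM.
    """

    LAYER = "sa2"

    def __init__(self, n_centroids=8, n_classes=3, taus=(0.2, 0.35, 0.5), seed=0):
        rng = np.random.default_rng(seed)
        c = rng.standard_normal((n_centroids, 3))
        r = rng.uniform(0, 1, n_centroids) ** (1 / 3)
        self.centroids = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-9) * (
            0.7 * r[:, None]
        )
        self.taus = np.asarray(taus, dtype=float)
        self._n_classes = n_classes
        n_feat = len(taus) * n_centroids
        self.Wh = rng.standard_normal((n_classes, n_feat)) / np.sqrt(n_feat)
        self.bh = np.zeros(n_classes)

    @property
    def n_classes(self) -> int:
        return self._n_classes

    def _kernels(self, x):
        d2 = ((np.asarray(x, dtype=float)[:, None, :] - self.centroids[None, :, :]) ** 2).sum(
            axis=2
        )  # (N, M)
        return np.exp(-d2[None, :, :] / (2.0 * self.taus[:, None, None] ** 2))  # (C, N, M)

    def features(self, x):
        return self._kernels(x).sum(axis=1)  # (C, M)

    def raw_score(self, x):
        return self.Wh @ self.features(x).ravel() + self.bh

    def score(self, x):
        return _softmax(self.raw_score(x))

    def gradient(self, x, class_index):
        x = np.asarray(x, dtype=float)
        E = self._kernels(x)  # (C, N, M)
        coeff = self.Wh[class_index].reshape(self.taus.size, -1)  # (C, M)
        # d/dp_i exp(-|p_i - c_m|^2 / (2 tau^2)) = E * (c_m - p_i) / tau^2
        scale = coeff[:, None, :] * E / (self.taus[:, None, None] ** 2)  # (C, N, M)
        diff = self.centroids[None, :, :] - x[:, None, :]  # (N, M, 3)
        return np.einsum("cnm,nmk->nk", scale, diff)

    def layer_forward_backward(self, x, class_index, layer_name):
        if layer_name != self.LAYER:
            raise ConfigurationError(f"no layer named {layer_name!r}")
        A = self.features(x)
        gA = self.Wh[class_index].reshape(A.shape)
        return A, gA

    def layer_coordinates(self, x, layer_name):
        if layer_name != self.LAYER:
            raise ConfigurationError(f"no layer named {layer_name!r}")
        return self.centroids.copy()

    def fit(self, datas, labels):
        feats = [self.features(d).ravel() for d in datas]
        self.Wh, self.bh = _fit_logreg(feats, labels, self._n_classes)
        return self


def check_gradients(adapter, x, class_index=0, eps=1e-5, tol=1e-4):
    """Central finite-difference check of the adapter's analytic gradient.

    Probes a deterministic subset of elements; raises :class:`FixtureError`
    on mismatch beyond ``tol``.
    """
    x = np.asarray(x, dtype=float)
    score_fn = getattr(adapter, "raw_score", adapter.score)
    g = np.asarray(adapter.gradient(x, class_index))
    flat = x.ravel()
    n = flat.size
    probe = np.linspace(0, n - 1, num=min(24, n), dtype=int)
    worst = 0.0
    for idx in probe:
        xp = flat.copy()
        xm = flat.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd = (
            float(score_fn(xp.reshape(x.shape))[class_index])
            - float(score_fn(xm.reshape(x.shape))[class_index])
        ) / (2 * eps)
        worst = max(worst, abs(fd - g.ravel()[idx]))
    if worst > tol:
        raise FixtureError(
            f"finite-difference gradient mismatch {worst:.2e} exceeds {tol:.0e}"
        )
    return worst


def make_adapter(modality: str, spec: FixtureSpec, kind: str = "auto") -> ModelAdapter:
    """Default untrained adapter for a modality: attention-gated CNN for
    grids (supports all five methods), point model for clouds."""
    if modality == "pointcloud":
        return TinyPointAdapter(n_classes=spec.n_classes, seed=spec.seed)
    if kind == "conv":
        return TinyConvAdapter(
            input_shape=spec.grid_shape, n_classes=spec.n_classes, seed=spec.seed
        )
    return TinyAttentionAdapter(
        input_shape=spec.grid_shape, n_classes=spec.n_classes, seed=spec.seed
    )


def make_benchmark_world(
    spec: FixtureSpec,
    adapter_kind: str = "auto",
    train_samples_per_class: int | None = None,
):
    """Generate a labelled pool, train an adapter on a disjoint seeded
    training set, and fill in the pool's predicted labels.

    The training set shares the class layout but uses an independent
    sampling seed; its per-class size defaults to the generator's standard
    10 samples per class regardless of the evaluation pool size, so the
    adapter quality does not degrade for small pools.

    Returns (samples, masks, adapter).
    """
    samples, masks = generate(spec)
    train_spec = replace(
        spec,
        seed=spec.seed + 1000,
        layout_seed=spec.effective_layout_seed,
        samples_per_class=(
            train_samples_per_class
            if train_samples_per_class is not None
            else max(spec.samples_per_class, 10)
        ),
    )
    train_samples, _ = generate(train_spec)
    adapter = make_adapter(spec.modality, spec, adapter_kind)
    adapter.fit([s.data for s in train_samples], [s.true_label for s in train_samples])
    for s in samples:
        s.predicted_label = adapter.predict(s.data)
    return samples, masks, adapter
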