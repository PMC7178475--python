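"""Dual-branch (Siamese) patch network producing the initial weight map.

Two identical branches share one parameter set (sharing is structural: both
branch evaluations read the same arrays).  Each branch applies three 3x3
convolutions (channel widths 16 -> 32 -> 64, rectifier nonlinearity) with a
2x2 max-pool after the second convolution.  The branch features are
concatenated and mapped by a single fully-connected layer to two logits and
a softmax, giving the probability that the *first* input patch is the
high-quality (sharp) one.  A dense weight map over a full image pair is
obtained by sliding a patch window over both images in lockstep, writing
each window's score to all pixels it covers and averaging the overlaps.

The network is trained from scratch on synthetically blurred patches: each
training example is a (sharp, blurred) patch pair in one of the two orders,
labelled 1 when the sharp patch comes first.  Patches are scaled to [0, 1]
before entering the network.  Everything runs on plain NumPy (im2col
convolutions, manual backprop, Adam) and is fully deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

from .nsst import FilterBank, nsst_decompose

__all__ = [
    "PatchNetParams",
    "PatchPairDataset",
    "WeightMaps",
    "make_patch_dataset",
    "init_params",
    "forward_pair",
    "forward_batch",
    "branch_features",
    "train_network",
    "evaluate_accuracy",
    "weight_map",
    "decompose_weight",
    "save_params",
    "load_params",
]

_KSIZE = 3
_CHANNELS = (16, 32, 64)
_FORMAT_VERSION = "nsstfuse-patchnet-v1"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PatchNetParams:
    """All trainable tensors; both branches reference these same arrays."""

    conv_w: list  # [(out, in, 3, 3)] x 3
    conv_b: list  # [(out,)] x 3
    fc_w: np.ndarray  # (2, feat_dim)
    fc_b: np.ndarray  # (2,)
    patch_size: int = 16
    seed: int | None = None
    history: list = field(default_factory=list)  # mean loss per epoch

    def finite(self) -> bool:
        tensors = [*self.conv_w, *self.conv_b, self.fc_w, self.fc_b]
        return all(np.all(np.isfinite(t)) for t in tensors)


@dataclass
class PatchPairDataset:
    """Ordered patch pairs with labels; label 1 = first patch is sharp."""

    first: np.ndarray   # (n, ps, ps) in [0, 1]
    second: np.ndarray  # (n, ps, ps)
    labels: np.ndarray  # (n,) in {0, 1}
    seed: int

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class WeightMaps:
    """Initial weight map W_S and its NSST components."""

    w_s: np.ndarray          # [0, 1], image-sized
    w_s_low: np.ndarray      # full low-frequency component (low1 + low2)
    w_s_high: list           # [level][direction] high-pass bands


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _blur_patch(image, top, left, patch_size, sigma):
    # the blurred class is the degraded version of the patch itself, so a
    # non-constant sharp patch always has the higher variance of the two
    patch = image[top:top + patch_size, left:left + patch_size]
    return gaussian_filter(patch, sigma, mode="reflect")


def make_patch_dataset(
    source_images,
    blur_sigma,
    patch_size: int = 16,
    n_pairs: int = 5000,
    seed: int = 0,
) -> PatchPairDataset:
    """Sample labelled sharp/blurred patch pairs from source images.

    ``blur_sigma`` is either a positive scalar or a ``(lo, hi)`` range from
    which a sigma is drawn uniformly per pair.  Labels are exactly balanced
    (ceil(n/2) ones) and shuffled; label 1 means the sharp patch is first.
    """
    images = [np.asarray(im, dtype=float) for im in source_images]
    if not images:
        raise ValueError("source_images is empty")
    for im in images:
        if min(im.shape) < patch_size:
            raise ValueError(
                f"patch_size {patch_size} exceeds an image dimension "
                f"{im.shape}"
            )
    if np.isscalar(blur_sigma):
        if blur_sigma <= 0:
            raise ValueError(f"blur_sigma must be positive, got {blur_sigma}")
        sigma_range = (float(blur_sigma), float(blur_sigma))
    else:
        lo, hi = (float(blur_sigma[0]), float(blur_sigma[1]))
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid blur sigma range {blur_sigma!r}")
        sigma_range = (lo, hi)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")

    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.arange(n_pairs) % 2).astype(np.int8)
    first = np.empty((n_pairs, patch_size, patch_size))
    second = np.empty_like(first)
    # scale each source to [0, 1] once (8-bit convention)
    scaled = [im / 255.0 for im in images]
    for i in range(n_pairs):
        im = scaled[rng.integers(len(scaled))]
        top = int(rng.integers(im.shape[0] - patch_size + 1))
        left = int(rng.integers(im.shape[1] - patch_size + 1))
        sigma = float(rng.uniform(*sigma_range))
        sharp = im[top:top + patch_size, left:left + patch_size]
        blurred = _blur_patch(im, top, left, patch_size, sigma)
        if labels[i] == 1:
            first[i], second[i] = sharp, blurred
        else:
            first[i], second[i] = blurred, sharp
    return PatchPairDataset(first=first, second=second, labels=labels,
                            seed=seed)


# ---------------------------------------------------------------------------
# layers (im2col convolutions, shared by forward and backward passes)
# ---------------------------------------------------------------------------

def _im2col(x, k):
    # x: (B, C, H, W) -> (B, P, C*k*k) for valid k x k windows
    b, c, h, w = x.shape
    cols = sliding_window_view(x, (k, k), axis=(2, 3))
    cols = cols.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(cols).reshape(b, (h - k + 1) * (w - k + 1),
                                              c * k * k)


def _conv_forward(x, w, b):
    bsz, _, h, wd = x.shape
    out_c, _, k, _ = w.shape
    ho, wo = h - k + 1, wd - k + 1
    cols = _im2col(x, k)
    y = cols @ w.reshape(out_c, -1).T + b
    return y.transpose(0, 2, 1).reshape(bsz, out_c, ho, wo), cols


def _conv_backward(gy, cols, w, x_shape):
    bsz, out_c, ho, wo = gy.shape
    _, in_c, k, _ = w.shape
    g = gy.reshape(bsz, out_c, ho * wo).transpose(0, 2, 1)
    gw = np.einsum("bpo,bpk->ok", g, cols).reshape(w.shape)
    gb = g.sum(axis=(0, 1))
    gpad = np.pad(gy, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    colsg = _im2col(gpad, k)
    wflip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(in_c, -1)
    gx = (colsg @ wflip.T).transpose(0, 2, 1).reshape(x_shape)
    return gx, gw, gb


def _pool_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    return y, xr


def _pool_backward(gy, xr, y):
    mask = xr == y[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    g = mask * (gy[:, :, :, None, :, None] / counts)
    b, c, h2, _, w2, _ = xr.shape
    return g.reshape(b, c, h2 * 2, w2 * 2)


def _branch_forward(x, params, *, want_cache=False):
    """One branch: conv-relu, conv-relu, pool, conv-relu, flatten."""
    caches = []
    a = x
    for layer in range(3):
        z, cols = _conv_forward(a, params.conv_w[layer], params.conv_b[layer])
        r = np.maximum(z, 0.0)
        caches.append((a.shape, cols, z))
        a = r
        if layer == 1:
            pooled, xr = _pool_forward(a)
            caches.append((xr, pooled))
            a = pooled
    feat = a.reshape(a.shape[0], -1)
    if want_cache:
        return feat, (caches, a.shape)
    return feat


def _branch_backward(gfeat, cache, params):
    caches, feat_shape = cache
    g = gfeat.reshape(feat_shape)
    grads_w = [None] * 3
    grads_b = [None] * 3
    # conv3
    x_shape, cols, z = caches[3]
    g = g * (z.reshape(g.shape) > 0)
    g, grads_w[2], grads_b[2] = _conv_backward(g, cols, params.conv_w[2],
                                               x_shape)
    # pool
    xr, pooled = caches[2]
    g = _pool_backward(g, xr, pooled)
    # conv2
    x_shape, cols, z = caches[1]
    g = g * (z.reshape(g.shape) > 0)
    g, grads_w[1], grads_b[1] = _conv_backward(g, cols, params.conv_w[1],
                                               x_shape)
    # conv1
    x_shape, cols, z = caches[0]
    g = g * (z.reshape(g.shape) > 0)
    _, grads_w[0], grads_b[0] = _conv_backward(g, cols, params.conv_w[0],
                                               x_shape)
    return grads_w, grads_b


def _feature_dim(patch_size: int) -> int:
    s = patch_size - 2 - 2  # two valid 3x3 convs
    s //= 2                 # 2x2 pool
    s -= 2                  # third valid conv
    if s < 1:
        raise ValueError(f"patch_size {patch_size} too small for the network")
    return _CHANNELS[2] * s * s


def init_params(patch_size: int = 16, seed: int = 0) -> PatchNetParams:
    """He-initialised parameters for the shared branch plus the head."""
    rng = np.random.default_rng(seed)
    widths = (1,) + _CHANNELS
    conv_w, conv_b = [], []
    for i in range(3):
        fan_in = widths[i] * _KSIZE * _KSIZE
        conv_w.append(rng.normal(
            0.0, np.sqrt(2.0 / fan_in),
            size=(widths[i + 1], widths[i], _KSIZE, _KSIZE)))
        conv_b.append(np.zeros(widths[i + 1]))
    feat = _feature_dim(patch_size)
    fc_w = rng.normal(0.0, np.sqrt(1.0 / (2 * feat)), size=(2, 2 * feat))
    fc_b = np.zeros(2)
    return PatchNetParams(conv_w=conv_w, conv_b=conv_b, fc_w=fc_w, fc_b=fc_b,
                          patch_size=patch_size, seed=seed)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def branch_features(patches: np.ndarray, params: PatchNetParams) -> np.ndarray:
    """Feature vectors of a batch of patches through the shared branch."""
    x = np.asarray(patches, dtype=float)
    if x.ndim == 2:
        x = x[None]
    return _branch_forward(x[:, None, :, :], params)


def forward_batch(first, second, params):
    """Softmax class probabilities for batches of ordered patch pairs."""
    f1 = branch_features(first, params)
    f2 = branch_features(second, params)
    logits = np.concatenate([f1, f2], axis=1) @ params.fc_w.T + params.fc_b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def forward_pair(patch_1, patch_2, params):
    """Class probabilities (p0, p1) for one ordered patch pair.

    p1 is the probability that ``patch_1`` is the high-quality patch.
    """
    p1a = np.asarray(patch_1, dtype=float)
    p2a = np.asarray(patch_2, dtype=float)
    expect = (params.patch_size, params.patch_size)
    if p1a.shape != expect or p2a.shape != expect:
        raise ValueError(
            f"patches must be {expect}, got {p1a.shape} and {p2a.shape}"
        )
    probs = forward_batch(p1a[None], p2a[None], params)[0]
    return float(probs[0]), float(probs[1])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_network(
    dataset: PatchPairDataset,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    seed: int = 0,
    batch_size: int = 64,
) -> PatchNetParams:
    """Train with two-class cross-entropy and Adam; fully seed-deterministic.

    Records the mean loss of each epoch in ``params.history``.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    classes = np.unique(dataset.labels)
    if len(classes) < 2:
        raise ValueError(
            "dataset contains a single class; two-class training is "
            "degenerate"
        )
    params = init_params(patch_size=dataset.first.shape[1], seed=seed)
    rng = np.random.default_rng(seed + 1)

    tensors = [*params.conv_w, *params.conv_b, params.fc_w, params.fc_b]
    m = [np.zeros_like(t) for t in tensors]
    v = [np.zeros_like(t) for t in tensors]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n = len(dataset)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x1 = dataset.first[idx][:, None, :, :]
            x2 = dataset.second[idx][:, None, :, :]
            y = dataset.labels[idx]

            f1, cache1 = _branch_forward(x1, params, want_cache=True)
            f2, cache2 = _branch_forward(x2, params, want_cache=True)
            feats = np.concatenate([f1, f2], axis=1)
            logits = feats @ params.fc_w.T + params.fc_b
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            bsz = len(idx)
            losses.append(
                float(-np.mean(np.log(probs[np.arange(bsz), y] + 1e-12)))
            )

            dlogits = probs.copy()
            dlogits[np.arange(bsz), y] -= 1.0
            dlogits /= bsz
            g_fc_w = dlogits.T @ feats
            g_fc_b = dlogits.sum(axis=0)
            gfeats = dlogits @ params.fc_w
            half = f1.shape[1]
            gw1, gb1 = _branch_backward(gfeats[:, :half], cache1, params)
            gw2, gb2 = _branch_backward(gfeats[:, half:], cache2, params)
            # shared branch: gradients from both inputs accumulate
            grads = [gw1[i] + gw2[i] for i in range(3)]
            grads += [gb1[i] + gb2[i] for i in range(3)]
            grads += [g_fc_w, g_fc_b]

            step += 1
            for t, mt, vt, g in zip(tensors, m, v, grads):
                mt *= beta1
                mt += (1 - beta1) * g
                vt *= beta2
                vt += (1 - beta2) * g * g
                mhat = mt / (1 - beta1 ** step)
                vhat = vt / (1 - beta2 ** step)
                t -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        params.history.append(float(np.mean(losses)))
    return params


def evaluate_accuracy(params: PatchNetParams, dataset: PatchPairDataset,
                      batch_size: int = 256) -> float:
    """Fraction of pairs whose argmax class matches the label."""
    correct = 0
    n = len(dataset)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        probs = forward_batch(dataset.first[sl], dataset.second[sl], params)
        correct += int(np.sum(probs.argmax(axis=1) == dataset.labels[sl]))
    return correct / n


# ---------------------------------------------------------------------------
# weight map
# ---------------------------------------------------------------------------

def weight_map(image_a, image_b, params: PatchNetParams,
               stride: int = 2, batch_size: int = 512) -> np.ndarray:
    """Dense initial weight map W_S in [0, 1], same size as the inputs.

    Slides a patch window over both images in lockstep; each window's p1
    score (probability that ``image_a``'s patch is the high-quality one) is
    written to every pixel of the window and overlapping scores are
    averaged.  Inputs are expected in the [0, 255] domain.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    ps = params.patch_size
    if min(a.shape) < ps:
        raise ValueError(f"images {a.shape} smaller than patch size {ps}")
    if stride < 1:
        raise ValueError("stride must be >= 1")

    an = a / 255.0
    bn = b / 255.0
    rows = list(range(0, a.shape[0] - ps + 1, stride))
    cols = list(range(0, a.shape[1] - ps + 1, stride))
    if rows[-1] != a.shape[0] - ps:
        rows.append(a.shape[0] - ps)
    if cols[-1] != a.shape[1] - ps:
        cols.append(a.shape[1] - ps)

    wa = sliding_window_view(an, (ps, ps))
    wb = sliding_window_view(bn, (ps, ps))
    positions = [(r, c) for r in rows for c in cols]
    acc = np.zeros(a.shape)
    cnt = np.zeros(a.shape)
    for start in range(0, len(positions), batch_size):
        chunk = positions[start:start + batch_size]
        pa = np.stack([wa[r, c] for r, c in chunk])
        pb = np.stack([wb[r, c] for r, c in chunk])
        scores = forward_batch(pa, pb, params)[:, 1]
        for (r, c), s in zip(chunk, scores):
            acc[r:r + ps, c:c + ps] += s
            cnt[r:r + ps, c:c + ps] += 1.0
    return acc / cnt


def decompose_weight(w_s: np.ndarray, fb: FilterBank) -> WeightMaps:
    """NSST-decompose W_S into one low component and per-band high components.

    The low component is the full low-frequency output (low1 + low2
    recombined); the high components mirror the source band structure, and
    being high-pass outputs they may be negative even though W_S is in
    [0, 1].
    """
    w_s = np.asarray(w_s, dtype=float)
    coeffs = nsst_decompose(w_s, fb)
    return WeightMaps(w_s=w_s, w_s_low=coeffs.low1 + coeffs.low2,
                      w_s_high=coeffs.highs)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_params(params: PatchNetParams, path) -> None:
    """Write parameters to a single versioned .npz file."""
    arrays = {"format": np.array(_FORMAT_VERSION),
              "patch_size": np.array(params.patch_size),
              "fc_w": params.fc_w, "fc_b": params.fc_b}
    for i in range(3):
        arrays[f"conv_w{i}"] = params.conv_w[i]
        arrays[f"conv_b{i}"] = params.conv_b[i]
    np.savez(path, **arrays)


def load_params(path) -> PatchNetParams:
    with np.load(path) as data:
        if str(data["format"]) != _FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {str(data['format'])!r} in {path}"
            )
        return PatchNetParams(
            conv_w=[data[f"conv_w{i}"] for i in range(3)],
            conv_b=[data[f"conv_b{i}"] for i in range(3)],
            fc_w=data["fc_w"],
            fc_b=data["fc_b"],
            patch_size=int(data["patch_size"]),
        )
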