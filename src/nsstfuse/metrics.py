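"""Objective fusion-quality metrics.

Six formula-defined scores of a fused image F against its sources A, B:

* MI — sum of the mutual informations (bits, 256-level joint histograms)
  between each source and F;
* MSSIM — mean of the two mean structural similarities SSIM(A,F), SSIM(B,F)
  (11x11 Gaussian window, sigma 1.5, the standard 8-bit constants);
* SD — population standard deviation of F (contrast);
* EI — mean magnitude of the backward-difference gradient field (edge
  intensity);
* AG — average gradient from forward differences with the 1/sqrt(2) scaling
  and full-pixel-count normaliser;
* Q_ncie — nonlinear correlation information entropy: rank-grid nonlinear
  correlation coefficients of the pairs among (A, B, F) assembled into a
  3x3 matrix whose eigenvalue entropy (log base b = 256) is reported.

All are "larger is better" except that MSSIM is capped at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "mutual_information",
    "mi_fusion",
    "ssim",
    "mssim",
    "sd",
    "ei",
    "ag",
    "ncc",
    "qncie",
    "evaluate_all",
]

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_DATA_RANGE = 255.0


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Map an 8-bit-domain image onto integer gray levels 0..levels-1."""
    q = np.floor(np.asarray(img, dtype=float) * levels / 256.0)
    return np.clip(q, 0, levels - 1).astype(np.int64)


def mutual_information(R_img, F_img, levels: int = 256) -> float:
    """MI in bits from the joint gray-level histogram of R and F."""
    R_img = np.asarray(R_img)
    F_img = np.asarray(F_img)
    if R_img.size == 0 or F_img.size == 0:
        raise ValueError("empty image")
    if R_img.shape != F_img.shape:
        raise ValueError(f"shape mismatch: {R_img.shape} vs {F_img.shape}")
    rq = _quantize(R_img, levels).ravel()
    fq = _quantize(F_img, levels).ravel()
    joint = np.bincount(rq * levels + fq, minlength=levels * levels)
    p = joint.astype(float) / joint.sum()
    p = p.reshape(levels, levels)
    pr = p.sum(axis=1)
    pf = p.sum(axis=0)
    nz = p > 0
    outer = pr[:, None] * pf[None, :]
    return float(np.sum(p[nz] * np.log2(p[nz] / outer[nz])))


def mi_fusion(A, B, F, levels: int = 256) -> float:
    """Total fusion information MI(A, F) + MI(B, F), in bits."""
    return mutual_information(A, F, levels) + mutual_information(B, F, levels)


# ---------------------------------------------------------------------------
# structural similarity
# ---------------------------------------------------------------------------

def _gaussian_window(size: int = _SSIM_WIN,
                     sigma: float = _SSIM_SIGMA) -> np.ndarray:
    ax = np.arange(size, dtype=float) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def _valid(arr: np.ndarray, pad: int) -> np.ndarray:
    return arr[pad:-pad, pad:-pad]


def ssim(X, Y, data_range: float = _DATA_RANGE) -> float:
    """Mean SSIM with a Gaussian-weighted sliding window (valid positions).

    Local weighted means/variances/covariance per window position; the
    stabilising constants are C1 = (0.01 * data_range)^2 and
    C2 = (0.03 * data_range)^2.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if min(X.shape) < _SSIM_WIN:
        raise ValueError(
            f"images must be at least {_SSIM_WIN}x{_SSIM_WIN} for the "
            f"SSIM window, got {X.shape}"
        )
    w = _gaussian_window()
    pad = _SSIM_WIN // 2
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2

    def smooth(a):
        return _valid(ndimage.correlate(a, w, mode="constant"), pad)

    mx = smooth(X)
    my = smooth(Y)
    sxx = smooth(X * X) - mx * mx
    syy = smooth(Y * Y) - my * my
    sxy = smooth(X * Y) - mx * my
    num = (2 * mx * my + c1) * (2 * sxy + c2)
    den = (mx * mx + my * my + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def mssim(A, B, F) -> float:
    """(SSIM(A, F) + SSIM(B, F)) / 2."""
    return 0.5 * (ssim(A, F) + ssim(B, F))


# ---------------------------------------------------------------------------
# contrast / gradient metrics
# ---------------------------------------------------------------------------

def sd(F) -> float:
    """Population standard deviation (1/(M*N) normaliser)."""
    F = np.asarray(F, dtype=float)
    if F.size == 0:
        raise ValueError("empty image")
    return float(np.sqrt(np.mean((F - F.mean()) ** 2)))


def ei(F) -> float:
    """Edge intensity: mean backward-difference gradient magnitude.

    The per-pixel field sqrt(dxF^2 + dyF^2) is defined on u, v >= 1 (one
    backward difference per axis); the scalar score is its mean.
    """
    F = np.asarray(F, dtype=float)
    if F.shape[0] < 2 or F.shape[1] < 2:
        raise ValueError(f"need at least 2x2, got {F.shape}")
    dx = F[1:, 1:] - F[:-1, 1:]
    dy = F[1:, 1:] - F[1:, :-1]
    return float(np.mean(np.sqrt(dx ** 2 + dy ** 2)))


def ag(F) -> float:
    """Average gradient with forward differences.

    AG = (1/(M*N)) * sum over the valid (M-1)x(N-1) pixels of
    sqrt((fx^2 + fy^2) / 2).
    """
    F = np.asarray(F, dtype=float)
    if F.shape[0] < 2 or F.shape[1] < 2:
        raise ValueError(f"need at least 2x2, got {F.shape}")
    fx = F[1:, :-1] - F[:-1, :-1]
    fy = F[:-1, 1:] - F[:-1, :-1]
    total = np.sum(np.sqrt((fx ** 2 + fy ** 2) / 2.0))
    return float(total / F.size)


# ---------------------------------------------------------------------------
# nonlinear correlation information entropy
# ---------------------------------------------------------------------------

def _ordinal_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=np.int64)
    ranks[order] = np.arange(len(x))
    return ranks


def ncc(X, Y, b: int = 256) -> float:
    """Nonlinear correlation coefficient of two equally sized samples.

    Both samples are rank-transformed, the rank plane is partitioned into a
    b x b grid, and NCC = 2 + sum_i (n_i/N) log_b (n_i/N) over the occupied
    cells (0 log 0 := 0).  Identical samples give 1, independent ones about
    0 when N >> b^2.
    """
    x = np.asarray(X, dtype=float).ravel()
    y = np.asarray(Y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if b < 2:
        raise ValueError(f"b must be >= 2, got {b}")
    n = len(x)
    if b * b > n:
        warnings.warn(
            f"rank grid has {b * b} cells for only {n} samples; the "
            "nonlinear correlation estimate will be coarse",
            stacklevel=2,
        )
    bx = _ordinal_ranks(x) * b // n
    by = _ordinal_ranks(y) * b // n
    counts = np.bincount(bx * b + by, minlength=b * b).astype(float)
    p = counts[counts > 0] / n
    return float(2.0 + np.sum(p * np.log(p) / np.log(b)))


def qncie(A, B, F, b: int = 256) -> float:
    """Eigenvalue-entropy aggregation of the 3x3 nonlinear correlation
    matrix of (A, B, F): Q = 1 + sum_i (l_i/3) log_b (l_i/3)."""
    A = np.asarray(A)
    B = np.asarray(B)
    F = np.asarray(F)
    if not (A.shape == B.shape == F.shape):
        raise ValueError(
            f"shape mismatch: {A.shape}, {B.shape}, {F.shape}"
        )
    mat = np.eye(3)
    mat[0, 1] = mat[1, 0] = ncc(A, B, b)
    mat[0, 2] = mat[2, 0] = ncc(A, F, b)
    mat[1, 2] = mat[2, 1] = ncc(B, F, b)
    lam = np.linalg.eigvalsh(mat)
    lam = np.clip(lam, 0.0, None)
    p = lam / 3.0
    nz = p > 0
    return float(1.0 + np.sum(p[nz] * np.log(p[nz]) / np.log(b)))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """All six scores for one fused result plus the parameters used."""

    ei: float
    ag: float
    sd: float
    mi: float
    mssim: float
    qncie: float
    params: dict = field(default_factory=dict)

    def to_frame(self):
        """One-row DataFrame in Table-style column order."""
        import pandas as pd

        return pd.DataFrame([{
            "EI": self.ei, "AG": self.ag, "SD": self.sd,
            "MI": self.mi, "MSSIM": self.mssim, "QNCIE": self.qncie,
        }])


def evaluate_all(A, B, F, levels: int = 256, b: int = 256) -> MetricReport:
    """Compute the full metric report for a fused image and its sources."""
    return MetricReport(
        ei=ei(F),
        ag=ag(F),
        sd=sd(F),
        mi=mi_fusion(A, B, F, levels),
        mssim=mssim(A, B, F),
        qncie=qncie(A, B, F, b),
        params={
            "gray_levels": levels,
            "ssim_C1": (0.01 * _DATA_RANGE) ** 2,
            "ssim_C2": (0.03 * _DATA_RANGE) ** 2,
            "rank_grid_b": b,
        },
    )
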