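"""Band-wise fusion rules.

Three strategies, one per coefficient group of the decomposition:

* coarsest low band (low1): per-pixel maximum selection on the product of
  two activity measures — weighted local energy (WLE, energy preservation)
  and the window-weighted eight-neighbourhood modified Laplacian (WSEML,
  detail extraction);
* second low band (low2): a global scalar blend whose weight is the spatial
  frequency of the weight map's low-frequency component;
* high bands: a pixel-wise blend driven by the matching high-frequency band
  of the weight map.

All local windows use symmetric (mirror) boundary extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FusionConfig",
    "weight_kernel",
    "wle",
    "eml",
    "wseml",
    "fuse_low1",
    "spatial_frequency",
    "fuse_low2",
    "fuse_high",
]

_WEIGHT_BAND_MODES = ("literal", "offset")


@dataclass
class FusionConfig:
    """Tunables of the three rules.

    radius: window radius R of the WLE/WSEML kernels (default 1 -> 3x3).
    weight_band_mode: how the raw (possibly negative) high-pass weight band
        enters the high-frequency blend — "literal" uses it as-is (the blend
        may extrapolate), "offset" adds 0.5 and clips to [0, 1].
    clamp_sf: clamp the spatial-frequency scalar into [0, 1] before the
        low2 blend (the blend presumes a convex weight).
    """

    radius: int = 1
    weight_band_mode: str = "literal"
    clamp_sf: bool = True

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.weight_band_mode not in _WEIGHT_BAND_MODES:
            raise ValueError(
                f"weight_band_mode must be one of {_WEIGHT_BAND_MODES}, "
                f"got {self.weight_band_mode!r}"
            )


def weight_kernel(R: int) -> np.ndarray:
    """(2R+1)x(2R+1) kernel with entries 2**(2R - r), r = |i| + |j|.

    r is the city-block (four-neighbourhood) step distance to the center,
    so the center entry is 2**(2R) and the kernel at R=1 is
    [[1,2,1],[2,4,2],[1,2,1]].
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    offs = np.arange(-R, R + 1)
    r = np.abs(offs)[:, None] + np.abs(offs)[None, :]
    return 2.0 ** (2 * R - r)


def wle(L: np.ndarray, R: int = 1) -> np.ndarray:
    """Weighted local energy: windowed sum of squared coefficients."""
    L = np.asarray(L, dtype=float)
    return ndimage.correlate(L * L, weight_kernel(R), mode="reflect")


def eml(L: np.ndarray) -> np.ndarray:
    """Eight-neighbourhood modified Laplacian.

    Sum of absolute axial second differences plus the diagonal ones scaled
    by 1/sqrt(2); symmetric boundary extension.
    """
    L = np.asarray(L, dtype=float)
    p = np.pad(L, 1, mode="symmetric")
    c = p[1:-1, 1:-1]
    up, down = p[:-2, 1:-1], p[2:, 1:-1]
    left, right = p[1:-1, :-2], p[1:-1, 2:]
    ul, lr = p[:-2, :-2], p[2:, 2:]
    ur, ll = p[:-2, 2:], p[2:, :-2]
    s = 1.0 / np.sqrt(2.0)
    return (np.abs(2 * c - up - down)
            + np.abs(2 * c - left - right)
            + s * np.abs(2 * c - ul - lr)
            + s * np.abs(2 * c - ur - ll))


def wseml(L: np.ndarray, R: int = 1) -> np.ndarray:
    """Window-weighted sum of the (unsquared) modified Laplacian."""
    return ndimage.correlate(eml(L), weight_kernel(R), mode="reflect")


def fuse_low1(L_A1: np.ndarray, L_B1: np.ndarray, R: int = 1) -> np.ndarray:
    """Maximum-selection on the WLE x WSEML activity product; ties go to A."""
    L_A1 = np.asarray(L_A1, dtype=float)
    L_B1 = np.asarray(L_B1, dtype=float)
    if L_A1.shape != L_B1.shape:
        raise ValueError(f"shape mismatch: {L_A1.shape} vs {L_B1.shape}")
    act_a = wle(L_A1, R) * wseml(L_A1, R)
    act_b = wle(L_B1, R) * wseml(L_B1, R)
    return np.where(act_a >= act_b, L_A1, L_B1)


def spatial_frequency(M: np.ndarray) -> float:
    """Scalar spatial frequency sqrt(RF^2 + CF^2).

    Row/column frequencies are root mean squares of first differences over
    the first M-1 rows and N-1 columns, normalised by the full pixel count
    M*N (as printed, the sums stop one row/column short of the image edge
    while the normaliser counts every pixel).
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 array, got shape {M.shape}")
    mn = M.size
    rf2 = np.sum((M[:-1, :-1] - M[:-1, 1:]) ** 2) / mn
    cf2 = np.sum((M[:-1, :-1] - M[1:, :-1]) ** 2) / mn
    return float(np.sqrt(rf2 + cf2))


def fuse_low2(L_A2: np.ndarray, L_B2: np.ndarray, W_S_low: np.ndarray,
              clamp_sf: bool = True) -> np.ndarray:
    """Global scalar blend: w = SF(W_S_low), L_F2 = w*L_A2 + (1-w)*L_B2."""
    L_A2 = np.asarray(L_A2, dtype=float)
    L_B2 = np.asarray(L_B2, dtype=float)
    if L_A2.shape != L_B2.shape:
        raise ValueError(f"shape mismatch: {L_A2.shape} vs {L_B2.shape}")
    w = spatial_frequency(W_S_low)
    if clamp_sf:
        w = min(w, 1.0)
    return L_A2 * w + L_B2 * (1.0 - w)


def fuse_high(H_A_band: np.ndarray, H_B_band: np.ndarray,
              W_band: np.ndarray, mode: str = "literal") -> np.ndarray:
    """Pixel-wise weight-band blend W*H_A + (1-W)*H_B.

    "literal" uses the raw high-pass weight band (values may be negative,
    making the blend extrapolating); "offset" first maps it through
    clip(W + 0.5, 0, 1) so the blend stays convex.
    """
    H_A_band = np.asarray(H_A_band, dtype=float)
    H_B_band = np.asarray(H_B_band, dtype=float)
    W_band = np.asarray(W_band, dtype=float)
    if not (H_A_band.shape == H_B_band.shape == W_band.shape):
        raise ValueError(
            f"shape mismatch: {H_A_band.shape}, {H_B_band.shape}, "
            f"{W_band.shape}"
        )
    if mode not in _WEIGHT_BAND_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    w = W_band if mode == "literal" else np.clip(W_band + 0.5, 0.0, 1.0)
    return w * H_A_band + (1.0 - w) * H_B_band
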