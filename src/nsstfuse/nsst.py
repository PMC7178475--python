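"""Non-subsampled shearlet transform (NSST).

The NSST combines a non-subsampled pyramid (NSP) — a cascade of 2-channel
undecimated low/high filter pairs whose filters are à-trous upsampled by
``2**j`` at stage ``j`` — with shear-based directional filtering of each
high-pass band.  Because nothing is decimated, every band has the size of
the input image and the transform is exactly shift-covariant.

Implementation notes
--------------------
* The pyramid filters are the separable maximally-flat binomial pair:
  ``h0 = [1, 4, 6, 4, 1] / 16`` (DC gain 1) and ``h1 = delta - h0``
  (DC gain 0).  With synthesis filters equal to the identity this gives the
  exact two-channel reconstruction identity ``H0*G0 + H1*G1 = 1``, so the
  inverse transform is a plain sum of bands.
* Directional filtering happens in the frequency domain.  Each high-pass
  band is multiplied by smooth Meyer-type angular windows laid out on the
  pseudo-polar grid induced by the shearlet dilation/shear matrices
  (``X = [[4,0],[0,2]]``, ``Y = [[1,1],[0,1]]``): the angular coordinate is
  piecewise linear in the shear variable ``tan(theta)`` on the horizontal
  cone and ``cot(theta)`` on the vertical cone.  The windows form an exact
  partition of unity, so summing the directional bands recovers the
  high-pass band without any synthesis filtering.
* Boundary handling is periodic (FFT-implied), which preserves exact
  reconstruction and exact circular-shift covariance.

The low-frequency output of the K-stage pyramid is further split by one
additional NSP stage into a coarsest approximation ``low1`` and an
intermediate component ``low2``; the inverse recombines them by summation.
This provides the two low-frequency components that the fusion rules treat
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterBank",
    "NsstCoeffs",
    "build_filter_bank",
    "nsst_decompose",
    "nsst_reconstruct",
]


# ---------------------------------------------------------------------------
# window construction helpers
# ---------------------------------------------------------------------------

def _meyer_ramp(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: C^3 ramp with v(x) + v(1-x) = 1."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x ** 2 - 20.0 * x ** 3)


def _pseudo_angle(shape: tuple[int, int]) -> np.ndarray:
    """Pseudo-polar angular coordinate on the FFT grid, periodic in [0, 4).

    Directions are taken modulo pi (windows must be symmetric under
    ``omega -> -omega`` so that directional bands of real images stay real).
    On the horizontal cone ``|wx| >= |wy|`` the coordinate is ``1 + wy/wx``;
    on the vertical cone it is ``3 - wx/wy``.  Both shear ratios are
    invariant under sign flips, and the two formulas agree on the cone
    diagonals, so the coordinate is continuous with period 4.
    """
    rows, cols = shape
    ky = (np.fft.fftfreq(rows) * rows)[:, None]
    kx = (np.fft.fftfreq(cols) * cols)[None, :]
    b, a = np.broadcast_arrays(ky, kx)
    cone_h = np.abs(a) >= np.abs(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_h = np.where(a != 0, b / np.where(a != 0, a, 1.0), 0.0)
        t_v = np.where(b != 0, a / np.where(b != 0, b, 1.0), 0.0)
    psi = np.where(cone_h, 1.0 + t_h, 3.0 - t_v)
    psi[(a == 0) & (b == 0)] = 0.0
    return psi


def _directional_windows(shape: tuple[int, int], n_dir: int) -> list[np.ndarray]:
    """``n_dir`` smooth angular windows summing to exactly 1 everywhere."""
    psi = _pseudo_angle(shape)
    spacing = 4.0 / n_dir
    windows = []
    for k in range(n_dir):
        d = (psi - k * spacing + 2.0) % 4.0 - 2.0  # wrapped to [-2, 2)
        u = np.abs(d) / spacing
        windows.append(_meyer_ramp(1.0 - u))
    return windows


def _binomial_lowpass_response(n: int, scale: int) -> np.ndarray:
    """Frequency response of the à-trous upsampled [1,4,6,4,1]/16 filter.

    The centered filter has the real response (6 + 8 cos w + 2 cos 2w)/16;
    upsampling by ``2**scale`` evaluates it at ``2**scale * w`` (Eq. of the
    cascading NSP: filters applied at z**(2**j)).
    """
    w = 2.0 * np.pi * np.fft.fftfreq(n) * (2 ** scale)
    return (6.0 + 8.0 * np.cos(w) + 2.0 * np.cos(2.0 * w)) / 16.0


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class FilterBank:
    """Tabulated NSST analysis/synthesis machinery for one image size.

    Attributes
    ----------
    levels : int
        Number of pyramid stages K (the extra low1/low2 split stage is
        stored at index K of ``pyr_analysis``).
    directions_per_level : tuple[int, ...]
        Directional band count per level, coarse to fine; each a power of 2.
    pyr_analysis : list[tuple[ndarray, ndarray]]
        Per-stage (H0, H1) frequency responses, H1 = 1 - H0.
    pyr_synthesis : list[tuple[float, float]]
        Per-stage (G0, G1); identity filters, so H0*G0 + H1*G1 == 1 exactly.
    shear_windows : list[list[ndarray]]
        Per-level directional frequency windows (partition of unity).
    build_size : tuple[int, int]
        Image size the frequency tables were built for.
    """

    levels: int
    directions_per_level: tuple[int, ...]
    pyr_analysis: list = field(repr=False)
    pyr_synthesis: list = field(repr=False)
    shear_windows: list = field(repr=False)
    build_size: tuple[int, int]

    def directional_partition_error(self) -> float:
        """Max pixel-wise deviation of each level's window sum from 1."""
        err = 0.0
        for wins in self.shear_windows:
            total = np.add.reduce(wins)
            err = max(err, float(np.max(np.abs(total - 1.0))))
        return err

    def pyramid_reconstruction_error(self) -> float:
        """Max deviation of H0*G0 + H1*G1 from 1 over all stages."""
        err = 0.0
        for (h0, h1), (g0, g1) in zip(self.pyr_analysis, self.pyr_synthesis):
            err = max(err, float(np.max(np.abs(h0 * g0 + h1 * g1 - 1.0))))
        return err


@dataclass
class NsstCoeffs:
    """Full NSST representation of one image (all bands image-sized).

    ``low1`` is the coarsest approximation, ``low2`` the second low-frequency
    component produced by the extra split stage, ``highs[l][k]`` the
    directional high-pass band at level ``l`` (coarse to fine), direction
    ``k``.
    """

    low1: np.ndarray
    low2: np.ndarray
    highs: list
    shape: tuple[int, int]
    provenance: str | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[tuple, FilterBank] = {}


def build_filter_bank(
    levels: int,
    directions_per_level,
    image_shape,
) -> FilterBank:
    """Build (or fetch from the in-memory cache) a filter bank.

    Parameters
    ----------
    levels : int
        Number of pyramid stages, >= 1.
    directions_per_level : sequence of int
        One power-of-two direction count (>= 2) per level, coarse to fine.
    image_shape : (rows, cols)
        Size of the images the bank will transform.
    """
    if not isinstance(levels, (int, np.integer)) or levels < 1:
        raise ValueError(f"levels must be a positive integer, got {levels!r}")
    directions = tuple(int(d) for d in directions_per_level)
    if len(directions) != levels:
        raise ValueError(
            f"directions_per_level has {len(directions)} entries "
            f"but levels={levels}"
        )
    for lvl, d in enumerate(directions):
        if d < 2 or (d & (d - 1)) != 0:
            raise ValueError(
                f"direction count at level {lvl} must be a power of two >= 2, "
                f"got {d}"
            )
    shape = (int(image_shape[0]), int(image_shape[1]))
    # the split stage uses scale `levels`; its spatial support radius is
    # 2 * 2**levels, so the image must be at least that big per dimension
    min_size = 4 * 2 ** levels + 1
    if min(shape) < min_size:
        raise ValueError(
            f"image shape {shape} is smaller than the filter support "
            f"({min_size}) for levels={levels}"
        )

    key = (levels, directions, shape)
    cached = _BANK_CACHE.get(key)
    if cached is not None:
        return cached

    pyr_analysis = []
    pyr_synthesis = []
    for j in range(levels + 1):
        h0 = np.outer(
            _binomial_lowpass_response(shape[0], j),
            _binomial_lowpass_response(shape[1], j),
        )
        pyr_analysis.append((h0, 1.0 - h0))
        pyr_synthesis.append((1.0, 1.0))

    shear_windows = [_directional_windows(shape, d) for d in directions]

    fb = FilterBank(
        levels=levels,
        directions_per_level=directions,
        pyr_analysis=pyr_analysis,
        pyr_synthesis=pyr_synthesis,
        shear_windows=shear_windows,
        build_size=shape,
    )
    _BANK_CACHE[key] = fb
    return fb


def nsst_decompose(image: np.ndarray, fb: FilterBank) -> NsstCoeffs:
    """Forward NSST: K high-pass levels of directional bands + low1/low2.

    Every output band has the shape of ``image`` (non-subsampled).  The
    low-pass output after K pyramid stages is split by one extra NSP stage
    into the coarsest approximation ``low1`` and the intermediate component
    ``low2``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    if image.shape != fb.build_size:
        raise ValueError(
            f"image shape {image.shape} does not match the filter bank's "
            f"build size {fb.build_size}"
        )
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    spectrum = np.fft.fft2(image)
    highs = []
    for lvl in range(fb.levels):
        h0, h1 = fb.pyr_analysis[lvl]
        high_spec = spectrum * h1
        bands = [
            np.fft.ifft2(high_spec * win).real
            for win in fb.shear_windows[lvl]
        ]
        highs.append(bands)
        spectrum = spectrum * h0

    h0, h1 = fb.pyr_analysis[fb.levels]
    low1 = np.fft.ifft2(spectrum * h0).real
    low2 = np.fft.ifft2(spectrum * h1).real
    return NsstCoeffs(low1=low1, low2=low2, highs=highs, shape=image.shape)


def _check_compatible(coeffs: NsstCoeffs, fb: FilterBank) -> None:
    if coeffs.shape != fb.build_size:
        raise ValueError(
            f"coefficient shape {coeffs.shape} does not match the filter "
            f"bank's build size {fb.build_size}"
        )
    if len(coeffs.highs) != fb.levels:
        raise ValueError(
            f"coefficients have {len(coeffs.highs)} high-pass levels, "
            f"filter bank has {fb.levels}"
        )
    for lvl, bands in enumerate(coeffs.highs):
        if len(bands) != fb.directions_per_level[lvl]:
            raise ValueError(
                f"level {lvl} has {len(bands)} directional bands, filter "
                f"bank expects {fb.directions_per_level[lvl]}"
            )


def nsst_reconstruct(coeffs: NsstCoeffs, fb: FilterBank) -> np.ndarray:
    """Inverse NSST, exact up to floating-point rounding.

    With identity synthesis filters and partition-of-unity directional
    windows the inverse is the sum of all bands: the directional bands of a
    level sum to that level's high-pass output, and each pyramid stage's
    low/high outputs sum to its input.
    """
    _check_compatible(coeffs, fb)
    out = coeffs.low1 + coeffs.low2
    for bands in coeffs.highs:
        for band in bands:
            out = out + band
    return out
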