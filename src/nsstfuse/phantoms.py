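"""Deterministic synthetic brain-like phantoms and sharp/blur corpora.

These fixtures stand in for registered CT/MRI slice pairs so the package
builds and tests without any external data.  A CT-like phantom has a bright
high-intensity outer ring (skull/bone) and a smooth, low-texture interior;
an MRI-like phantom has a dim rim and a high-texture interior (soft-tissue
bands, smooth gradients, a few focal blobs).  Pairs share their geometry,
so they are co-registered by construction.  All outputs are 8-bit-range
floats in [0, 255] and byte-reproducible for fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_pair",
    "make_blur_corpus",
    "pair_masks",
]

_MODALITIES = ("ct_like", "mri_like")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (256, 256)
    seed: int = 0
    modality: str = "ct_like"
    noise_sigma: float = 2.0

    def __post_init__(self):
        if self.shape[0] < 32 or self.shape[1] < 32:
            raise ValueError(f"shape {self.shape} too small for a phantom")
        if self.modality not in _MODALITIES:
            raise ValueError(
                f"modality must be one of {_MODALITIES}, "
                f"got {self.modality!r}"
            )


def _geometry(shape, seed):
    """Shared anatomy: skull ellipse, ventricles, focal blobs."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy = rows / 2 + rng.uniform(-rows * 0.02, rows * 0.02)
    cx = cols / 2 + rng.uniform(-cols * 0.02, cols * 0.02)
    ry = rows * rng.uniform(0.36, 0.42)
    rx = cols * rng.uniform(0.33, 0.39)
    rad = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    outer = rad <= 1.0
    inner = rad <= 0.88
    ring = outer & ~inner

    ventricles = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        vy = cy + rng.uniform(-0.05, 0.05) * rows
        vx = cx + sign * cols * 0.09
        vr = np.sqrt(((yy - vy) / (ry * 0.28)) ** 2
                     + ((xx - vx) / (rx * 0.12)) ** 2)
        ventricles |= vr <= 1.0

    blobs = []
    for _ in range(rng.integers(2, 5)):
        by = cy + rng.uniform(-0.4, 0.4) * ry
        bx = cx + rng.uniform(-0.4, 0.4) * rx
        br = rng.uniform(0.05, 0.12) * min(ry, rx)
        blobs.append(((yy - by) ** 2 + (xx - bx) ** 2) <= br ** 2)

    return {"outer": outer, "inner": inner, "ring": ring,
            "ventricles": ventricles & inner, "blobs": blobs,
            "center": (cy, cx), "radial": rad, "grid": (yy, xx)}


def make_phantom(spec: PhantomSpec, geometry_seed: int | None = None):
    """Render one phantom; geometry defaults to the spec's own seed."""
    geo = _geometry(spec.shape, spec.seed if geometry_seed is None
                    else geometry_seed)
    rng = np.random.default_rng(spec.seed + 7919)
    yy, xx = geo["grid"]
    img = np.zeros(spec.shape)

    if spec.modality == "ct_like":
        img[geo["ring"]] = 235.0
        img[geo["inner"]] = 55.0
        # faint smooth interior modulation, no fine texture
        smooth = gaussian_filter(rng.normal(0, 1, spec.shape), 12.0)
        smooth = 18.0 * smooth / (np.abs(smooth).max() + 1e-12)
        img[geo["inner"]] += smooth[geo["inner"]]
        img[geo["ventricles"]] = 20.0
    else:
        img[geo["ring"]] = 45.0
        base = 110.0 + 60.0 * np.sin(yy / 9.0) * np.cos(xx / 11.0)
        grad = 40.0 * (xx / spec.shape[1] - 0.5)
        # fine-grained soft-tissue detail: band-passed noise at ~1-2 px scale
        fine = rng.normal(0, 1, spec.shape)
        fine = gaussian_filter(fine, 0.8) - gaussian_filter(fine, 2.5)
        fine *= 30.0 / (fine.std() + 1e-12)
        tissue = base + grad + fine
        img[geo["inner"]] = tissue[geo["inner"]]
        for blob in geo["blobs"]:
            img[blob & geo["inner"]] = rng.uniform(170.0, 230.0)
        img[geo["ventricles"]] = 15.0

    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, spec.shape)
    return np.clip(img, 0.0, 255.0)


def make_pair(spec_ct: PhantomSpec, spec_mri: PhantomSpec):
    """Co-registered (ct_like, mri_like) pair sharing the CT spec's geometry."""
    if spec_ct.shape != spec_mri.shape:
        raise ValueError(
            f"phantom shapes differ: {spec_ct.shape} vs {spec_mri.shape}"
        )
    ct = make_phantom(spec_ct, geometry_seed=spec_ct.seed)
    mri = make_phantom(spec_mri, geometry_seed=spec_ct.seed)
    return ct, mri


def pair_masks(spec_ct: PhantomSpec):
    """Ring/interior masks of the shared geometry (for region statistics)."""
    geo = _geometry(spec_ct.shape, spec_ct.seed)
    return geo["ring"], geo["inner"]


def _texture_image(shape, rng):
    """A random sharp training image: ellipses, bands and filtered noise."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    img = 90.0 + 50.0 * np.sin(yy / rng.uniform(4, 12)) \
        * np.cos(xx / rng.uniform(4, 12))
    for _ in range(rng.integers(4, 9)):
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        ry, rx = rng.uniform(6, rows / 3), rng.uniform(6, cols / 3)
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img[mask] = rng.uniform(10, 245)
    img += gaussian_filter(rng.normal(0, 25, shape), 1.0)
    return np.clip(img, 0.0, 255.0)


def make_blur_corpus(n_images: int = 10,
                     blur_sigma_range=(1.0, 3.0),
                     seed: int = 0,
                     shape=(128, 128)):
    """List of (sharp, blurred, sigma) triples feeding the patch sampler."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    lo, hi = float(blur_sigma_range[0]), float(blur_sigma_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid sigma range {blur_sigma_range!r}")
    rng = np.random.default_rng(seed)
    corpus = []
    for _ in range(n_images):
        sharp = _texture_image(shape, rng)
        sigma = float(rng.uniform(lo, hi))
        corpus.append((sharp, gaussian_filter(sharp, sigma, mode="reflect"),
                       sigma))
    return corpus
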