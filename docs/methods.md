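# Methods

## The transform

The decomposition is a non-subsampled shearlet transform: K undecimated
pyramid stages followed by directional filtering of each high-pass band.

**Pyramid.** Each stage is the 2-channel pair `H0` (separable binomial
[1,4,6,4,1]/16, DC gain 1) and `H1 = δ − H0` (DC gain 0), with the filter
of stage *j* à-trous upsampled by `2^j` (frequency response evaluated at
`2^j ω`). Choosing identity synthesis filters makes the two-channel
reconstruction identity `H0·G0 + H1·G1 = 1` hold exactly, so the inverse
transform is a plain sum of all bands. Boundary handling is periodic
(everything is applied as FFT multiplication), which is what makes the
round trip exact to machine precision and the transform exactly covariant
under circular shifts.

**Directional windows.** Directions are parameterised by a pseudo-polar
angular coordinate that is piecewise linear in the shear ratios `ωy/ωx`
(horizontal cone) and `ωx/ωy` (vertical cone), taken modulo π so windows
are symmetric under `ω → −ω` and bands of real images stay real. Over this
periodic coordinate, Meyer-ramp bumps (`v(x) = x⁴(35−84x+70x²−20x³)`,
which satisfies `v(x)+v(1−x)=1`) are laid out so adjacent windows overlap
pairwise; their sum is exactly 1 at every frequency sample. Summing a
level's directional bands therefore recovers that level's high-pass band
with no synthesis filtering.

**Low-band split.** The fusion rules operate on two low-frequency
components. After the K regular stages, one additional pyramid stage (at
scale index K) splits the low-pass output into the coarsest approximation
`low1` and the intermediate component `low2`; the inverse recombines them
by summation. This is the one self-consistent, perfectly invertible
reading of "first/second component of the low-frequency coefficients" and
is a deliberate design choice — other splits (e.g. reusing the last
regular stage) would change what the selection rule sees.

**Defaults.** K = 4 levels with (8, 8, 16, 16) directions coarse→fine, the
common choice in shearlet-domain fusion; both are configurable. Filter
banks are tabulated once per (levels, directions, image size) and cached
in memory.

## The weight network

A two-class patch classifier: two branches with *structurally* shared
parameters (both branch evaluations read the same arrays), each branch
three valid 3×3 convolutions (1→16→32→64 channels, ReLU) with one 2×2
max-pool after the second, features concatenated and mapped by a single
fully-connected layer to two logits and a softmax. `p1` is the probability
that the first patch of the ordered pair is the sharp/high-quality one —
the orientation is fixed purely by the dataset labelling convention, and
no `W_S(b,a) = 1 − W_S(a,b)` symmetry is assumed or enforced.

Training data are 16×16 patches sampled from synthetic textured images
paired with their own Gaussian-blurred versions (σ uniform in [1, 3],
reflect boundary on the patch itself, so a non-constant sharp patch always
has strictly higher variance than its blurred partner). Labels are exactly
balanced. Patches are scaled to [0, 1]. Optimisation is Adam (lr 1e-3,
batch 64) on two-class cross-entropy, single-threaded NumPy, deterministic
for a fixed seed; the per-epoch mean loss is recorded on the returned
parameter object. The sharp/blur task saturates quickly: held-out accuracy
reaches 100% well before the default 20 epochs.

The dense map `W_S` slides the patch window with stride 2 (denser = slower
but smoother; configurable), writes each window's `p1` to all covered
pixels and averages overlaps, appending a final row/column of windows when
the stride does not land on the image edge so every pixel is covered.

## Fusion rules

* **low1** — pure per-pixel selection by the activity product WLE×WSEML.
  The kernel entry at offset (i, j) is `2^(2R−r)` with `r = |i|+|j|` (the
  city-block reading; it is the only one under which the corner entries
  follow the formula, giving [[1,2,1],[2,4,2],[1,2,1]] at R = 1). Windowed
  sums use symmetric (mirror) boundary extension; EML enters the WSEML sum
  unsquared. Ties select the first source.
* **low2** — a *global scalar* blend: the spatial frequency of `W_S`'s low
  band, computed with sums over the first M−1 rows / N−1 columns but the
  full `1/(M·N)` normaliser (kept exactly as the formula prints it), then
  clamped to [0, 1] by default because the blend presumes a convex weight.
  A per-pixel variant is deliberately not implemented.
* **high** — `H_F = W·H_A + (1−W)·H_B` with the *matching* (level,
  direction) high band of `W_S` (the only shape-consistent reading).  In
  the default "literal" mode the raw high-pass weight is used, so values
  near zero make the blend lean strongly toward B and the combination can
  extrapolate outside the input envelope; the alternative "offset" mode
  maps the band through `clip(W+0.5, 0, 1)` and stays convex. Whether the
  original method normalised these bands is unknowable, so both modes are
  exposed.

All three rules are exactly idempotent on identical inputs, which combined
with exact reconstruction gives the pipeline-level identity
`fuse(A, A) = A` within one gray level after 8-bit quantisation.

## Metrics

* **MI**: joint 256-level histograms, log base 2; reported as
  MI(A,F) + MI(B,F).
* **MSSIM**: Gaussian-weighted 11×11 window (σ = 1.5), weighted local
  moments without sample-covariance correction, constants
  C1 = (0.01·255)², C2 = (0.03·255)², averaged over valid window
  positions, then averaged over the two sources. Cross-checked in the test
  suite against scikit-image's implementation.
* **SD**: population standard deviation (1/(M·N)).
* **EI**: mean magnitude of the backward-difference gradient field over
  the valid region. The per-pixel field is what the formula defines; the
  mean is the reduction that yields scores on the customary scale.
* **AG**: forward differences, `sqrt((fx²+fy²)/2)` summed over the valid
  (M−1)×(N−1) pixels, normalised by the full pixel count.
* **Q_ncie**: for each pair among (A, B, F), both samples are
  rank-transformed (ordinal, stable ties), the rank plane partitioned into
  a b×b grid (b = 256) and `NCC = 2 + Σ (n_i/N) log_b(n_i/N)` computed
  with `0·log 0 = 0`; the three pairwise NCCs fill a 3×3 unit-diagonal
  matrix whose eigenvalues λ give `Q = 1 + Σ (λ_i/3) log_b(λ_i/3)`. The
  printed form of this metric mixes its symbols; this rank-grid +
  eigenvalue-entropy reading is the one whose output range matches the
  customary ≈0.80 values (three mutually independent images give
  `1 − log_256 3 ≈ 0.8023`). A warning is emitted when `b² > N`.

Each metric is verified against an independent naive double-loop
implementation to 1e−10 on 16×16 inputs.

## Synthetic phantoms

`phantoms` generates co-registered CT-like / MRI-like pairs (256×256 by
default): a shared elliptical geometry (skull ring, ventricles, focal
blobs) with modality-specific rendering — CT: bright ring (235), smooth
low-texture interior; MRI: dim rim (45), interior with sinusoidal tissue
bands, a smooth gradient, focal blobs and a fine-grained band-passed-noise
texture (std 30 gray levels at ~1–2 px scale). The fine texture matters:
it makes the MRI-like image the detail-rich modality, which is the defining
property of the CT/MRI contrast this generator emulates. Mild Gaussian
noise (σ = 2) is added and everything is clipped to [0, 255],
seed-deterministic.

What the phantoms do **not** model: real anatomy, partial-volume effects,
bias fields, registration error, or modality-specific noise statistics.
Passing tests on phantoms therefore demonstrate the *mechanics* of the
pipeline (invertibility, rule behaviour, trainability, and that the rules
beat pixel averaging on detail/contrast metrics under complementary-
information conditions) — not clinical fusion quality on hospital data.

## Problem sizes and numerical choices

The test suite trains the full default configuration once (5000 pairs, 20
epochs, ≈4 min single-threaded); pipeline-level tests share one compact
model (1500 pairs, 5 epochs, which already saturates the task). The
acceptance script uses 20 round-trip images, 2500 training pairs / 8
epochs and three 256×256 phantom pairs — sizes at which every reported
quantity is stable run-to-run at fixed seed. Internally pixels stay
float64 in [0, 255]; quantisation to 8 bits happens only when writing
PNG/TIFF output. Degenerate inputs (constant images in SF, empty
histograms, single-class training sets, sub-window images) raise
informative errors rather than returning NaN.

## Known limitations

* The literal high-band rule transfers most of B's high-frequency content
  (the weight's high bands are small); the "offset" mode is provided but
  is not the default because the literal formula is.
* The low1/low2 split is one consistent interpretation of an
  under-specified decomposition contract (see above).
* Training and inference are CPU NumPy; large batches of fusions would
  benefit from a compiled backend, which is out of scope.
* Images must be pre-registered; no resampling or registration is
  performed.
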