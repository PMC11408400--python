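# Methods

## The model

The pipeline treats margin delineation as a three-stage problem on a
hyperspectral cube `(rows, cols, bands)` of per-pixel reflectance
spectra.

**Calibration.** Raw digital numbers are mapped to relative reflectance
with the two-reference relation `R = ρ_w (I − D)/(W − D)`.  `D` may be a
full dark frame or per-band means; `W` is normally a per-band spectrum
collapsed from the pixels of an in-scene white tile (PTFE, ~98%
reflectance) and broadcast spatially, since a full flat-field frame is
not available when the standard sits inside the scene.  The tile's own
reflectance ρ_w (default 0.98) is applied as a multiplier and is
configurable, since published reflectance figures do not always make
clear whether it has been divided out.  Assumptions: detector response
linear in exposure between dark and white levels, illumination constant
between the tile and the tissue.  Limits: no correction for illumination
gradients beyond what the (scale-invariant) classifier tolerates.

**Segmentation.** The initial partition is edge-based: Sobel gradient
magnitude of the mean-intensity image, suppression of gradients below the
`scale_level`-th percentile (0–100; default 30), and watershed seeded at
the regional minima of the suppressed gradient.  Merging then follows the
full lambda-schedule: always merge the adjacent pair with globally
minimal cost

    t_ij = [ |S_i||S_j| / (|S_i|+|S_j|) * ||v_i - v_j||^2 ] / l(∂(S_i,S_j))

while the minimum stays below a threshold T.  `v_i` is the full-band mean
spectrum (using only mean intensity would discard the spectral term the
cost is built around); the area factor is the harmonic-mean weighting
that penalises merging two large dissimilar regions; `l` counts shared
4-adjacent pixel edges.  `merge_level` (0–100; default 75) maps to T as
that percentile of the pairwise cost distribution of the *initial*
partition — data-adaptive, monotone (higher level ⇒ more merging), with
`merge_level=100` treated as T = ∞ and an absolute T accepted directly
for exact reproducibility.  Ties on the minimal cost break on the
lexicographically smallest `(min id, max id)` pair.  Mean spectra update
by exact area weighting, so the merged mean equals the pixel mean of the
union at every step.

**Classification.** One decision per segment (region-based, the core
design choice: segment mean spectra average out pixel noise and produce
coherent margins; a per-pixel mode exists for comparison).  Per class,
the reference spectrum is the pixel-area-weighted mean over training
segments; the classifier assigns the class of the smallest spectral angle
`α = arccos(t·r / (‖t‖‖r‖))` if it is within `max_angle` (default
0.1 rad), else `unclassified`.  SAM ignores per-segment intensity scaling
entirely — the property that makes it robust to uneven illumination.
Ties at exactly equal angle resolve to the earlier class in the reference
order (tumor first), deterministically.

**Evaluation.** ROC curves per class score each held-out segment by its
rule angle to that class's reference (lower = more class-like) and sweep
every distinct cutoff; the AUC equals the normalised Mann–Whitney
statistic, which the test suite verifies against exhaustive pair counting
to 1e-10.  A compatibility mode sweeps mean reflectance over a fixed
grid (default 0.10–0.78) instead.  Unclassified segments keep their
angles and are scored like any other unit — ROC needs scores, not hard
labels.  D_max scans the image row through the tumor center for the
farthest tumor-class pixel (the same one-dimensional measurement a
dermoscopic ruler makes); an any-direction variant exists behind a flag
and serves as fallback when the center row holds no tumor pixel.
Bland–Altman limits are mean ± 1.96 sample SD (n−1) of the paired
differences; box summaries use linear-interpolation quantiles, recorded
in the output.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `scale_level` | 30 | percentile | initial segmentation coarseness |
| `merge_level` | 75 | percentile | merge aggressiveness (threshold T) |
| `max_angle` | 0.1 | rad | SAM decision threshold |
| `train_fraction` | 0.37 | — | share of segments used as training |
| `white_reflectance` | 0.98 | — | PTFE tile reflectance |
| `pixel_pitch` | 0.1 | mm/px | converts D_max to mm |
| clip range | [0, 1.5] | reflectance | glints above 1 must survive; SAM is scale-tolerant, so clipping at 1 would distort shape |
| denominator floor | 1e-6 × white range | DN | dead-band protection; floored pixels flagged invalid |

## The phantom generator

The generator emulates a VIS–NIR pushbroom skin imager: 400–800 nm
uniform wavelength grid (205 bands at 348 × 260 px at full scale;
64 × 64 × 40 by default, which keeps a full pipeline run under a second
while leaving hundreds of initial watershed regions).  Normal skin
follows a monotone PCHIP curve through (400 nm, 0.15), (600 nm, 0.45),
(800 nm, 0.85).  The tumor curve subtracts `delta_r_700 · ramp(λ)` with
`ramp = max(0, (λ−500)/200)`, so the 700 nm contrast equals
`delta_r_700` exactly and the curve *shape* changes — a pure intensity
scaling would be invisible to SAM.  At ΔR = 0.2 the angle between class
spectra is ≈ 0.13 rad, monotone in ΔR.  Defaults: `delta_r_700 = 0.2`
(between the BCC-like 0.192 and SCC-like 0.311 contrasts), additive
per-band Gaussian noise σ = 0.02.

Within-class texture is a smooth multiplicative per-pixel field
(amplitude 0.04): correlation length rows/12 over normal skin, and
rows/24 at 1.5× amplitude inside the tumor, reflecting the spectral
heterogeneity of carcinoma tissue relative to normal skin.  Being scalar
per pixel the texture is invisible to SAM but visible to the merge cost,
which is what keeps several segments per class alive at merge level 75 —
without it the phantom merges to one segment per class and held-out
segment-level evaluation becomes degenerate.  An optional third tissue
zone (default 1.6% of the scene, inside the tumor) carries a spectrum
rotated a chosen angle away from both class spectra in a direction
orthogonal to their span, to exercise the unclassified pathway.

The raw acquisition is synthesized in reverse: a flat 100-DN dark frame,
a smooth halogen-like white spectrum, and
`raw = D + R (W − D)/0.98`, so standard calibration recovers the scene
exactly (to float round-off) when noise and texture are zero.

What the phantom does **not** model: biophysical skin optics (chromophore
absorption, scattering, melanin variation), specular glints, curvature
shading, instrument smile/keystone, shot noise proportional to signal.
Passing tests on phantoms therefore demonstrate the pipeline's
correctness and its behavior under controlled contrast and noise — not
clinical performance.

## Numerical choices

- Watershed boundary refinement: the watershed line on a gradient ridge
  is ambiguous to about one pixel, and single-pixel protrusions are
  systematically flooded from the wrong side.  A nearest-mean pass (two
  iterations) reassigns boundary pixels whose intensity is strictly
  closer to an adjacent segment's mean, guarded by a simple-point test
  so segments stay 4-connected and non-empty.  On noiseless phantoms
  this makes segment boundaries coincide with the true region boundary
  exactly.
- Perfectly flat suppressed-gradient regions have no regional minima to
  seed the watershed; they are labeled as plateau components directly.
- Invalid pixels are carried in a boolean mask, never as sentinel values;
  before gradient computation they are filled with the nearest valid
  neighbor so an ROI outline does not register as an edge.
- The merge engine uses a lazy-deletion heap keyed by
  `(cost, min id, max id)`; a popped entry is acted on only if it matches
  the pair's current cost.  It is equivalent (verified exhaustively on
  random 8×8 instances against a full-rescan oracle) to recomputing all
  pair costs each iteration.
- The arccos argument is clamped to [−1, 1]; zero-norm spectra are
  reported unclassified and logged rather than raising mid-pipeline.
- Training selection is a stratified largest-remainder allocation with a
  floor of one segment per class, deterministic under the seed; an
  explicit (segment, class) list bypasses sampling to reproduce
  physician-style selection.

## Known limitations

- The `scale_level`/`merge_level` percentile semantics reproduce the
  documented 0–100 behavior of the original analysis software, whose
  internals are unpublished; absolute thresholds are exposed for exact
  reproducibility, but level values are not interchangeable with other
  implementations.
- Very small spectrally distinct regions (≈1–2% of the scene) can leak
  into neighboring segments fragment-by-fragment during early merging,
  while areas are still small and the area-weighted cost is low.  In a
  minority of phantom seeds the third tissue zone is absorbed into the
  tumor class before classification; its recovered area share still
  stays within two percentage points of truth.
- ROC on held-out segments requires at least one test segment per class;
  scenes that merge to a single segment per class cannot be evaluated at
  segment level (the pipeline logs and skips the class rather than
  guessing).
- Reported AUCs on phantoms are typically 1.0 — the phantom contrast at
  default settings is an easy ranking problem for segment-mean spectra.
  The value of the suite is in the exact identities and oracle
  equivalences, not in reproducing clinical AUC levels.
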