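# Methods

This note documents the model implemented by `corticolumn`, the choices
made where the design was genuinely open, and what the synthetic-data
studies do and do not demonstrate.

## Census coding

A receptive field is a rectangle `[x0, x0+w) × [y0, y0+h)` (0-based,
half-open) with `w, h ≥ 3`. Its nine sub-regions are delimited by cut
points `round(k·w/3)`, `k = 0…3` (likewise for height), which tiles the
rectangle exactly for any size — e.g. `w = 10` gives column widths
(3, 4, 3). Sub-region bit `n = 3·row + col` is set iff the sub-region
mean is **at least** the whole-field mean; the nine bits pack row-major,
top-left in the least significant bit. Worked examples fixing this
convention: a middle-row bar encodes to 56, the left column to 73, a
top-row-plus-left-column corner to 79, the main diagonal to 273.

Numerical choices:

* All rectangle sums come from an integral image (`int64` for integer
  images), so means are exact and O(1).
* For integer images the comparison `⟨I_fn⟩ ≥ ⟨I_F⟩` is evaluated on
  cross-multiplied integer sums (`sum_fn · area_F ≥ sum_F · area_fn`),
  eliminating floating-point tie artifacts. Float images use float
  arithmetic; ties there are measure-zero.
* Ties set the bit to 1. Color input is collapsed with Rec.601 luma
  (0.299, 0.587, 0.114) and rounded.

**The 511-code fact.** The area-weighted average of the nine sub-region
means equals the whole-field mean, so at least one sub-mean is always ≥
the field mean: code 0 can never be produced. Consequently, encoding one
block image per 3×3 pattern yields 511 distinct codes, not 512: the
all-zero pattern renders as a uniform image, all nine comparisons tie,
and it encodes to 511 exactly like the all-ones pattern. The 9-bit code
*space* has 512 values; the census operator's *image* has 511. Any
deterministic tie rule produces the same collision (the two uniform
renderings are the same image up to brightness, and codes are brightness
invariant). Tests assert the true invariant; the acceptance script
reports the computed count.

## Weak classifiers

Class-conditional histograms over the 512 codes are estimated from
training windows (optionally weighted). The default decision is the
likelihood-ratio support rule: fire iff the code has nonzero
object-class density. Division-by-zero conventions: background density 0
with positive object density → ratio +∞ (fires); both zero → ratio 0
(does not fire). The support rule makes a weak classifier's response
table depend only on which codes occur among positives — a deliberate
fidelity choice; the Laplace-smoothed alternative (`rule="laplace"`,
fire iff the add-one-smoothed ratio exceeds 1) is available behind a
configuration switch for noisier data.

## Boosting and cascade training

Discrete AdaBoost, Viola–Jones flavor: uniform initial sample weights;
each round selects the pool feature with minimum weighted error (ties →
first in pool order; features whose response column duplicates an
already-selected one are skipped), assigns `ω_k = ln((1−ε_k)/ε_k)` with
`ε` clamped to `[1e−10, 1−1e−10]`, and multiplies correct samples'
weights by `ε/(1−ε)` before renormalizing. Weak histograms are refit to
the current weights at selection time (under the support rule this
leaves the response table unchanged; the weighted counts are what gets
serialized). The classical bound — training error of the majority vote ≤
`Π_k 2√(ε_k(1−ε_k))` — is verified in the tests.

The stage threshold `Θ` (strict inequality) is the largest value keeping
a target detection rate `d_min` on held-out positives: the k-th largest
validation score, `k = ⌈d_min·n⌉`, nudged down by one ulp. If that value
is negative the threshold falls back to 0 with a warning.

Cascade schedule (defaults): `d_min = 0.995` per stage, stage
false-accept ceiling `f_max = 0.5`, global per-window FAR target
`1e−5`, at most 20 stages, weaks per stage doubled (1, 2, 4, …, ≤ 64)
until `f_max` is met. A quarter of the positives is held out for
threshold selection. Negatives start as random multi-scale background
crops (one per training positive) and after every stage are re-collected
by scanning the backgrounds with the current cascade (stride 3, scale
step 1.3) — the surviving false positives become the next stage's
negatives, and the accepted/scanned ratio of that sweep is the empirical
FAR used for the stopping rule. If fewer than 50 hard negatives remain
the set is padded with fresh random crops; if none remain training ends
early (success). All sampling flows from one seed; identical inputs and
seed reproduce identical XML model files byte for byte.

## Scanning and grouping

Detection scans a scale pyramid by growing the window by 1.2× per level
(receptive fields rescale and clamp with it; the integral image is built
once), stride 2 px at base scale, scaled proportionally. Raw accepts are
grouped by single-link connected components under IoU ≥ 0.3; components
with ≥ 2 members emit one detection at the member-mean box, with the
mean normalized stage margin as score and the member count as support.
Grouping is permutation invariant, and raising the neighbor threshold
can only remove detections.

## The seven-layer column model

The functional layer list (input, polymorphic, inner-pyramidal,
inner-granular, outer-pyramidal, outer-granular, axonal) is the ground
truth for introspection; layer numbering variants are ignored. Census
counts: 1 input element; one polymorphic element per distinct receptive
field used anywhere in the column; one inner-pyramidal element per weak
classifier; one inner-granular element per stage; single outer-pyramidal
and outer-granular elements; one axonal element per declared inter-column
link. Structural bounds are enforced on load and on census: 0–100
stages, 1–1000 weaks per stage, kernel area ≤ 1024 px (32×32), nine
sub-regions per receptive field. Axonal excite/suppress links are
metadata only — inter-column dynamics are not executed.

Activation traces score every canonical window inside the query region
without short-circuiting, pick the window passing the most stages (ties
by total normalized margin), then report per-stage scores, firing weak
sets and the referenced codes; `stages_evaluated` follows cascade
semantics (stops at the first rejection). Renders are drawn with PIL at
a fixed palette, so a fixed trace yields byte-identical PNGs; the 3D
export is a plain vertex/edge CSV pair (z = layer index) for external
viewers.

The XML model file stores the object type, window size, stage count,
and per stage the strict threshold and each weak's vote weight,
receptive-field geometry, decision rule and both 512-bin histograms.
Weighted histogram counts are written as full-precision decimal floats
(integers where the counts are integral) so that loading reproduces
every decision bit-exactly. The schema is self-defined and documented by
`save_column_xml`.

## Lateral-inhibition layer

The coupling function is a sampled difference of Gaussians on a
`(2R+1)²` support, `R = ⌈3σ_i⌉` by default; `σ_i > σ_e` is enforced.
Zero-sum normalization rescales the inhibitory amplitude so the sampled
weights sum to 0, making the layer exactly silent on uniform input. One
synchronous step convolves with reflective boundary handling and
thresholds strictly; no temporal iteration is performed. The kernel's
preferred blob diameter is `2·r_0` with `r_0` the zero crossing of Φ,
`r_0² = ln(A_e/A_i)·σ_e²σ_i²/(σ_i²−σ_e²)` — the central response to a
disk of radius ρ is the integral of Φ over `r < ρ`, which peaks where Φ
changes sign.

Derived extractors and their threshold rules (both self-calibrating from
the kernel and a unit-contrast image normalization):

* **Contours**: tight kernel (σ_e = 1, σ_i = 2), θ = half the kernel's
  peak response to a unit step edge (computable exactly from column
  cumulative sums). The active band then hugs the bright side of an edge
  within ~2 px.
* **Objects of a given size**: σ_e = diameter/2, σ_i = 2σ_e, θ halfway
  between the kernel's peak straight-edge response and its central
  response to a size-matched disk. Edges and oversized structures (whose
  best response is edge-like) stay below threshold; blobs near the
  preferred size fire. Components of the thresholded field are labelled
  and reported with centroid and area. Note σ_e = diameter/2 puts the
  kernel's preferred diameter ≈ 1.36× the nominal target; size
  discrimination against 4–5× objects, the intended use, is unaffected.

## Synthetic data: what it emulates and what it does not

Glyph windows emulate symbol-detection training material: a built-in
public-domain 5×7 dot-matrix digit font scaled to ~75% of a 24 px
window, with geometric jitter (shift ±2 px, scale ±10%), photometric
jitter (gain 0.85–1.15, offset ±20 grey levels) and additive Gaussian
noise (σ = 8). Backgrounds are smoothed noise, linear ramps, or
sinusoidal gratings. Phantoms emulate fluorescence-like microscopy
frames: disjoint bright disks (somas), random-walk strokes (processes),
flat background plus Gaussian noise, with exact ground truth emitted
alongside. All generators are pure functions of spec + seed.

The error-rate study (held-out FRR ≤ 0.10, per-window FAR ≤ 1e−3,
checked in the acceptance tests) trains on 2000 digit windows and 51
backgrounds of 128×128 px. These sizes keep the full suite in the
minutes range on one CPU while leaving the cascade non-trivial (multiple
stages, real bootstrapping). Passing them shows the machinery is correct
and that the cascade generalizes across jitter and noise *of the
generator's kind*; it does not show performance on natural imagery —
real backgrounds are vastly more diverse than three texture families,
real symbols deform nonlinearly, and the reported FAR floor is limited
by the number of background windows scanned (~4×10⁵).

## Known limitations

* Only the brightness coding channel is implemented; gradient, texture
  and color channels for the polymorphic layer are out of scope.
* Weak responses are hard 0/1 votes; no confidence-rated variants.
* The support decision rule makes stage-1 features close to "code seen
  among positives" lookups; heavily multimodal object classes may need
  the Laplace rule.
* Multi-column interactions (mutual excitation/suppression) are declared
  in metadata but never simulated.
* Scanning rescales receptive fields by rounding, so detections at
  scales far from 1 inherit quantization error of a pixel or two.
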