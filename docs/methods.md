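# Methods

## Scope and data model

`ciliaquant` quantifies two-channel immunofluorescence staining of ciliated
airway epithelium. Each field of view is a pair of single-plane grayscale
TIFFs: a *test* channel (red by default; the antibody under evaluation) and a
*marker* channel (green; acetylated α-tubulin, a stable stain of the ciliary
axoneme), optionally with a nuclear channel (blue). A *slide* is the set of
fields for one (donor, storage condition, antibody) triple. The controlled
vocabulary covers seven storage conditions — continuous −80 °C or −20 °C
storage, an 8-week −20 °C variant, three clinic/transport/lab combinations
(−20 °C, 4 °C or room temperature for 11 days, then 3 days at RT, then −80 °C),
and 28 days at RT — and eight antibody targets (DNAH5, DNALI1, RSPH4A,
RSPH9, GAS8, CCDC39, CCDC40, SPEF2). Unknown tokens are processed but
flagged, so the pipeline is reusable beyond this design.

Channel roles are carried by filename colour tokens plus an explicit
role→colour map, never inferred from pixel content. A fluorochrome colour
switch is therefore a pure configuration change, and the test suite checks
that swapping the roles end to end leaves every rank matrix unchanged.

All linear measures convert px → µm with the acquisition resolution
(default 0.1136 µm/px, configurable); areal measures square the factor.

## Synthetic slide generator

The generator exists so that every stage has exact ground truth. A cell is
an elliptical body (semi-axes ~28–38 px, axis ratio ≤ 1.3) carrying an
apical tuft of 5–9 ridge primitives — anti-aliased thick segments with a
Gaussian cross-profile (length 18–32 px, width σ 1.2–2 px, peak amplitude
2400–3200 intensity units) fanning outward from an anchor on the body
boundary — plus a nuclear blob. Fields are 256 × 256 px and hold 1–3
non-overlapping cells; these sizes are the package's defaults for tractable,
fully-testable studies and are freely configurable.

Degradation follows a mass-conserving mixture. With tuft field `T` and a
diffuse field `D` normalized so `ΣD = ΣT`:

```
green = T + b + ε,      red = (1−δ)·T + δ·D + b + ε
```

where `b` is a flat background (default 150), `ε` i.i.d. Gaussian read noise
(default σ 40), and δ ∈ [0, 1] the degradation fraction. `D` lives on the
cytoplasm (body minus nucleus minus tuft), weighted away from the tuft
anchor (epitope signal retracts into the cell interior) and modulated by a
smooth random texture (unit-mean, σ 3 px), which makes degraded staining
blotchy rather than flat. Consequences used by the tests:

* total red intensity is independent of δ — *localization* is the only
  degraded property;
* the red signal fraction inside the tuft is strictly decreasing in δ;
* red(δ) is affine in δ at fixed seed, so the mixture can be verified
  pixel-wise from the δ = 0 and δ = 1 renders.

A study assigns each (condition, antibody) a δ via a delta map. The default
map is `clip(base(condition) × sensitivity(antibody))` with bases
0.08, 0.16, 0.26, 0.34, 0.42, 0.60, 0.70 along the condition order above and
sensitivities 0.60 (RSPH4A), 0.70 (DNAH5), 0.80 (GAS8), 0.90 (RSPH9),
1.00 (SPEF2), 1.15 (CCDC40), 1.25 (DNALI1), 1.35 (CCDC39). These numbers
are free design parameters of the simulator, chosen once so that the seven
conditions span the regime where the mixture is detectable and so that the
injected orderings mirror the qualitative best→worst gradients the metric
is meant to recover; they are not measured quantities. Donor-to-donor
variability is a small Gaussian jitter on δ (σ 0.02, clipped to [0, 1]).

Reproducibility: each slide's random stream derives from
SHA-256(master seed | donor | condition | antibody), truncated below 2³¹, so
regeneration is bit-identical and independent of generation order; TIFFs are
written without timestamps, and identical seeds give byte-identical files.
Intensities are rendered in floating point and quantized to 16 bit on write.

What the generator does **not** emulate: point-spread blur, channel
bleed-through, z-structure, intensity saturation, autofluorescence,
cell-type mixtures, debris, or genuinely absent staining (δ only relocates
signal, never removes it). Passing tests on synthetic studies therefore
demonstrate that the measurement and scoring machinery recovers a known
localization gradient under realistic noise — not that the pipeline's
absolute numbers match any particular microscope.

## Segmentation

Per channel: Gaussian smoothing (σ 1 px) → global threshold → 8-connected
components → hole filling → size filter (40 px … 10⁶ px). The default
threshold is two-class Otsu computed on log1p intensities and mapped back:
with a few very bright tuft pixels over a dim extended diffuse signal,
raw-intensity Otsu lands halfway up the bright class and is blind to early
degradation, whereas the log-scale threshold separates background from all
signal and yields a smooth, monotone parameter response across the δ grid.
Raw-intensity Otsu and fixed thresholds remain options. Objects touching
the border are kept (partially imaged cells still carry signal); no
declumping is performed, since tufts are analysed as whole stained regions.
A constant image has no threshold and yields zero objects with a warning.
Otsu thresholds are computed from the data range, so segmentation is
equivariant under affine intensity maps and translation (up to borders).

## Object features

Moments use integer pixel-centre coordinates, no subpixel interpolation —
deterministic and reproducible by brute-force pixel sums (the test suite
holds the features to 1e−9 against independent oracles).

* **Eccentricity**: with λ₁ ≥ λ₂ the eigenvalues of the 2 × 2 central
  second-moment matrix, `e = sqrt(1 − λ₂/λ₁)`; 0 for a disc, → 1 for a
  line; rotation-invariant; single-pixel objects return 0 by convention.
* **Compactness**: `2π · MSD / area`, MSD the mean squared distance of
  object pixels from the centroid. A filled disc gives ≈ 1; elongation,
  holes and sparse/patchy support raise it. The radial-variance definition
  (disc-normalized, robust to boundary noise) is the default; a
  perimeter-based variant was deliberately not used.
* **Mass displacement**: Euclidean distance between the geometric and the
  intensity-weighted centroid; 0 for uniform or mirror-symmetric intensity;
  invariant to intensity rescaling but not to additive offsets (a pedestal
  drags the weighted centroid inward — documented behaviour). On renders it
  grows from intact to moderately degraded staining; at δ → 1 the object is
  nearly uniform about its own centroid and the displacement falls again, an
  intrinsic property of mass-conserving relocation measured on the relocated
  object itself, so the cell-level monotonicity test targets the mixture
  regime (δ ≤ 0.25) while study-level discrimination is tested end to end.

## Colocalization

See the README for the RWC formula. Choices: midranks for ties; `R_max` is
the largest observed rank difference in the mask (weights are 1 everywhere
if all ranks agree); colocalized pixels are those strictly above both
channel thresholds; zero primary intensity returns 0 with a warning. The
analysis mask is the union of the two channels' foregrounds — including the
empty background would inflate rank agreement — and is configurable to the
whole image. RWC is invariant to strictly monotone transforms of the
secondary channel that preserve threshold membership, lies in [0, 1] by
construction, and is directional; Pearson correlation over the same mask is
reported alongside as the symmetric, [−1, 1] companion measure. Manders and
Costes-style coefficients are out of scope.

## Pairing

Each red (test) object is assigned to the green (marker) object with which
it shares the most pixels; exact ties resolve to the lower green id (logged);
red objects with no green overlap stay unpaired. `green_multiplicity` counts
a green object's red children; the unique-pair filter keeps only pairs whose
green object has exactly one red child, so red and green measurements
describe the same cilium — this filter is applied before aggregating object
parameters. Centroid distances use unweighted (geometric) centroids, in px
and µm. Max-overlap parent assignment (rather than centroid containment) is
the package's documented choice.

## Scoring

Aggregation: per-slide means of the six headline parameters (test-channel
area, compactness, eccentricity, mass displacement from unique-pair objects;
mean unique-pair centroid distance; mean image-level RWC red→green), then
means across donors. Slides with no surviving objects contribute nothing
and are counted in a warning.

Screen: per parameter, a Kruskal–Wallis test of per-slide values across
storage conditions, significant at p < 0.001. The non-parametric choice
avoids distributional assumptions on skewed object features; one-way ANOVA
is available, as is an optional Benjamini–Hochberg adjustment (off by
default — the fixed stringent α is the primary design). The unit of
replication is the slide.

Ranking: per parameter, entities (conditions or antibodies) are ordered by
their mean value in the parameter's better direction — Area ↓,
Compactness ↓, Eccentricity ↑, MassDisplacement ↓, RWC red→green ↑,
centroid distance ↓ — and ranked 1..n with midranks on ties. The overall
performance rank is the unweighted mean of the per-parameter ranks,
reported to one decimal. Condition ranks are computed on values averaged
across antibodies; antibody ranks on values averaged across conditions, with
a subset variant that drops selected conditions (e.g. the two prolonged-RT
conditions) before re-ranking. Where a genuinely different convention was
possible (rank-then-average versus average-then-rank across the other axis),
average-then-rank was chosen and the alternative can be obtained by calling
`rank_entities` per stratum.

## Numerical and degenerate-input conventions

* Constant images: zero objects / empty colocalization, warnings, no error.
* Single-pixel objects: eccentricity 0; all-zero object intensity: mass
  displacement 0; zero variance: Pearson NaN — all logged.
* Percent paired is reported to the nearest percent; undefined (None) with
  zero red objects.
* CSVs are written with 15 significant digits (round-trip safe), JSON
  manifests with sorted keys; identical inputs give byte-identical outputs.

## Problem sizes

Default synthetic studies use 256 × 256 px fields with 1–3 cells and the
full 5 × 7 × 8 design at 22 images per slide (280 slides). The end-to-end
recovery experiment in the tests and the acceptance script uses 5 donors ×
7 conditions × 2 antibodies (DNAH5, SPEF2 — one middling and one average
sensitivity) × 10 images per slide, i.e. 70 slides / 700 images, the
package's chosen balance between statistical power (Spearman ρ ≥ 0.9
recovery, RWC screen p ≈ 10⁻¹⁰) and a round trip that completes in about a
minute on one CPU.

## Known limitations

* Equivalence with any specific interactive image-analysis software is not
  claimed: exact thresholds, size windows and declumping rules of such
  pipelines are implementation-specific; here they are explicit, documented
  configuration.
* The degradation model is an assumption (mass-conserving relocation with a
  patchy, interior-weighted diffuse field); real epitope loss may also
  reduce total signal, which intensity-normalized parameters would see
  differently.
* Compactness discriminates weakly on the synthetic mixture (a smooth
  diffuse ellipse is nearly as compact as a dense tuft); it is retained
  because it is one of the six headline parameters and is exercised fully by
  the oracle tests.
* The significance screen assumes slides are exchangeable within a
  condition; donor is not modelled as a random effect.
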