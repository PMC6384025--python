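# Methods

## The competitive-allocation model

Each scene carries a fixed pool of `S` synapses distributed over its `n`
neurons by a single multinomial draw with probabilities
`p_i = e_i^γ / Σ_j e_j^γ`, where `e_i ≥ 0` is neuron *i*'s ephrin-B3
expression weight and `γ` (default 1) is an allocation exponent. The linear
default reflects the observed linear relationship between eB3 level and
synapse density; `γ` is exposed because the true mapping from expression to
allocation share is not established beyond its monotonicity, and a
winner-take-all regime (`γ → ∞`) or a compressed one (`γ < 1`) may be worth
probing. Pool conservation (`Σ counts = S`) holds for every draw by
construction — the model can only redistribute.

Consequences used as test oracles: with two cells the draw is
`Binomial(S, p)`; under equal weights the long-run winner fraction is 1/2
(exact ties excluded); the probability that the higher-expression cell wins
is the binomial exceedance probability `P(X > S/2 | X ≠ S/2)`.

## Synthetic scenes

**Geometry.** Fields default to 150 × 150 µm at 0.2 µm/px (a typical
high-zoom confocal pixel pitch; the acquisition hardware fixes objective and
zoom but not pitch, so it is configurable). Cells are somata (6 µm-radius
disks) with straight dendrite branches (default 3 × 60 µm, 1.5 µm wide) in
doublets; field scenes shorten branches so a jittered-grid layout keeps cell
masks provably disjoint. Puncta are uniform disks of radius 0.5 µm
(area ≈ 0.79 µm², inside the 0.5–7.5 µm² detection band), placed on
dendrite centre-lines with a 1.5 µm minimum centre separation so planted
puncta can never merge; each colocalized pair offsets the postsynaptic
partner by ~0.4 µm, guaranteeing ≥ 1 shared pixel. RNAscope nuclei are
non-overlapping ellipses (semi-axes 3.3–4.5 µm, keeping areas above the
30 µm² ROI filter) holding per-probe dots of ~5 px drawn Poisson or fixed
per class.

**Imaging model.** `image = PSF(amplitude·mask) + background`, optional
Poisson shot noise on the whole signal and additive Gaussian read noise;
PSF is a Gaussian of configurable σ (0 = off). With PSF and noise off the
rasters are pixel-exact indicator images of the ground truth, which is what
makes exact round-trip tests meaningful.

**Seeding.** Synapse allocation draws from the `CompetitionParams.seed`
stream; punctum placement and noise draw from a separate scene stream
(derived from the allocation seed unless given). Two scenes with the same
allocation seed but different scene seeds therefore carry identical
per-cell counts at different pixel positions — the property the doublet
tests rely on. Identical (spec, params, seed) triples give bit-identical
rasters.

**What the generator does not emulate.** Out-of-focus light, spectral
bleed-through, curved/branching dendrite geometry beyond straight rays,
axons as connected structures (only sub-threshold fragments), staining
heterogeneity, and optical sectioning. Passing the recovery tests therefore
demonstrates the correctness of the measurement chain, not robustness to
every failure mode of real microscopy.

## Detection conventions

* Binarization is strict (`intensity > threshold`); Otsu per channel by
  default, fixed per-channel overrides available. A constant image under
  Otsu yields an empty mask plus a warning, not an exception.
* Components are 8-connected (particle-analysis default; 4 available).
* The punctum size band "0.5–7.5 µm of continuous pixels" is dimensionally
  ambiguous in its original phrasing; it is read here as **area in µm²**,
  closed on both ends, matching standard particle-analysis practice. An
  equivalent-diameter (µm) mode is provided for the alternative reading.
* Colocalization requires ≥ `min_overlap_px` shared pixels with the union
  of the reference set; default 1 (the "at least one pixel" reading),
  settable to 2 for the stricter "> 1 pixel" reading — the two phrasings
  coexist in the source protocol and the weaker one is the common
  convention. The partner is the reference punctum of maximal overlap, ties
  to the lowest label.
* Linear density is per 100 µm of dendrite with a 50 µm per-cell minimum;
  shorter records are computed but flagged excluded. Field densities are
  per 1000 µm² of **cell-mask area** (not field area, which would make
  density depend on empty space; a field-area mode would be a one-line
  change in `field_density`).

## Doublet analysis

Transfected-cell density counts PSD-95-GFP/vGlut1 colocalized pairs; the
untransfected cell gets `|PSD-95 ∩ vGlut1| − |PSD-95-GFP ∩ vGlut1|`.
Negative subtraction counts (possible with noisy detections) are reported
and flagged, excluded from cohort averages by default rather than clamped,
preserving their diagnostic value; a clamp option exists. Exact density
ties are classified `tie` and excluded from winner proportions — real-valued
densities make them rare, and no published tie rule exists. The winner
contrast builds the 2×2 table of untransfected winners among decided
competitive doublets against transfected winners among decided control
doublets, the published contrast's construction.

## Field analysis

Axon removal deletes connected components below `min_component_area_um2`
(default 50 µm²: above the area of thin axon fragments, below a soma with
proximal dendrites; no published value exists). "Unknown" puncta (equal
non-zero overlap with both channels) are counted and excluded from
densities, never manually reassigned — reproducibility is preferred over
fidelity to the original manual step. The manual "exceedingly high cell
density" exclusion is automated as: > 8 somata or > 60% cell-mask coverage,
both configurable and logged; exclusion changes membership only, never the
values of retained fields.

## Morphometry

Spine-like protrusions are removed by morphological opening (disk radius
0.4 µm, a typical spine-neck scale) — the automated surrogate for manually
erasing protrusions. Mean width is opened-area / length. Length is the
Euclidean distance between the two geodesically most distant pixels of the
opened mask (two-sweep search) plus one pixel of end-caps; this is accurate
for the straight-to-moderately-curved apical-dendrite segments the
measurement targets and rotation-invariant to within about a pixel, whereas
summed skeleton length is biased by end-spur artifacts on wide segments.
Strongly curved or branched structures would need a pruned-skeleton length
instead. Width exactly 1.6 µm classifies **thin** (thick requires strictly
exceeding the boundary). Segments below 40 µm are flagged. Spine counts are
inputs (the counting itself is manual upstream), only densities and cohort
statistics are computed.

## RNAscope

One shared threshold binarizes every probe channel of a section — enforced
by making the threshold a required argument with no auto-selection, since
per-probe auto-thresholds would break cross-probe comparability of dot
counts. Preprocessing is Gaussian blur (σ = 1 px) then rolling-ball
background subtraction (radius 25 px); both values are unpublished choices.
Dots are 4–100 px components (the band is in pixels — dot size is set by the
amplification chemistry, not physical scale). Nucleus segmentation (Otsu →
hole fill → optional watershed split → 30–500 µm² area filter) is an
invented surrogate for an unspecified "automatic" step and is fully
parameterized. Dots join the ROI containing their centroid (order-free,
each dot counted at most once); positivity needs ≥ 10 dots. Blinded
field-of-view selection is an acquisition practice and is not modelled.

## Statistics

Two-sample comparisons use the pooled-variance Student t — fixed by the
published degrees-of-freedom arithmetic (e.g. df = 27 + 47 − 2 = 72), not
Welch. Tukey HSD adjusted p-values come from `scipy`'s studentized-range
distribution with the Tukey–Kramer standard error for unequal n. Fisher's
two-sided p follows the sum-of-no-more-probable-tables convention (the
dominant software convention; a doubled-one-tail mode is provided), with a
1e-12 relative tolerance on point-probability ties; the unit tests pin it
to an exact rational enumeration. Group summaries are mean ± SEM with the
(n − 1)-denominator SD. p-values are kept at full precision; comparisons to
printed values round to the printed decimals.

Four published statistic→p pairs disagree with recomputation by one unit in
the last printed digit because the printed statistic was itself rounded;
one pair (t(76) = 0.01448, p = 0.9882) is consistent only if the
statistic's last digits were transposed (0.01484 reproduces the p exactly).
The tests encode these facts rather than forcing false matches.

## Problem sizes

The test suite and acceptance script use 12–12 µm oracle rasters
(500 per operation), 4–6 rendered doublet/field scenes per recovery check,
40,000 count-level doublets for the null winner fraction, 2,000 cohorts for
the Fisher type-I rate, and 16 nuclei for the RNAscope recovery — sizes at
which every Monte-Carlo tolerance (3 SE) is meaningful while the whole
suite runs in well under a minute.
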