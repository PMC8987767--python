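# Methods

## The classification model

The package classifies exfoliated canine vaginal epithelial cells with a
deterministic decision tree over three morphometric features: cell diameter,
cornification-line count, and nuclear area plus nuclear state. The tree and
its thresholds are fixed by `ClassifierConfig`:

| parameter | default | unit | meaning |
|---|---|---|---|
| `parabasal_max_diameter_um` | 20.0 | µm | cells at or below this diameter are parabasal; only larger cells are evaluated further |
| `cornified_min_lines` | 2 | count | minimum number of cornification lines for "moderate to significant" cornification |
| `intermediate_min_nucleus_area_um2` | 79.5 | µm² | minimum nuclear area for an intermediate call among non-cornified cells |

Three choices in the tree deserve comment:

- **The 20.0 µm boundary is inclusive on the parabasal side.** The rule is
  that only cells *exceeding* 20.0 µm proceed to the cornification step, so
  a cell of exactly 20.0 µm is parabasal.
- **The 79.4/79.5 µm² pair is implemented as a single threshold at 79.5**
  with `area >= 79.5 → intermediate`. Stated as two one-decimal numbers,
  the rule leaves the open interval (79.4, 79.5) undefined for continuous
  measurements; the gap is an artifact of one-decimal reporting and a
  single inclusive threshold preserves the intermediate rule exactly.
- **A large, non-cornified cell with no nucleus** cannot be evaluated at
  the nuclear-area step. We route it to the nucleus-visibility step, where
  it comes out squamous. This is an interpretation (the source flowchart
  does not address the case) and is recorded in the decision trace.

Two further conventions: cornification grade is operationalized purely as
the line count (no subjective grade input is accepted), and the nuclear
state (absent / eroded / demarcated) is an explicit categorical input at the
feature-table level — the morphometry module derives it from images — which
keeps the classifier deterministic and testable. A cell at or below 20 µm
that nevertheless shows cornification lines or an altered nucleus is still
classified parabasal but flagged with a warning in its decision trace,
because validation measurements of 200 sub-20 µm cells found no such cell.

Basal cells are deliberately not an output class; there is no soft or
probabilistic output.

## Threshold calibration

`percentile_threshold` derives the nuclear-area threshold as the q-th
percentile (default 95) of nucleus areas measured on cornified cells with a
demarcated nucleus. The percentile estimator is linear interpolation
between closest ranks (the "type 7" convention) — the most widespread
default and deterministic; the estimator used in the original derivation is
unstated, so the choice is documented here and the raw sample summary
(mean, SD with n−1 denominator) is reported alongside the threshold so
users can compare alternatives. The published summary of such a
measurement — mean 57.7 µm², SD 13.8 µm², n = 200 — is interpreted as mean
and *standard deviation* (an SEM of 13.8 at n = 200 would imply an
implausibly wide spread).

The 20 µm parabasal cut-off is taken as given from the comparative
literature; `validate_parabasal_rule` checks it the way it was validated
empirically: among cells under the cut-off, count any with cornification
lines or a non-demarcated nucleus. The rule "holds" only at a violation
fraction of exactly zero.

## Fleiss' kappa

`fleiss_kappa` implements the standard fixed-rater-count agreement
statistic; all intermediate quantities (per-subject agreement, category
proportions, chance agreement) are returned, and the degenerate case where
every rating falls in one category raises an explicit undefined-kappa error
that still carries the observed agreement. The interpretation bands follow
the quoted convention: below 0.40 poor, above 0.75 good, exactly 1.0
perfect, moderate in between. Boundary values 0.40 and 0.75 are banded
moderate (the convention's inequalities are strict on both sides), and a
value of 0.412 is accordingly banded *moderate* even though such values are
sometimes loosely described as poor; negative kappa is reported as-is and
banded poor. No confidence intervals, weighting or two-rater variants are
provided.

The implementation is cross-checked in the test suite against two
independent oracles: a brute-force count of agreeing ordered rater pairs,
and `statsmodels.stats.inter_rater.fleiss_kappa`.

## Cycle staging

`call_estrus` evaluates one of three literature rule sets, with every
inequality applied exactly as printed (strict where the source says "more
than"): `antonov` (100% superficial + squamous and > 80% pyknotic-or-absent
nuclei), `feldman90` (> 90% superficial keratinized cells, operationalized
on the superficial + squamous proportion since both are keratinized), and
`kustritz` (100% cornification and > 50% anuclear squames). The package
exposes all three and does not declare a canonical one.

Two proxies are documented as proxies: "pyknotic" is approximated by a
demarcated nucleus smaller than the intermediate threshold (the feature
model carries no separate pyknosis flag), and "decreased by at least 20%"
for diestrus onset is read as an absolute 20-percentage-point drop in the
superficial + squamous proportion (the conventional application); a
relative-drop mode is available behind a flag. The onset call requires the
drop *and* neutrophil presence jointly.

## Synthetic smear generator

The generator emulates what a stained smear presents to the classifier, not
how it looks to a pathologist. Feature priors:

- **Diameters** (µm, uniform): parabasal 10–20, intermediate 20–50,
  superficial 30–75, squamous 30–75 — the consensus ranges of the
  comparative literature.
- **Nucleus areas** (µm², normal, truncated below): superficial
  N(57.7, 13.8²) truncated at 0, matching the published measurement;
  intermediate N(95, 15²) truncated at the 79.5 µm² threshold (the mean
  reflects the classical "> 90 µm²" description and the 38.5–95.0 µm²
  diameter-range conversion); parabasal N(60, 10²); squamous eroded
  remnants N(45, 12²). No distributional form is published beyond a
  histogram; truncated normals are an assumption. Nucleus area is
  additionally capped at 45% of the cell's footprint area so the rendered
  nucleus fits inside the cell.
- **Cornification lines**: parabasal always 0 (the empirical validation
  found no cornified sub-20 µm cell), intermediate 0 or 1, superficial and
  squamous 2–5.
- **Nucleus state**: demarcated for parabasal/intermediate/superficial;
  squamous cells are anuclear with probability 0.9, eroded 0.1.
- **Stage mixtures** (parabasal/intermediate/superficial/squamous):
  anestrus 70/30/0/0, proestrus 20/40/35/5, estrus 0/0/30/70, early
  diestrus 20/40/30/10 (with a high neutrophil distractor rate). Only the
  estrus and diestrus criteria are constrained by the literature; the
  other mixtures are plausible defaults and fully configurable. The
  estrus mixture and the squamous anuclear probability were chosen so that
  a default estrus smear satisfies the cytological estrus definitions
  (full cornification, a clear majority of anuclear squames), which a more
  superficial-heavy mixture with a weaker anuclear split would not.

A margin keeps generated features away from the decision boundaries —
`margin_um` (default 1.0 µm) around the 20 µm diameter cut-off and
`margin_area_um2` (default 3.0 µm²) above the 79.5 µm² area threshold — so
ground-truth labels are exactly recoverable by the classifier. The margins
absorb the small positive bias of rasterized Feret measurement and
pixel-count area estimation. With margins set to 0, boundary draws may
legitimately flip class.

The renderer draws flat-shaded cells on a bright background (normalized
intensities: background 0.92, cytoplasm 0.65, nucleus 0.25, eroded remnant
0.55, creases 0.35, Gaussian noise σ = 0.01): angular polygons for
cornified cells, smooth ellipses otherwise, with the longest axis equal to
the cell diameter by construction; nuclei as disks of the record's area;
cornification lines as thin creases parallel to the long axis, placed clear
of the nucleus (a crease is skipped when it cannot fit, so a rendered cell
may show fewer creases than its record — never more). Cells are placed
without overlap by rejection sampling (the empirical measurement protocol
excluded overlapping cells; a failed placement raises an error reporting
the achievable count). Erythrocytes (6 µm pale-centered disks) and
neutrophils (clusters of 1.5 µm dark lobes) are background clutter only and
never enter the ground-truth mask. Rendering is byte-deterministic for a
fixed seed.

What the synthetic data does **not** emulate: staining variability and
color, focus blur, debris and mucus, cell clumping and folding, and the
continuous biological transition between cell types. Passing tests
therefore demonstrate that the measurement-classification chain is
self-consistent, not that it is robust to real stained slides.

## Morphometry

Segmentation is global Otsu thresholding (cells are darker than
background), 8-connected components, then the exclusion rules of the
measurement protocol: regions smaller than an 8 µm disk are debris
(this also removes the distractor clutter), border-touching regions are
excluded, and solidity < 0.8 is the overlap proxy. An image with
negligible intensity range is treated as blank and yields no regions.

Per-region measurements:

- **Diameter** is the maximum Feret (caliper) diameter times the scale —
  the convention matching how an ocular scale is applied to elongated
  cornified cells; equivalent-circle diameter is available as an option.
- **Nucleus**: pixels darker than the region median by `dark_delta`
  (default 0.06) form the dark mask; a binary opening with a 1.5 µm disk
  removes thin creases, the largest surviving blob above 10 µm² seeds the
  nucleus, and the full dark component containing the seed (bounded by a
  small dilation of the seed) is the nucleus mask — recovering the
  boundary pixels the opening shaves off, which keeps the pixel-count area
  estimator unbiased across scales. Michelson contrast between nucleus and
  surrounding cytoplasm decides demarcated (≥ 0.2) versus eroded. No blob
  above the floor means absent.
- **Cornification lines**: the dark mask minus the dilated nucleus is
  skeletonized; components are merged when nearly collinear with a small
  gap and lateral offset (a crease interrupted by the nucleus), and counted
  when at least 25% of the Feret diameter long.

The contrast and ridge parameters are meaningful for this package's
renderer and are not calibrated for stained micrographs.

Problem sizes used in the shipped tests and the reproduction script — 200
rendered cells per pipeline run, 5,000–10,000 cells for table-level checks,
100,000 draws for calibration — mirror or scale up the empirical protocol
(which measured 200 cells per question) while keeping each run in the tens
of seconds.

## Known limitations

- The classifier is exactly as good as its inputs; it encodes one
  standardization of conflicting literature definitions and cannot resolve
  cells whose true biology is transitional.
- Published headline agreement values from multi-rater surveys cannot be
  reproduced here because the underlying rating matrices are not public;
  the kappa implementation is instead verified against oracles and
  reference values that are fully specified (e.g. the 16-rater count row
  (9, 6, 1, 0, 0), whose per-subject agreement is 0.425).
- The morphometry module makes no robustness claims for real stained
  slides; whole-slide formats (svs) are out of scope, as are stain
  simulation and learned segmentation.
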