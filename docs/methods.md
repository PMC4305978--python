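# Methods

## Workflow model

The package models DIA-assisted reference-data production for Ki67
scoring as a four-stage pipeline. (1) An upstream, opaque image
analysis paints every detected epithelial nucleus into a multicolor
*markup* raster, one class color per Ki67 class. (2) The markup is
decoded into machine-generated point marks (dD), one per nuclear
profile, and combined with a systematic grid of unbiased counting
frames. (3) An expert reviews the marks inside the frames and produces
the corrected set (cD) by adding, deleting and relabeling. (4) The
dD/cD pair is diffed, each difference classified and attributed to a
DIA component, and results aggregated across a spot series.

The upstream segmentation itself (tissue classification, nuclear
segmentation) is out of scope: the pipeline consumes its markup raster
and, optionally, its binary epithelial tissue mask.

## Markup decoding

Per pixel the excess channels are `exR = 2R−G−B`, `exG = 2G−R−B`,
`exB = 2B−R−G`, computed in exact signed integer arithmetic (range
[−510, 510]; they sum to zero identically). Class masks are
`exR ≥ t_pos` (positive) and `exB ≥ t_neg` (negative); a pixel passing
both is assigned to the larger excess, ties to positive. Defaults
`t_pos = t_neg = 80`: any saturated class palette clears this by a wide
margin while near-gray background (zero excess) never does. The
green-excess channel is computed for completeness but unused by the
default class rule. Components are labeled with 8-connectivity;
components smaller than `min_area = 20 px` (about half the smallest
rendered nucleus) are noise and dropped; each surviving component
yields one mark at its centroid, rounded half-up to integer pixels so
coordinates survive XML round trips. Two components occasionally round
to the same pixel; a mark set holds one mark per coordinate, so the
first in row-major order is kept and a warning logged.

## Counting frames

Classical unbiased 2D counting frames adapted to point marks, y-down
pixel coordinates: the left edge (x = x0) and bottom edge
(y = y0 + h) are forbidden, the right and top edges accept, i.e. a mark
is counted iff `x0 < x ≤ x0+w` and `y0 ≤ y < y0+h`. With frames on a
regular lattice this is a partition: no point is counted twice, and a
full tiling counts every interior point exactly once. Grids are
systematic uniform random — one offset per grid, drawn uniformly from
`[0, spacing)` per axis. Offsets are drawn as *integers* so frame
coordinates are exact integer pixels and serialize losslessly; on a
pixel raster the integer lattice is the natural sampling space.
Frames that would cross the image border are dropped, not clipped:
clipping would shrink the sampled area unevenly and bias the counted
fraction. Defaults: frame 150×150 px, spacing 2× frame size (a 25%
sampling fraction). These are configurable; no claim is made that they
match any particular historical protocol.

Adaptive sizing: given `n` detected marks and a target review count
`t`, the sampled fraction needed is `f = min(1, t/n)`, met by spacing
`frame_size/√f` per axis (rounded up, floored at the frame size). The
counted fraction of uniformly scattered points equals the frame-area
fraction in expectation, which the property suite verifies to within
three standard errors.

## Annotation XML

ImageScope-style structure (`Annotations → Annotation → Regions →
Region → Vertices → Vertex`), one layer per Ki67 label with
single-vertex point regions, plus an optional grid layer of two-vertex
rectangles carrying the lattice parameters as attributes. Each point
region's `Id` is the mark's position in the full set, so reading
restores the original order even though storage is grouped by label.
Provenance (`AUTO` vs `EXPERT_ADDED`) is an optional per-region
attribute defaulting to `AUTO`. Writing is deterministic and
byte-stable; unknown layers are skipped with a logged warning. The
dialect is interoperable in structure with viewer annotation files but
no bit-compatibility with any vendor product is claimed.

## Audit

Correspondence between dD and cD is greedy nearest-neighbour
one-to-one matching among candidate pairs within a tolerance (default
5 px), taken in ascending distance order with ties broken by (dD
index, cD index). An unmoved mark matches at distance zero, so in the
dominant case matching is exact; greedy is deterministic and every
decision is auditable. Classification: paired equal labels →
TRUE_POSITIVE/TRUE_NEGATIVE (no edit); paired differing labels → one
RELABEL edit, named for the dD error (dD-positive/cD-negative is a
false positive label); unmatched dD → FALSE_DETECTION (one DELETE);
unmatched cD → one ADD, attributed to the tissue-classification
component when the coordinate lies outside the epithelial mask and to
the nuclear segmenter otherwise. False detections are not split by
component: distinguishing a tissue-mask over-call from a segmenter
over-call would require the upstream algorithms' internals, so they
form one category, and the tissue mask (when provided) is only used
for under-detection attribution. A relabel counts as one edit, not a
delete plus an add.

Both sets are restricted to grid-counted marks *before* matching, so
effort metrics reflect exactly the marks the expert reviewed. Ki67% is
`100·pos/(pos+neg)` over the counted marks, NaN when no marks are
counted; NaN spots are dropped pairwise from series statistics with a
logged count.

## Series statistics

OLS regression of cD Ki67% on dD Ki67% (delegated to
`scipy.stats.linregress`; the test suite checks it against the
closed-form normal equations), with R² = 1 − SS_res/SS_tot and the
slope's t-test p-value reported at the conventional 0.05 level but not
gating anything. Zero variance in x makes the slope unidentifiable and
raises; zero variance in y returns a flat fit with R² defined as 0 and
a warning. Bland–Altman: differences y−x, bias = mean, limits of
agreement = bias ± 1.96 times the sample (n−1) standard deviation.

Effort: `pct_edits = 100·edits/cD-nuclei` with edits = relabels +
deletions + additions, and `savings_fraction = 1 − edits/cD-nuclei`,
floored at zero. The rationale for the savings definition: every
reviewed mark that needed no edit is one mark the expert did not have
to place by hand, so the unedited fraction is the manual marking saved.
Reported percentages are rounded to one decimal; raw values are kept.

## Synthetic data

The generator emulates a ~1 mm TMA spot: a disc of diameter 0.9× the
image size containing an irregular epithelial region (union of 24
random discs clipped to the spot), with nuclei as axis-aligned filled
ellipses, radii 4–8 px, placed by hard-core rejection sampling (centers
at least `r1+r2+3` px apart, so components never touch under
8-connectivity and any two centers are ≥ 11 px apart — beyond the 5 px
matching tolerance, making the dD/cD correspondence unambiguous).
Integer centers and point-symmetric pixel sets make the decoded
centroid reproduce the ground-truth coordinate exactly, which is what
turns the generator into an *exact* oracle: with no injected errors the
decoded dD equals the truth mark for mark.

Injected errors, every one logged with category and coordinate:

| parameter | meaning | default |
|---|---|---|
| `p_miss_tissue` | nucleus placed outside the tissue mask (never detectable) | 0.028 |
| `p_miss_nuclear` | within-mask nucleus absent from the markup | 0.241 |
| `false_detections_per_spot` | Poisson rate of spurious components | 68 |
| `p_label_flip_pos` | positive rendered negative | 0.002 |
| `p_label_flip_neg` | negative rendered positive | 0.010 |

The defaults mirror the error composition reported for a calibrated
commercial two-stage (tissue classification + nuclear segmentation)
pipeline on breast-carcinoma Ki67 TMAs, expressed as conditional
per-nucleus probabilities; the false-detection rate is per spot of
roughly 660 nuclei, so smaller synthetic spots over-weight it. Labels
are Bernoulli draws matching the requested Ki67% in expectation.
`simulate_cd` produces a *perfect* expert: cD equals truth, with
provenance recording which marks had to be added.

What the generator does not emulate: stain physics, scanner noise,
focus artifacts, overlapping or touching nuclei, spatially correlated
detection failure, and imperfect experts. Passing the end-to-end
oracle therefore shows the bookkeeping (decoding, counting rule,
matching, classification, aggregation) is exact; it does not certify
performance on real histology, where matching tolerance and thresholds
would need tuning against real markup palettes.

## Numerical and scale choices

Deterministic throughout under seeds: one integer seed drives a spot, a
master seed spawns per-spot child seeds (all < 2³¹) for series.
Centroid rounding is half-up (`floor(v+0.5)`), avoiding banker's
rounding surprises. Matching distances are exact Euclidean on integer
coordinates. Packing uses 2000 placement attempts per nucleus before
declaring the geometry infeasible; requested densities above ~70% of
the random-sequential-adsorption jamming density of the tissue region
will fail fast rather than loop. Validation and the acceptance script
use 100-spot cohorts of 500–660-nucleus spots at 896–1024 px — large
enough for stable rates while keeping a full run in tens of seconds.

## Known limitations

* Component attribution of *over*-detections is not possible from the
  markup alone; all false detections form one category.
* The greedy matcher is order-deterministic but not globally optimal;
  with the enforced ≥ 11 px mark separation and 5 px tolerance the
  optimal and greedy matchings coincide, but on real data with dense
  marks a Hungarian assignment could differ.
* The perfect-expert simulator makes cD = truth; real experts disagree
  with each other, so real cD sets carry reviewer noise the audit will
  attribute to the machine.
* Thresholds (80), `min_area` (20 px) and the frame defaults are
  package choices for the synthetic palette and geometry, configurable
  for real markup conventions.
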