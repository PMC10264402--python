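# Methods

`stmatch` implements a consensus workflow for reference-based cell-type
assignment of imaging-based spatial transcriptomics data: individual
correlation matchers produce per-cell, per-subclass confidence scores;
ensemble combiners merge several methods' scores into a consensus; agreement
and laminar-depth statistics quantify the result; and a guided
segmentation-free mode types pixels directly from spot coordinates. This
note records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## Data model and normalization

Counts are raw molecule counts per segmented cell and gene. Library-size
normalization rescales each nonzero expression vector to a fixed total
(default 10, the convention used for pixel vectors and signatures in the
guided mode) and the log transform is the natural `log(1 + x)`, which keeps
zeros at zero and avoids −∞. All-zero vectors pass through as zeros rather
than erroring, so empty cells and background pixels flow through the
pipeline and end up unassigned. Coordinates are continuous µm in a
Cartesian plane; cortical depth is µm from the pia, increasing toward white
matter.

Gene-panel accounting (`panel_overlap`) is exact set arithmetic after an
optional single case-fold; no alias resolution is attempted, because panel
membership is an input, not something the package arbitrates.

## Quality control

Cells are screened on four segmentation statistics with per-protocol
presets (`merfish`, `smfish`, `baristaseq`, `exseq`). The boundary
conventions are deliberate and preserved literally: transcript minimum
inclusive (`≥`), elongation bound exclusive (`<`), area half-open
(`min ≤ area < max`), confidence bound strict (`>`). Removal counts are
reported per rule and overlap (a cell failing two rules counts under both);
no precedence ordering is imposed. Region cropping takes a user-supplied
simple polygon and keeps centroids inside or on the boundary — anatomical
region outlines are drawn by eye in practice and are not computable here.

## Correlation matchers

`match_correlation` computes, per cell, the Pearson correlation vector *y*
against per-subclass cluster profiles (median by default) over the shared
gene panel, then maps it to probabilities with the scaled-correlation
transform

    s_i = max(y_i − max(y)/2, 0)²,   p_i = s_i / Σ s

so only types correlating above half the best correlation receive mass and
contrast is sharpened quadratically. The transform preserves the argmax
whenever any mass survives; if `max(y) ≤ 0` the row is all-zero and the
cell is unassigned. Undefined correlations (constant vectors) score 0
rather than propagating NaN. Both sides are restricted to shared genes and
(by default, switchable) library-size normalized and log-transformed before
correlating.

`match_bootstrap` quantifies the stability of the best-correlated
assignment under gene-panel perturbation: each of B rounds (default 100)
draws `⌈gene_fraction · G⌉` genes (default fraction 0.8) without
replacement, assigns each cell to its best-correlated profile, and the
confidence is the vote fraction. Per-round exact ties go to the first type
in taxonomy order, making runs bit-reproducible from the seed. The
sampling scheme (without replacement, fraction 0.8) is this package's
choice; bootstrap matchers in the field vary in these details and no
single convention is canonical.

## Ensemble combiners

**Geometric-median combining.** For each cell the m methods' rows are
vertices in Rⁿ and the combined row is their geometric median — the point
minimizing the sum of Euclidean distances. The solver is Weiszfeld
iteration initialized at the componentwise mean, stopping when the step
norm falls below 1e−9 or after 1000 iterations; iterates that land exactly
on a data point use the Vardi–Zhang corrected update, which also certifies
vertex optimality (this yields the majority property: any point shared by
more than half the methods is returned exactly). Two degenerate cases are
resolved by convention: for m = 2 the whole segment is optimal and the
midpoint (= mean initialization, a fixed point of the update) is returned;
identical points return that point. Input rows are renormalized to sum 1
by default before combining, since upstream methods emit scores on
incomparable scales but the median is taken between probability rows.

**Negative-weighting combining.** Per method and cell, the top-scoring
type keeps its score and every other type is weighted −1; the combined
matrix is the elementwise sum. Ties for a method's top retain all tied
types by default (`tie_policy="first"` keeps only the first in taxonomy
order). Combined scores are reported raw in [−m, m] with no rescaling:
confidence scores are not comparable across methods, so only the ranks of
the combined scores are meaningful, and the deterministic assignment uses
only the argmax.

Deterministic assignment is per-cell argmax with taxonomy-order
tie-breaking; all-zero rows map to `UNASSIGNED`.

## Agreement

Cohen's kappa is the unweighted multi-class form computed from the
cross-tabulation; subclasses carry no ordinal structure, so weighted kappa
is out of scope. Cells unassigned by either labeling are excluded pairwise
rather than treated as a class — a refusal to assign is not a category —
and the excluded count is reported to keep this auditable. Qualitative
bands follow the usual interpretation scale (≤ 0 none, to 0.20 slight, to
0.40 fair, to 0.60 moderate, to 0.80 substantial, to 1.00 almost perfect).
Subclass overlap reports, for every exact combination of methods, the
number of cells assigned the subclass by precisely those methods (the
buckets of an UpSet plot); buckets partition the union of the per-method
sets.

## Depth statistics

Depth bins are half-open `[k·w, (k+1)·w)` anchored at the pia, width 25 µm
by default. Spot depth densities are fixed-bandwidth 1-D Gaussian KDEs of
pooled marker-gene spot depths, normalized to integrate to 1 on the
evaluation grid; the default bandwidth is 25 µm (bin scale — the smoothing
used for published laminar density curves is not standardized). For raw
spots, depth is the signed projection onto a user-supplied
pia→white-matter axis. The ensemble bin table reports, per bin, the mean
over individual methods of the matched fraction (`avg_frac`), the mean
number of methods matching a cell to the subclass (`avg_method`), and the
matched fraction of each combined labeling.

## Guided pixel typing

Per gene, every molecule deposits an isotropic 2-D Gaussian (σ = 2.5 µm)
evaluated at the centers of 1 µm pixels and truncated at 4σ; with these
defaults the sampled kernel mass per molecule is 1 within well under 1%,
so total field mass ≈ molecule count. Pixel size and truncation radius are
rasterization choices, configurable. Per-type signatures are the mean of
library-size-normalized (target 10), log-transformed expression vectors of
the labeled cells. Pixel vectors are normalized identically and
Pearson-correlated against the signatures over the signature panel; a
pixel takes the argmax type when that correlation is ≥ 0.6, else stays
unassigned. A density floor (default total raw density ≥ 1e−3 molecules)
masks empty background before normalization — practical correlation maps
exclude background, so the mask is explicit and configurable. Because
normalization absorbs uniform scaling, labeling is invariant to rescaling
the raw field (with the floor scaled accordingly).

## Synthetic tissue generator

The generator emulates the features of laminar cortex that the workflow
depends on: six contiguous layers spanning 0–1000 µm of cortical depth,
twelve subclasses with layer-restricted mixtures (inhibitory types spread
across layers, excitatory types layer-specific, astrocytes everywhere),
two marker genes per subclass elevated 20-fold over a baseline
negative-binomial mean of 0.3, and a 250-gene universe. Four protocol
presets subset the panel and thin counts binomially, mirroring the spread
of real imaging panels (250 genes at efficiency 0.7, 30 at 0.9, 79 at 0.5,
42 at 0.8). Counts are negative-binomial with `var = µ + φµ²` (φ = 0.5 by
default; φ → 0 is the Poisson limit) — a standard overdispersion model, not
a fit to any real dataset. Spots scatter isotropically (σ = 5 µm) around
cell centroids. Segmentation statistics (elongation, area, confidence) are
drawn from log-normal/beta distributions chosen so QC presets remove a
realistic minority of cells; they are independent of expression, which real
segmentation statistics are not.

Simulated method ensembles (`generate_confidences`) flip each cell's label
with a given probability (default 0.25) to a uniformly drawn wrong type
and emit softmax rows peaked at the chosen type (temperature 0.25, with
sub-0.5 uniform logits elsewhere so the chosen type always holds the row
maximum and the zero-temperature limit is exactly one-hot). Method errors
are independent — real methods share biases, so consensus gains measured
here are an upper bound on what correlated ensembles would give.

What passing tests on this generator do show: the matchers, combiners and
pixel typer recover planted structure at realistic panel sizes, noise and
detection efficiency, and the consensus strategies beat the average
simulated individual method. What they do not show: robustness to
segmentation errors, optical crowding, spatially correlated noise, or the
empirical count distributions of any specific protocol.

A separate synthetic four-panel gene table
(`synthetic_protocol_panels`) reproduces the published set arithmetic of
the four imaging-protocol panels — sizes 253/22/79/42, six genes common to
all four, union 314 — with synthetic filler names, so panel accounting is
testable without the original supplementary tables.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data at
deliberately modest sizes — 2000-cell sections, 50 cells per reference
type, a 400-cell two-layer scene for pixel typing, 100 random
geometric-median instances against a 1e−3-step simplex grid — chosen so a
full run completes in well under a minute while keeping every statistical
margin wide (matcher accuracy ≈ 0.93 against a 0.9 bound; pixel agreement
≈ 0.999 against 0.95; consensus gains ≈ +0.23).

Grid-oracle comparison note: on near-flat objectives a discrete grid
cannot localize the minimizer more tightly than its own step, so the
well-posed agreement check is on the objective value (the solver's sum of
distances must not exceed the grid minimum by more than 1e−3; in practice
the solver is strictly better), with coordinate agreement asserted at two
grid steps.

## Known limitations

- The bootstrap matcher is a generic gene-subsampling scheme, not a
  re-implementation of any published tool's internals.
- Depth-density curve shapes depend on the KDE bandwidth, which published
  figures rarely state; comparisons should be qualitative.
- The guided mode produces only the thresholded pixel label map; local
  maxima extraction and de-novo clustering of field vectors are out of
  scope.
- Kappa values depend on how unassigned cells are handled; the pairwise
  exclusion used here is one defensible convention and is reported
  alongside the excluded count.
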