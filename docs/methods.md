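# Methods

## Problem setting

Image-based RNAi screens on printed cell arrays measure, for every
well, the per-cell values of 27 features describing two parallel
endocytic routes in *Drosophila* S2R+ cells — the clathrin-dependent
(CD) pathway tracked by transferrin (`T*` features) and the
clathrin-independent CLIC/GEEC (CG) pathway tracked by fluid-phase
dextran (`F*` features) — plus nuclear and cell geometry.  Well arrays
carry systematic positional artifacts (row/column/edge biases), and
most perturbations are subtle: they change the *shape* of the
single-cell feature distribution rather than its mean.  The package
quantifies those shape changes, calls hits in triplicate, organizes
hit genes on a parsimony tree of the features they perturb, annotates
and enriches tree nodes, and classifies genes by a secondary
pulse/chase assay.

## The shape Z-score

For a test well with per-cell sample $x$ and the pooled reference
negatives $r$ of the same slide, the two-sample Kolmogorov–Smirnov
statistic is

$$D = \sup_t |\hat F_x(t) - \hat F_r(t)|.$$

Under `shape_mode` (default on) every sample is affine-normalized
(mean 0, SD 1) first, so location and scale — including multiplicative
positional artifacts — cancel and only shape differences register.
Because the null $D$ scales like $n^{-1/2}$, we standardize the
size-adjusted statistic $T = D\sqrt{nm/(n+m)}$, whose null law is
nearly free of the cell count, against an empirical null:

* the negative wells of each slide are split (seeded, default 50/50)
  into a *reference* set that defines the null and an *evaluation* set
  held out to measure the false-positive rate;
* each reference well is compared against the pool of the remaining
  reference wells (leave-one-out), giving per-slide null $T$ values;
* per feature, the null values of all slides are pooled and summarized
  robustly (median, $1.4826\times$MAD).  Comparisons remain
  slide-local; only the null *moments* pool.  Slide-local classical
  moments are available with `pool_calibration=False`.

$Z = (T - \mathrm{med})/\mathrm{MAD}^*$.  Wells with fewer than
`min_cells = 50` cells are missing, not zero.  The Z-score is unsigned
(KS is two-sided); direction comes from the secondary assay.

Why robust pooled moments: a single slide's ~15 leave-one-out values
estimate the null SD poorly, and a noisy SD for one slide×feature
silently suppresses (or inflates) every gene on that slide for that
feature — a *correlated* error that downstream tree building is very
sensitive to.  Pooling across slides is valid because shape
normalization removes the slide-specific scale; the median/MAD pair
resists the occasional aberrant reference well, as is standard for
screening statistics.

## Hit calling

A gene is a hit for a feature when at least 2 of its 3 replicate
Z-scores reach the threshold (default 3, inclusive `>=`; `strict`
flag for `>`).  Genes with fewer than two scored replicates are
unevaluable.  The per-feature false-positive rate of the triplicate
rule is $3f^2(1-f)+f^3$ for single-well rate $f$.  The
permutation control shuffles Z-scores across genes independently per
(feature, replicate), destroying replicate concordance while keeping
every marginal distribution, and re-applies the same rule.

## Feature tree

Hit genes' 27-bit feature vectors become binary *characters* over the
27 features as *taxa*.  Characters hitting fewer than two features are
set aside (they reside at their single leaf).  Search: random-order
stepwise addition followed by nearest-neighbor-interchange
hill-climbing, best of 25 shuffled restarts, scored by exact Fitch
parsimony (bit-packed, rooted along a leaf edge; a character present
in *all* taxa still counts one origin event).  Support: 100
half-jackknife replicates (retain ⌈G/2⌉ characters without
replacement), majority-rule consensus (> 50 %), support = replicate
percentage; polytomies are kept.

Ancestral states on the consensus use unit-cost Sankoff dynamic
programming (exact for polytomies).  A provisional penalty-free pass
counts state-1 characters per internal node; the least-populated node
becomes the root (ties → lowest node id).  The final pass charges a
state-1 root one origin event and breaks ties toward state 0, so
equal-cost reconstructions prefer independent gains over a deep gain
plus losses — losses are interpreted as assay false negatives.  Gains
(0→1) and losses (1→0) along rooted edges populate per-node gene
sets; the per-character event count equals the brute-force minimum
(verified exhaustively in tests).

## GO pull-up

Each leaf receives the union of cellular-component terms of its hit
genes.  A term's homes are the maximal nodes whose entire subtree leaf
set carries the term: a term covering one clade rises to that clade's
node, a term on all leaves reaches the root, scattered occurrences
stay at their leaves.  Six generic terms (cytoplasm, nucleus,
membrane, intracellular, extracellular region, plasma membrane) are
forced to the root.  Every occurrence is covered by exactly one home,
and additional occurrences can only move a home upward.

## Enrichment

Hypergeometric upper tails for term/ortholog/screen enrichment;
Benjamini–Hochberg correction by default (Bonferroni available),
significance reported at corrected p ≤ 0.05.  Interaction edges are
confidence-filtered at ≥ 0.400 (inclusive).  Within-node interaction
enrichment compares the observed within-node edge count against
permuted networks that redraw the same number of edges uniformly over
the network's gene universe (no self-edges or duplicates); a
degree-preserving double-edge-swap variant is available behind a
flag.  Empirical p uses the +1 pseudo-count, so it is never zero.

## Secondary quadrant assay

Each gene's three test wells sit beside six local negative and three
local positive wells; fold ratios are test means over the local
negative mean, tested two-sidedly (Welch by default; pooled-variance
flag).  Axes dichotomize at ratio 1, but an axis counts as changed
only when significant at p < 0.10 — the sign of a non-significant
axis is noise and carries no direction.  Quadrants: 1 = pulse and
chase up, 3 = both down, 2 = chase down without pulse down
(late-acting genes), 4 = other mixed patterns; a gene is null when
neither axis is significant.  The concordance summary uses the exact
binomial sign test, e.g. 21 successes in 22 fair trials gives
$23/2^{22} \approx 5.5\times10^{-6}$.

## Image features

Channels are processed with white top-hat (image minus grayscale
opening by a disk) at three radii — fluid 64/10/5 px, transferrin
64/14/7 px (larger small/medium disks accommodate tubular Tf
endosomes).  Disks with radius > 16 use skimage's sequence
decomposition of the footprint (a close approximation that is orders
of magnitude faster; small radii are exact).  Endosomes are
8-connected components of the small-radius top-hat above an Otsu
threshold floored at 3× the robust noise MAD, minimum area 2 px.
Choices the upstream assay leaves open and our stand-ins: circularity
$=4\pi A/P^2$ with the Crofton perimeter (the least biased standard
estimator — an ideal rasterized disk still reads ≈0.94 at radius
10 px); `NucFluct` = coefficient of variation of nuclear-channel
intensity in the nuclear mask; `NucDist` = nuclear-to-cell centroid
distance in pixels; colocalization by spot-centroid containment
(pixel-overlap variant by flag).  Segmentation is an input; the
Otsu+watershed fallback is for convenience only.

## Synthetic data

The generator defines the testbed conditions: 10×30 arrays with 30
negative and 8 positive wells per slide, triplicate slides, cell
counts negative-binomial with mean 150, per-cell baselines log-normal
(intensities), gamma (counts/sizes) and beta (bounded fractions) —
heavy-tailed, bounded families typical of single-cell data, with the
parameters exposed in the config.  Positional artifacts multiply
row × column × edge factors drawn uniformly within ±15 % per slide;
they apply to unbounded features only, because clipping a scaled beta
variate at 1 would itself create well-to-well shape differences under
the null (bounded geometric features are also the artifact-robust ones
in practice).  Gene effects: `shift` (add k baseline SDs), `scale`
(stretch about the mean), `skew` (shift a subpopulation, default 30 %
of cells, by k SDs — a pure shape change).  Positive-control wells
receive strong skew effects on the six core intensity features.
Everything is a pure function of config + seed.

What the generator does not emulate: correlated features (each of the
27 is drawn independently, so e.g. Rto ≠ Tint/Okt numerically),
cell-density dependence, optics beyond Gaussian spots, or real
per-cell distribution families (unreported upstream; ours are
stipulated).  Passing tests therefore demonstrate statistical
correctness of the pipeline under known ground truth, not performance
on real images.

## Problem sizes and seeds

The acceptance checks run a 500-gene null screen and a 150-gene
planted screen (100 affected genes in 12 nested groups) at 150
cells/well in triplicate, 100 jackknife replicates × 25 restarts for
the tree, 9 999 permutations for the planted interaction module and
999 for the null-uniformity check — sizes at which every statistical
band is stable across seeds while a full run stays in minutes on one
core.  All randomness flows from explicit integer seeds through
`numpy.random.Generator(PCG64)`.

## Known limitations

* The exact scaling of the upstream "modified KS" statistic is not
  public; our contract is the reproduced one — null mean ≈ 0, SD ≈ 1
  against held-out negatives — not bit-equality.
* Consensus trees may contain weakly-supported arbitrary resolutions
  when characters cannot distinguish placements; only supports well
  above 50 % are meaningful.
* PHYLIP tie-breaking is not reproduced; event *counts* match the
  Sankoff minimum but the chosen reconstruction among equal-cost ones
  follows our documented gain-biased convention.
* The GO pull-up treats terms as opaque labels; no ontology-graph
  ancestor expansion is performed.
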