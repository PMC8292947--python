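# Methods

This note documents the models implemented in `molvocab`, their assumptions,
the defaults that matter, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Occurrence censuses

An occurrence matrix holds non-negative integer counts of traits (protein
domains, GO terms, loops, architectures...) across genomes, each genome
labeled with a superkingdom (A, B, E; viral genomes labeled V are accepted
and excluded from the default partition). All census statistics binarize at
count ≥ 1: the distribution index and the Venn groups are presence/absence
notions, and abundance is consulted only by the law fits.

The distribution index of trait *t* in a genome subset *S* is
`f(t) = |{g ∈ S : count(t, g) ≥ 1}| / |S|`, stored as an exact rational
(`fractions.Fraction`). This makes threshold predicates such as `f = 1`
(universal) or the strict `f > 0.5` decidable without floating-point
tie ambiguity. Traits are assigned to one of the seven disjoint Venn
taxonomic groups (ABE, AB, AE, BE, A, B, E) by the exact set of
superkingdoms containing them; with viruses included, the 15-group
A/B/E/V partition is built instead.

`venn_complete` reconstructs a full partition from any mix of directly given
group counts and superkingdom totals (each total being the sum of the four
groups containing that superkingdom). The system is solved by exact rational
Gaussian elimination; underdetermined systems report the free groups by
name, and infeasible, negative, or non-integer solutions are errors rather
than rounded. On-disk matrices are TSV with traits as rows and genomes as
columns — the transpose of the heatmap orientation — because every other
per-trait table (ages, f-profiles, Venn membership) is row-per-trait.

Cross-census summaries report fold ratios of vocabulary totals and of
superkingdom-specific groups with mean, standard error `sd/√n`, and the
adjusted Fisher–Pearson skewness (the common "sample skewness"; the
estimator choice is a convention, flagged undefined rather than zero for
fewer than three censuses).

## Law fitting

**Zipf.** The occurrence spectrum maps `k` (total occurrences of a trait) to
the number of traits occurring `k` times. The tail `k ≥ xmin` is fitted by
discrete maximum likelihood: `P(k) = k^-γ / ζ(γ, xmin)` with the Hurwitz
zeta normalization, γ maximized by bounded scalar optimization on
γ ∈ (1, 20] to 1e-8 tolerance. Counts are modeled as discrete throughout —
no continuous approximation — because trait occurrences are integers and the
continuous MLE is biased at small `k`. Goodness is reported as the KS
distance between the empirical and fitted discrete tail CDFs plus a
p-value from a seeded semiparametric bootstrap (default 100 replicates:
sample `n_tail` draws from the fitted law, refit, recompute D; the p-value
is the fraction of replicate D ≥ observed D). Automatic `xmin` selection
minimizes D over the observed candidate cutoffs. Sampling from the discrete
law uses exact inverse-CDF inversion via a vectorized binary search on the
complementary CDF `ζ(γ, k)/ζ(γ, xmin)` — not the floor approximation, which
biases γ recovery at small xmin. The fitters only ever report statistics;
deciding whether a "law holds" is left to the analyst, since heavy-tailed
count data admit many regularly varying alternatives.

**Heaps.** A vocabulary-growth curve is either the cumulative distinct-count
trajectory of an ordered token stream or, in proteome mode, one point per
proteome (N = total occurrences, V = distinct traits), sorted by N with ties
broken by proteome id for determinism. Multi-regime fits run an exact
dynamic program over contiguous segmentations of the log–log points,
minimizing total SSE with closed-form per-segment SSE from prefix sums; the
segment count is chosen by BIC (`n·log(SSE/n) + 3s·log n`, three parameters
per segment) unless forced. Curves longer than 256 points are thinned to
geometrically spaced N first — the fit lives in log–log space, where densely
linearly sampled large-N points would otherwise dominate every segment.
Note that the kernel/novelty stream generator (below) with a *constant*
novelty probability p produces asymptotically linear growth `V ≈ pN`
(β → 1): the sublinear Heaps signature requires a decaying novelty schedule,
which is how the generator is exercised in the tests.

**Menzerath–Altmann.** Per-`k` mean part lengths `z_k` are fitted as
`log z_k = log A + b·log k` by weighted least squares with weights `n_k`
(the number of proteins with `k` domains); inverse-variance weighting would
require per-`k` variance estimates that single-proteome data rarely support,
so count weighting is the default and unweighted fitting is available.
`A = exp(intercept)` is the fitted length at `k = 1`; R² is computed on the
weighted fit and flagged undefined (not 1 or 0) when the response has no
variation. The fit is invariant under duplicating every protein.

## Timelines and ontologies

Relative ages come from a rooted tree with branch lengths: every labeled
node (internal or leaf) gets `age = dist(root, node) / max_node dist(root, ·)`,
so the root is age 0 and the most derived node age 1. Ages are invariant
under uniform branch-length rescaling. A pectinate four-leaf tree with unit
branches therefore exhibits exactly the ages {0, 1/3, 2/3, 1} across its
nodes. The linear clock maps `gy(nd) = origin·(1 − nd)` with a configurable
origin (default 3.8 Gy before present); the calibration of any particular
molecular clock is not reproduced here.

GO-style graphs carry typed child→parent edges (`is_a`, `part_of`,
`regulates`). Terminal terms of a namespace are its `is_a` leaves. Level
assignment walks `is_a` edges only, with the namespace root at level 0 and
its direct children at level 1 ("the highest three levels" are 1–3). A term
reachable at several depths is collapsed to a single retained level — the
minimum depth by default (the shallowest annotation is the most general
sense of the term), with maximum-depth collapse as an option. Terms with no
`is_a` path to the root (connected only through `part_of`/`regulates`) are
excluded from leveling and reported.

`f_trajectory` joins a matrix with an age table into per-superkingdom
(age, f) series; the first-loss age is the minimum age among traits with
`f = 0` in a taxon (None when nothing is fully lost). Group age statistics
report per-Venn-group median ages, an oldest-first ranking (exact median
ties broken by group name), and outliers by the 1.5×IQR boxplot convention —
the standard convention, adopted because no other criterion is specified for
these plots.

## The synthetic-data generators

All generators are bit-reproducible under a fixed seed
(`numpy.random.default_rng`).

* `sample_discrete_powerlaw`: exact draws as described above. Default
  γ = 2.0, xmin = 1 — the exponent regime typical of domain occurrence
  spectra.
* `simulate_kernel_growth`: at each step a never-seen token is emitted with
  the schedule's novelty probability, else an existing token is re-drawn
  proportionally to its current frequency (Yule/Simon-style preferential
  reuse, implemented as a uniform draw from the emission history). The
  two-probability structure (kernel reuse vs novelty) is kept and its
  parameters exposed; no claim is made to reimplement any particular
  published feedback model.
* `simulate_ma_proteome`: for each `k = 1..kmax` (default 10), `n_per_k`
  (default 20) proteins with domain lengths `A·k^b·exp(N(0, σ²))`. Defaults
  A = 200 residues, b = −0.2, σ = 0.05: a single-domain length and slope in
  the middle of the ranges reported for cellular proteomes, with mild
  multiplicative noise. Lognormal noise keeps lengths positive; no noise
  model is canonical for this quantity.
* `simulate_vocabulary_evolution`: traits are born (Poisson, default 2 per
  step over 100 steps) into one uniformly chosen extant lineage on a fixed
  deterministic lineage tree: one ancestral lineage splits into the A stem
  and the B/E stem at relative age 0.1, B and E separate at 0.2, and each
  stem bifurcates at evenly spaced times until its superkingdom reaches its
  configured lineage count (default 8) by age 0.8. A fixed topology (rather
  than a random coalescent) makes oracle checks deterministic. Both
  daughters inherit the parent's traits; each present trait is lost per
  lineage per step with its superkingdom's loss probability (defaults
  A 0.02, B 0.01, E 0.01 — mild, Archaea-biased loss), and from the
  horizontal-transfer onset age (default 0.5) each surviving trait jumps
  into one random lacking lineage with the transfer probability per step
  (default 0). Recorded ages are birth times quantized to a 0.01 grid,
  which deliberately creates age ties for exercising word-cloud collision
  handling. Births before the first split are ancestral and universal;
  later births are clade-confined — this vertical dilution plus loss
  produces the declining-f "losing" trend, and late transfer produces the
  "expansive" trend with post-onset traits reaching high f.
* `make_synthetic_go_terms`: head-final names (1–2 modifiers plus a head)
  drawn from per-Venn-group word pools, guaranteed to round-trip through the
  tokenizer; repeated names keep their first age so dominance is
  well-defined.

What the generators do *not* emulate: real sequences or structures, paralog
copy-number dynamics (matrices are effectively presence/absence), gene-tree/
species-tree discordance, correlated loss across lineages, or empirically
calibrated birth/loss/transfer rates. Passing tests therefore demonstrate
that the *analyses* recover the structure they assume — not that real
proteomes satisfy these laws at any particular parameter values, which
depends on external census data.

## Word clouds

Tokenization is induced from the worked naming patterns: the last
space-separated word is the head, the previous word the sub-head, and all
remaining left words join (order preserved) into a single modifier chain;
hyphenated words are single tokens. The rule is a plain function so
alternative chain groupings can be substituted.

A unit's dominance is the minimum age over terms containing it. Layout
processes terms oldest-first (ties by term id): each not-yet-placed unit is
placed at x = its dominance age, starting on the row of its term's anchor
(the unit of the same term placed just before it; the base row for a term's
first unit), and moved up one row at a time on bounding-box collision.
Placed units never move; later terms that reuse a unit flag it as repeated
(outline font). Units of a single term share the term's age, so sub-head and
chain necessarily stack upward from the head's row — the precedence axis
reads upward by convention. Bounding boxes are approximated as
0.6·font·characters wide and 1.2·font high in canvas units, which keeps the
layout independent of font metrics and therefore deterministic; rows are
max-font-height tall, so cross-row overlap is impossible by construction and
the no-overlap invariant reduces to disjoint x-spans per row (still checked
exhaustively in tests). Font sizes map linearly from unit frequency to a
10–30 pt range (all-equal frequencies map to the midpoint); colors come from
a fixed 7-color per-group palette, and a unit named by terms of several
groups takes the group of its oldest term. Per-group clouds are combined by
stacking each subsequent group's rows above the previous ones, preserving
the union of placements without cross-group overlap. SVG output is generated
by direct string templating so that re-rendering the same layout is
byte-identical.

## Persistence triangle

Economy/flexibility/robustness scores (a matter–energy budget and two
mechanism counts) are normalized to barycentric coordinates — scale-invariant
by construction — and drawn in the unit triangle with economy at the origin,
flexibility at (1, 0) and robustness at the apex. The placement is a
visualization device only: no quantitative axis from molecular data to these
scores is defined, so none is inferred.

## Problem sizes and determinism

The test suite and acceptance checks run at desk scale by choice: 10^4 draws
for exponent recovery, 10^4-step growth streams, 200-trait/24-genome
evolution scenarios, 500-term clouds, and ≥100 randomized small instances
per brute-force oracle comparison. Every stochastic component takes an
explicit seed, and bootstrap p-values are seeded, so all reported numbers
are reproducible bit-for-bit.

## Known limitations

* The bootstrap KS p-value is approximate at its default replicate count
  (resolution 1/100) and, like any test with estimated parameters, rejects
  a true power law about 5–6% of the time at the 0.05 level.
* Level assignment assumes a single namespace root reachable by `is_a`;
  multi-root subsets must be split beforehand.
* The Venn completion returns the unique exact solution or an error; it does
  not least-squares-reconcile over-determined inconsistent counts.
* The evolution simulator's lineage tree is fixed and balanced; it is not a
  sampled phylogeny, and transfer is uniform across lineages rather than
  distance-dependent.
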