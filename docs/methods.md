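# Methods

This note documents the statistical and algorithmic choices behind
`fuseki`, in the spirit of a model-description appendix: what each stage
computes, the assumptions and defaults, what the synthetic corpus does and
does not emulate, and the numerical conventions that make outputs
deterministic.

## Corpus model and cleaning

A corpus is a list of game records: an ordered move sequence on the 19×19
grid plus metadata (date, players, nationalities, handicap, komi, result,
AI flags). Records are read from SGF (FF[4] conventions, `GM[1]`,
`SZ[19]`); pass moves are dropped, variations follow the main line, and
unrecognised properties are preserved opaquely so writing re-parses to an
equal record. AI players are flagged with the extension properties
`AIB[1]`/`AIW[1]`; nationalities ride on `BC`/`WC`.

Cleaning removes, in priority order: handicap games (`HA > 0`), games
without a parseable year, games before 1600, and games involving an AI
player. Each removed game is attributed to exactly one reason — the first
that applies — so report counts always reconcile even when reasons
overlap. A bare year is a valid date (much of the historical record is
year-only); a game spanning two dates uses its start year.

Retained games are segmented two ways:

- **Eras** — six named periods partitioning 1600–2024 at 1867/68, 1945/46,
  1972/73, 1991/92, 2015/16, chosen for the major ruptures in how players
  learned the game (print, war and partition, internationalization, the
  internet, superhuman AI).
- **Time bins** — annual from 1950, 5-year (anchored at 1850) for
  1850–1949, 25-year (anchored at 1600) earlier, compensating for the
  sparseness of the early record. Anchors sit at the regime boundaries;
  the bins tile the timeline without overlap.

## Symmetry canonicalization

The board's symmetry group is D4 (order 8). A game's canonical form is the
image under the transform that (i) puts the first move in the *closed*
top-right quadrant (col ≥ 10 and row ≥ 10 — closure guarantees a
qualifying transform exists for every first move, including axis and
center points) and (ii) among qualifying transforms minimizes the whole
transformed sequence lexicographically, points ordered by `(col, row)`;
remaining ties fall back to declaration order of the transforms. This
makes canonicalization idempotent, orbit-invariant (any pre-transform of
the input yields the same output), and total.

Orbit counting uses Burnside's lemma. A sequence of distinct points is
fixed by a group element iff every point is, so each element's fixed-
sequence count is the falling factorial P(f, depth) of its fixed-point
count f: 361 for the identity, 1 (the center) for each rotation, 19 (the
axis) for each reflection. The count for depth 7 is
94,198,450,418,435,160 ≈ 9.4 × 10¹⁶. For depths 1–2 the tests verify the
formula against exhaustive orbit enumeration.

## Diversity and divergence

Variants are comma-joined Korschelt labels of the first `depth` canonical
moves (default 2). Games shorter than `depth` are excluded from tallies
and reported, not given a sentinel label. Hill numbers are computed
directly on the frequency vector; q = 1 uses the exp-entropy limit. JSD
uses base-2 logarithms by default (bounded by 1 bit; natural log is an
option) with the 0·log 0 ≡ 0 convention; distributions are zero-padded to
the union of labels.

The bootstrap series draws `n_draw = 100` games with replacement per bin
and averages the statistic over `n_iter = 100` iterations — the constant
draw size is the point, since raw bin sizes span four orders of
magnitude. Bins smaller than `n_draw` are still resampled to `n_draw`.
For the divergence-versus-previous series, draws are paired across
adjacent bins within an iteration, and a bin is compared against the
nearest preceding non-empty bin. Empty bins yield missing values with a
warning. A test-only `replace=False` mode confirms the estimator
converges on the plug-in value when subsampling is disabled.

Where the *era-level* ¹D is estimated for recovery comparisons, the
plug-in entropy gets the Miller–Madow correction (+(S−1)/2n before
exponentiating) and a bootstrap standard error; the recovery tolerance is
3 SE.

## Sequence space

Edit distances are computed at the *token* level — one move, one symbol —
so coordinate spelling never leaks into the distance. Three methods:
Levenshtein (`lv`, the default and a true metric), optimal string
alignment (`osa`, adjacent transpositions without reuse; may violate the
triangle inequality), and full Damerau–Levenshtein (`dl`,
Lowrance–Wagner). Sequences are canonicalized first and truncated to 50
moves by default. The all-pairs Levenshtein matrix uses a vectorized
row-DP (the same-row deletion minimum rewritten as a cumulative minimum
of `cur[k] − k`).

Classical (Torgerson) MDS double-centers −½d², eigendecomposes, and keeps
the top-k non-negative eigenvalues; negative eigenvalues (non-Euclidean
input) are truncated to zero and counted in the output. Axis signs are
fixed by making each column's largest-magnitude loading positive, so
embeddings are deterministic. On distances that are exactly Euclidean the
embedding reproduces them to 1e−9. Era occupancy attaches to each era the
cumulative point set of all earlier eras (the "explored so far"
background). Large corpora are embedded on a seeded subsample (pipeline
default 300 games; the CLI default is 6,000).

## Opening trees

Prefix trees count, at every node, the games whose opening passes through
it; games shorter than the depth limit terminate where they end, and the
invariant `count = Σ children + terminals` is asserted after building and
after pruning. The pruning rule keeps, at each node, the ⌈exp(H′)⌉ most
common children — H′ the natural-log Shannon entropy of the child
frequencies — so uniform nodes keep everything and dominated nodes keep a
couple of branches. Equal-count ties are broken lexicographically by
label; a floating-point guard (−1e−12 before the ceiling) keeps the
uniform case at exactly m. Distinct move orders reaching the same board
state are *not* merged in the tree; they are reported separately as a
transposition table keyed by the (Black set, White set) position.

## Match networks

Nodes are players, edge weights count games between a pair; games missing
a player id are skipped and counted. Average path length is over
unweighted hops on the main component (largest; ties to the component
containing the smallest node id); average transitivity is the mean local
clustering coefficient over all nodes with degree-<2 nodes contributing
zero. Communities come from weight-aware greedy modularity maximization
(Clauset–Newman–Moore, via networkx) on the main component only;
community ids are ordered by (size, smallest member) for determinism. The
per-period summary joins network statistics with the period's ¹D for the
diversity-versus-population analysis.

## Tempo of evolution

For consecutive years, Δpᵢ(t) = pᵢ(t) − pᵢ(t−1) over the union of
variants observed in either year, computed separately for depth-1 and
depth-2 variants and pooled into one vector; the year's raw tempo is the
population SD of that vector. Years following a gap are compared against
the most recent prior year and flagged. An alternative, haldane-like mode
standardizes |Δpᵢ| by each variant's historical change SD. The pipeline
skips years with fewer than 30 games (configurable): with a handful of
games a year, Δp is dominated by sampling noise, which is also why the
annual series conventionally starts at 1945.

The smoother is direct Gaussian-process regression with a squared-
exponential kernel plus observation noise. Hyperparameters (amplitude,
length-scale, noise SD) are fitted by maximizing the log marginal
likelihood (multi-start L-BFGS on log-parameters, deterministic starts at
span/20, span/5, span/2). The band is the central 89% interval of the
Gaussian posterior for the latent function — a Gaussian approximation to
an HPDI, exact here because the posterior is Gaussian. A constant series
short-circuits to itself with a zero band; a 1e−10 jitter stabilizes the
Cholesky factorization.

## Synthetic corpus

The generator emulates the structure of the professional archives the
pipeline targets, with every planted quantity recorded as ground truth:

- **Eras and growth.** Six eras with game counts growing roughly
  exponentially (defaults 3%/9%/12%/16%/27.5%/32.5% of the corpus),
  player pools growing from 60 to 1,500, years uniform within an era.
- **Openings.** A fixed pool of 24 real two-move opening labels (4-4,
  3-4 and 3-3 first moves with standard responses), stored in canonical
  form so planted labels equal pipeline labels exactly. Each era draws 12
  variants from a rotated window into the pool with Zipf weights; the
  window offsets create moderate turnover between eras and a large
  support shift at 2016, and era-specific Zipf exponents (1.6 down to
  0.85 and back up) plant a diversity trajectory. The planted
  step-change year is defined as the era boundary with maximal JSD
  between planted distributions — 2016 under the defaults.
- **Continuations.** Beyond move 2, games extend to depth 12 by a
  per-prefix branching process (3 cached candidate children with
  geometric weights), giving the trees and the edit-distance geometry
  realistic shared structure without claiming realistic play.
- **Communities.** Players partition into contiguous planted communities;
  a game stays within a community with probability 0.9 by default
  (0.95 in the planted-partition benchmark).
- **Blemishes.** Exactly round(fraction × N) games get handicap stones
  (4%), missing dates (0.6%), and AI flags (5% of post-2016 games) —
  rates shaped like a real archive's; each game's single-reason removal
  attribution is recorded.
- **Scrambling.** Every game is transformed by a uniformly random D4
  element, so canonicalization is load-bearing, not decorative.

What the generator does **not** emulate: legal-move constraints, captures
and ko, realistic continuation theory, win/loss dynamics, nationality-
dependent behaviour, or within-era drift. Passing recovery tests
therefore demonstrates that the estimators recover planted structure of
this kind at these sample sizes — not that the pipeline's scientific
conclusions transfer to any particular real archive.

## Pipeline determinism and problem sizes

Every stage derives its sub-seed as SHA-256(seed:stage) mod 2³¹, so
stages are independently re-runnable and the whole run is reproducible;
the manifest records a SHA-256 per artifact and identical configurations
produce identical hashes. Default end-to-end problem sizes: 20,000
generated games, 100×100 bootstrap per bin, a 300-game seeded subsample
for the MDS map, depth-7 trees, per-era networks — a configuration chosen
so a full run completes in well under a minute on one CPU while leaving
every estimator comfortably inside its tolerance.

## Known limitations

- Single-reason removal attribution is a convention; archives with
  overlapping defects can report different marginal counts under a
  different priority order.
- The canonical-form tie-break (lexicographic by `(col, row)`) is one of
  several defensible conventions; it can prefer e.g. a `Q17` rendering of
  a 3-4 opening over the `R16` a human annotator might write. All
  downstream statistics are invariant to this choice.
- OSA distances are not metric; only `lv` is used where metric behaviour
  matters.
- The GP band is a posterior interval under fitted point hyperparameters;
  it does not propagate hyperparameter uncertainty.
- Community detection by greedy modularity inherits that family's
  resolution limits; counts on very sparse period networks (few games per
  player) over-split, which the recovery report makes visible rather than
  hiding.
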