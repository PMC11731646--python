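# Methods

## Problem and unit of analysis

Facilitated communication (FC) produces dialogue transcripts in which a
user with a developmental disability types with physical support from a
facilitator, whose prompts appear in caps lock. The contested question is
whether such text carries any stylistic signature of the user, or only of
the facilitator. `costylo` operationalizes that question stylometrically:
the unit of analysis is the *pairing text* — the user-side lines of all
sessions of one user–facilitator pairing, concatenated chronologically —
and every statistic below asks whether pairing texts that share a user are
systematically closer in style than the facilitator-only hypothesis
allows.

## Feature model

Texts are cast as bag-of-feature vectors: relative frequencies of the
corpus's top-k most frequent words (MFW) or character n-grams (trigrams
by default; the n-gram window slides over the token stream re-joined with
single spaces, spaces included). Default k is 1,000 for single-table
analyses; consensus networks sweep k from 100 to 5,000 in steps of 100.
Each feature column is z-scored across samples using the population
standard deviation; exactly constant columns are dropped and reported.

Tokenization is Unicode-letter based, lowercased, with digits and
punctuation discarded. The default "elision" dialect keeps an apostrophe
glued to the preceding elided form (`l'anima` → `l'`, `anima`), the usual
convention for Italian stylometry; a "plain" dialect treating the
apostrophe as a bare boundary is available because the convention is not
universal and token totals shift slightly between the two. Accents are
preserved, so `sì` and `si` remain distinct types.

## Distances and clustering

Two delta metrics over z-score rows `z_a`, `z_b`:

* **cosine delta** (default): `d(a,b) = 1 − (z_a·z_b)/(‖z_a‖‖z_b‖)`,
  range [0, 2], invariant to positive scaling of a row;
* **Burrows (classical) delta**: mean absolute z-score difference, kept
  as an independent cross-check.

Hierarchical clustering is agglomerative over the precomputed distance
table (SciPy), default Ward linkage applied to the delta distances, with
`complete` and `average` available for sensitivity checks — the linkage
used in the original analyses is not recorded, so it is configuration,
not a fixed constant. The **leaf-pairing rate** is the fraction of
samples whose first merge partner is another leaf belonging to the same
user; a sample first absorbed into a multi-leaf cluster has no sibling
and counts against the rate. This is a deliberately strict formalization
of "paired together at the leaves".

## Red-line rank analysis

For each text, all other texts are ranked by ascending distance, ties
broken by label order. If the text's facilitator assisted `n` texts, the
red line is `r = n − 1`: under the facilitator-only hypothesis the first
`r` positions should hold exactly the other same-facilitator texts. A
*breach* is a same-user text (same user, different facilitator) at rank
≤ r. Corpus totals count breaches, top-3/5/10 same-user placements, and
— per column and per other facilitator the focal user wrote with —
whether the user's own text ranks first among that facilitator's texts.

The null model formalizes "ranks randomly" as exchangeability: a
column's breach count is then hypergeometric (`m` same-user among `M`
non-focal texts, `r` drawn), giving closed-form expectation `m·r/M` and
variance `m(r/M)(1−r/M)(M−m)/(M−1)`; totals sum over columns, and a
Monte-Carlo permutation sampler provides interval estimates for the
total. Two calibration facts matter when interpreting results:

* a *style-free* corpus (no author signal at all, σ = 0 below) satisfies
  exchangeability, and its breach totals land in the central 95%
  permutation interval at the nominal rate — this is the check that the
  null machinery is correct;
* a *facilitator-only* corpus (λ = 0 with distinct facilitator styles)
  is **not** exchangeable: same-facilitator texts deterministically fill
  the top ranks, pushing breach totals to ≈ 0, below the interval. The
  permutation null is therefore conservative for detecting user signal —
  facilitator style alone cannot inflate the breach count.

## Relationship groups and their statistics

Every ordered pair of texts gets exactly one label: IU (same user), FU
(same facilitator + similar users), F (same facilitator), RU (similar
users), NR (neither). Similarity comes from a curated map of up to two
stylistically similar users per user; the map is directional, and group
assignment follows the focal text's direction by default. The
symmetrized variant (`mutual=True`) is available, but the directional
rule is the default because it is the reading under which the reference
design's published group counts are reproduced exactly (a symmetric rule
over ordered pairs can only produce even counts, and the published FU
and RU counts are odd). Ordered-pair counting (each unordered pair
contributes twice) is used throughout because the published counts sum
to N(N−1).

Statistics per group: count, mean, sample SD; a two-sided one-sample
t-test against μ = 1 (the neutral midpoint of the cosine-delta range)
and against the corpus grand mean; an iterated equal-size subsample
two-sample t-test (both groups subsampled without replacement to the
smaller size, unpaired t-test, mean p over 10 repetitions) to compare
groups of very different sizes; and a stratified 5-fold cross-validated
classification (weighted KNN and RBF SVM) of the scalar distance values
into the five groups. The classifier feature is deliberately the scalar
distance alone — the only quantity attached to each observation — so the
accuracy measures separability of the groups' distance distributions,
nothing more. No multiple-testing correction is applied.

## Bootstrap consensus network

For each sweep size k the full distance analysis is repeated and every
text contributes weight `w_j = k_nn + 1 − j` to the undirected edge with
its j-th nearest neighbour (defaults `k_nn = 3`, weights 3/2/1). Edge
weights accumulate across the sweep, and total edge weight equals
`runs × nodes × Σ w_j` exactly — an invariant checked on every run.
These defaults were chosen because, for the reference corpus's published
link/weight table, the total printed weight equals twice
`50 runs × 28 nodes × 6` (the per-node counting convention) to within a
unit, pinning down the edge rule the original analysis most plausibly
used. Link tables, category summaries (same-user / same-facilitator /
neither, same-user precedence) and theoretical link maxima all use the
per-node (directed) counting convention, so an undirected edge appears
once from each endpoint and category shares sum to 100%.

## Synthetic corpus generator

The generator is the ground truth for every stage. A shared Zipfian
lexicon (`p_i ∝ i^(−s)`, default V = 10,000, s = 1) is perturbed per
author by multiplicative log-normal noise (`p_i · exp(σ ε_i)`,
renormalized; default σ = 0.4, a perturbation strong enough that two
authors' 1,000-MFW profiles are clearly distinct at 20,000 words while
keeping realistic rank-frequency structure). A pairing text of length L
(default 20,000 words, matching the >5,000-word inclusion rule with
headroom for quartering) draws each token from the user's profile with
probability λ and from the facilitator's otherwise, recording per-token
sources. λ = 0 realizes the facilitator-only null; λ = 1 a pure user
voice. Two ready-made designs emulate the study settings: a
single-facilitator center (7 users × 1 facilitator) and a
multi-facilitator center (10 users × 7 facilitators, 28 unbalanced
pairings, one facilitator assisting every user). Corpora can be rendered
as caps-lock dialogue session files (facilitator prompts uppercased,
interleaved) whose parse round-trips to the exact user token stream, so
transcript parsing is exercised against known truth.

What the generator does **not** emulate: topic structure, syntax, word
order, session-to-session drift, orthographic idiosyncrasies, or length
imbalance between pairings (available via per-pair word budgets but not
defaulted). Passing tests therefore show that the pipeline recovers a
planted *unigram* mixture signal and stays calibrated under its null;
they do not show that real FC corpora contain such a signal, nor rule
out topic confounds in real data.

## Numerical choices and degenerate inputs

* Distance ties and nearest-neighbour ties break by label order;
  rankings are fully deterministic.
* Quarter-split remainders go to the earliest quarters, so the two
  chunks of a text differ by at most 3 tokens.
* The minimum-length filter is strict (`> 5,000` words); chunked
  analyses additionally drop users whose chunks fall at or below the
  threshold.
* Caps-lock detection uses a threshold (default 0.8) on the uppercase
  fraction of alphabetic characters, tolerating punctuation and stray
  accents; lines without letters follow the user.
* Zero-variance features are dropped before z-scoring (exact-constancy
  test, since floating-point SD of a constant column is ~1e−17, not 0);
  all-zero z-rows and empty documents raise explicit errors.
* Feature ties at the top-k boundary break lexicographically, making
  feature sets deterministic given the corpus.
* All randomness flows from one master seed through spawned generators,
  one per pairing, so individual texts are reproducible independently of
  design size.

## Problem sizes used in the test and acceptance runs

Synthetic checks use the defaults above (V = 10⁴, L = 2×10⁴) for the
calibration and signal-recovery suites (50 and 20 seeds respectively);
the λ-monotonicity trend uses a lighter grid (V = 5,000, L = 6,000,
20 seeds per λ), which is ample for a mean-trend comparison across five
λ values. The acceptance script runs the same stack at the default sizes
with a reduced seed count per quantity (5–20), chosen so a full
recomputation stays in the low tens of seconds.

## Known limitations

* The tokenizer is a reconstruction; printed token/type totals of the
  original corpora may shift by a small margin under any dialect.
* Linkage, BCN edge rule, and classifier feature representation are
  unreported in the source analyses; defaults are the package's best
  supported reconstruction and are all configurable.
* The unigram generator cannot probe character-trigram-specific effects
  beyond what word choice induces.
* Real-corpus replication (the Zenodo deposit) is supported by the I/O
  layer but is not part of the automated checks.
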