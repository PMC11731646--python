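# costylo

Stylometric co-authorship analysis for facilitated-communication (FC)
dialogue corpora — and for anyone who needs to ask whether two candidate
authors both leave detectable fingerprints in jointly produced text.

In FC, a user with a developmental disability types while a facilitator
provides physical support; session transcripts interleave the user's
lines with the facilitator's caps-locked prompts. The long-standing
dispute is whether such text is authored solely by the facilitator.
`costylo` implements the quantitative side of that question as a tested,
reusable pipeline: from raw session files to most-frequent-feature
profiles, delta distance tables, cluster dendrograms, facilitator
"red-line" rank statistics, pair-relationship group tests, and bootstrap
consensus networks — plus a synthetic mixture-corpus generator so every
stage can be validated against known ground truth without any sensitive
data.

## The model in brief

Each text becomes a vector of relative frequencies over the corpus's
top-k most frequent words or character trigrams, z-scored per feature.
Stylistic distance is **cosine delta**,

    d(a, b) = 1 − (z_a · z_b) / (‖z_a‖ ‖z_b‖)  ∈ [0, 2],

with classical Burrows delta (mean |Δz|) as a cross-check. If a text's
facilitator assisted *n* texts, the first *n* − 1 rank positions of its
neighbour list should — under the facilitator-only hypothesis — hold
exactly the other same-facilitator texts. A same-user text appearing
above that **red line** is a breach: evidence of a user-borne signature.
Breach totals are compared against a closed-form/hypergeometric random-
ranking null. Pairs of texts are further grouped by relationship (same
user IU, same facilitator F/FU, stylistically similar users RU, neither
NR) for distance statistics and tests, and a bootstrap consensus network
accumulates nearest-neighbour links across feature-vector sizes from 100
to 5,000.

The synthetic generator models each author as a perturbed Zipfian
unigram distribution; a pairing text draws each token from the user's
profile with probability λ and from the facilitator's otherwise, so
λ = 0 realizes the facilitator-only null and the whole pipeline can be
tested for both calibration and signal recovery. See
[docs/methods.md](docs/methods.md) for assumptions, parameter choices
and limitations.

## Worked example

Generate a synthetic multi-facilitator corpus (10 users, 7 facilitators,
28 pairings, 20,000 words each, even user/facilitator mix λ = 0.5) and
run the full multi-facilitator workflow:

```python
from costylo.synthetic import center2_config, generate_corpus
from costylo.pipeline import RunConfig, run_study2

corpus = generate_corpus(center2_config(lam=0.5, seed=7))
config = RunConfig(output_dir="out", mfw=1000, seed=7)
report = run_study2(config, pairs=corpus.pairs, metadata=corpus.metadata)
print(report["red_line"])
print(report["null_total_expected_breaches"])
```

which prints

```
{'breaches': 33, 'top3': 31, 'top5': 48, 'top10': 60,
 'first_among_facilitator': 60, 'second_among_facilitator': 60,
 'denominator': 60}
10.222222222222221
```

Reading: of the 60 same-user rank observations, 33 breach the red line
against a random-ranking expectation of 10.2 — the planted user signal
is clearly detected — and in all 60 cases a user's text ranks first
among the texts of each other facilitator that user wrote with. The
report also contains the group statistics (here IU mean distance 0.90 vs
NR 1.08), the iterated subsample tests, distance-classification
accuracies, and the consensus-network summary (same-user links carry 44%
of total link weight at λ = 0.5); `out/` holds the distance tables,
rank tables, newick dendrogram, GraphML network and a JSON report.

The same workflows are available from the shell:

```bash
costylo simulate corpus/ --design center1 --lam 0.6 --seed 1
costylo study1 --input-dir corpus/ --output-dir out/
```

For a real corpus, point `study2` at a directory of UTF-8 session files
(one folder per user, facilitator code in the file name, facilitator
lines in caps lock). The curated inter-user similarity map of the
deposited reference corpus (Zenodo, DOI 10.5281/zenodo.7273147) is built
in (`--reference-similarity`); otherwise the map is derived from the
distance table itself.

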