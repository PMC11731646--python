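"""Tokenization, lexical statistics, and most-frequent-feature matrices.

The bag-of-words model underlying delta-style authorship analysis: every
text becomes a vector of relative frequencies over the corpus's top-k most
frequent words (MFW) or character n-grams, which are then standardized
per feature (z-scored) so that each feature contributes on a comparable
scale to the distance computation.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "LexicalStats",
    "tokenize",
    "lexical_stats",
    "extract_features",
    "zscore",
]

# Word = run of Unicode letters, optionally ending in an elision apostrophe
# so Italian elided articles survive as their own tokens (l'anima -> l', anima).
_WORD_ELISION = re.compile(r"[^\W\d_]+['’]?")
# Plain dialect: the apostrophe is a bare boundary (l'anima -> l, anima).
_WORD_PLAIN = re.compile(r"[^\W\d_]+")


def tokenize(text: str, dialect: Literal["elision", "plain"] = "elision") -> list[str]:
    """Lowercase word tokenization; digits and punctuation are discarded.

    ``elision`` (default) keeps an apostrophe glued to the preceding elided
    form, the common convention for Italian stylometry; ``plain`` treats the
    apostrophe as an ordinary boundary.  Accented letters are preserved
    (``sì`` and ``si`` remain distinct types).
    """
    pattern = _WORD_ELISION if dialect == "elision" else _WORD_PLAIN
    out = pattern.findall(text.lower())
    # normalize typographic apostrophes so both forms count as one type
    return [t.replace("’", "'") for t in out]


@dataclass(frozen=True)
class FeatureSpec:
    """What to count: word forms or character n-grams, and how many features.

    ``k`` is the number of top features by whole-corpus frequency (1,000 for
    the single-table analyses; swept 100..5,000 for consensus networks).
    ``n`` is the n-gram length and is ignored in word mode.
    """

    mode: Literal["word", "char_ngram"] = "word"
    n: int = 3
    k: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode == "char_ngram" and self.n < 1:
            raise ValueError("n must be >= 1")

    def describe(self) -> str:
        if self.mode == "word":
            return f"{self.k}-MFW"
        return f"{self.k}-MF{self.n}gram"


@dataclass
class LexicalStats:
    """Token/type/hapax accounting for one token stream."""

    tokens: int
    types: int
    hapax: int
    type_token_ratio: float | None

    def to_dict(self) -> dict:
        return {
            "tokens": self.tokens,
            "types": self.types,
            "hapax": self.hapax,
            "type_token_ratio": self.type_token_ratio,
        }


def lexical_stats(tokens: Sequence[str]) -> LexicalStats:
    """Count tokens, types, and hapax legomena (types occurring once)."""
    counts = Counter(tokens)
    n = len(tokens)
    return LexicalStats(
        tokens=n,
        types=len(counts),
        hapax=sum(1 for c in counts.values() if c == 1),
        type_token_ratio=(len(counts) / n) if n else None,
    )


def _as_tokens(sample: str | Sequence[str]) -> list[str]:
    if isinstance(sample, str):
        return tokenize(sample)
    return list(sample)


def _char_ngrams(tokens: Sequence[str], n: int) -> Iterable[str]:
    stream = " ".join(tokens)
    return (stream[i : i + n] for i in range(len(stream) - n + 1))


def extract_features(
    samples: Mapping[str, str | Sequence[str]], spec: FeatureSpec
) -> pd.DataFrame:
    """Relative-frequency matrix over the corpus's top-k features.

    ``samples`` maps sample label to raw text or a pre-tokenized list.
    Features are ranked by total count over the whole corpus, ties broken
    lexicographically, and each cell is the feature's count in that sample
    divided by the sample's token (or n-gram) total.  Rows are samples in
    input order, columns features in rank order.

    In ``char_ngram`` mode the n-gram window slides over the token stream
    re-joined with single spaces, spaces included as characters.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    per_sample: dict[str, Counter] = {}
    totals: dict[str, int] = {}
    corpus: Counter = Counter()
    for label, sample in samples.items():
        tokens = _as_tokens(sample)
        units = tokens if spec.mode == "word" else _char_ngrams(tokens, spec.n)
        c = Counter(units)
        per_sample[label] = c
        totals[label] = sum(c.values())
        corpus.update(c)

    ranked = sorted(corpus.items(), key=lambda kv: (-kv[1], kv[0]))
    if spec.k > len(ranked):
        warnings.warn(
            f"requested k={spec.k} but only {len(ranked)} distinct features exist; "
            "truncating",
            stacklevel=2,
        )
    feats = [f for f, _ in ranked[: spec.k]]

    data = np.zeros((len(per_sample), len(feats)))
    for i, (label, c) in enumerate(per_sample.items()):
        tot = totals[label]
        if tot == 0:
            raise ValueError(f"sample {label!r} has no countable units")
        data[i] = [c.get(f, 0) / tot for f in feats]
    return pd.DataFrame(data, index=list(per_sample), columns=feats)


def zscore(freq: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each feature column across samples (population SD).

    Zero-variance features cannot be standardized; they are dropped and
    returned in the second element so callers can log them.
    """
    if len(freq) < 2:
        raise ValueError("cannot standardize fewer than 2 samples")
    mean = freq.mean(axis=0)
    sd = freq.std(axis=0, ddof=0)
    # a constant column's computed sd can be ~1e-17, not exactly 0
    keep = (freq.nunique(axis=0) > 1) & (sd > 0)
    dropped = list(freq.columns[~keep])
    z = (freq.loc[:, keep] - mean[keep]) / sd[keep]
    return z, dropped
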