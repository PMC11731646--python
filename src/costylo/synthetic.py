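"""Synthetic dialogue corpora with known user/facilitator style mixing.

The generator formalizes the "stylistic fingerprint" the analyses
presuppose as a unigram distribution per author: a shared Zipfian base
lexicon, perturbed per author by multiplicative log-normal noise of scale
``sigma``.  A user--facilitator pairing text draws each token from the
user's profile with probability ``lambda`` and from the facilitator's
otherwise, so ``lambda = 0`` realizes the facilitator-only null
hypothesis and ``lambda = 1`` a pure user voice, with per-token source
labels kept as ground truth.

Corpora can be rendered to the caps-lock dialogue session format the
parser consumes, so the whole pipeline — including transcript parsing —
is exercised against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np

from .corpus import PairText
from .designs import (
    CENTER1_FACILITATOR,
    CENTER1_USERS,
    CENTER2_DESIGN,
    design_to_metadata,
)

__all__ = [
    "StyleProfile",
    "SynthConfig",
    "SyntheticCorpus",
    "make_profiles",
    "generate_pair_text",
    "render_sessions",
    "generate_corpus",
    "write_corpus",
    "center1_config",
    "center2_config",
]


def word_form(i: int) -> str:
    """Letter-only surface form for vocabulary index ``i`` (bijective base-26).

    Pure lowercase a–z so forms survive the tokenizer unchanged.
    """
    i += 1
    chars = []
    while i > 0:
        i, rem = divmod(i - 1, 26)
        chars.append(chr(ord("a") + rem))
    return "".join(reversed(chars))


@lru_cache(maxsize=8)
def _vocab_forms(size: int) -> np.ndarray:
    """Vectorized surface-form lookup table for a vocabulary size."""
    return np.array([word_form(i) for i in range(size)], dtype=object)


@dataclass
class StyleProfile:
    """An author's unigram distribution over the shared vocabulary."""

    author_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        total = float(np.sum(self.probs))
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"profile {self.author_id}: probabilities sum to {total}")


@dataclass(frozen=True)
class SynthConfig:
    """Generative settings for one synthetic corpus.

    Defaults mirror the study conditions the pipeline is validated
    against: a 10,000-word Zipfian lexicon (exponent 1), author
    perturbation ``sigma = 0.4``, 20,000 words per pairing, and an even
    user/facilitator mix (``lam = 0.5``).
    """

    design: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CENTER2_DESIGN)
    )
    vocab_size: int = 10_000
    zipf_s: float = 1.0
    sigma: float = 0.4
    lam: float = 0.5
    words_per_pair: int = 20_000
    #: optional per-pair word budgets, label ("U8_F1") -> words
    word_budgets: Mapping[str, int] | None = None
    sessions_per_pair: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.vocab_size < 2 or self.words_per_pair < 1:
            raise ValueError("vocab_size >= 2 and words_per_pair >= 1 required")
        if not self.design:
            raise ValueError("design matrix must be non-empty")

    @property
    def users(self) -> tuple[str, ...]:
        return tuple(sorted({u for us in self.design.values() for u in us}))

    @property
    def facilitators(self) -> tuple[str, ...]:
        return tuple(sorted(self.design))

    def metadata(self) -> dict[str, tuple[str, str]]:
        return design_to_metadata(self.design)


def make_profiles(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, StyleProfile]]:
    """Zipfian base distribution plus one perturbed profile per author.

    Base ``p_i ∝ (i + 1)^(-s)``; each author's profile is
    ``p_i * exp(sigma * eps_i)`` with standard-normal ``eps_i``,
    renormalized.  ``sigma = 0`` collapses every profile onto the base.
    Authors are processed in sorted order (users then facilitators) so the
    draw is reproducible.
    """
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    base = ranks ** (-config.zipf_s)
    base /= base.sum()
    profiles = {}
    for author in list(config.users) + list(config.facilitators):
        eps = rng.standard_normal(config.vocab_size)
        p = base * np.exp(config.sigma * eps)
        p /= p.sum()
        profiles[author] = StyleProfile(author_id=author, probs=p)
    return base, profiles


def generate_pair_text(
    user_profile: StyleProfile,
    facilitator_profile: StyleProfile,
    lam: float,
    length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Token indices and per-token source labels for one pairing text.

    Each token is drawn from the user's profile with probability ``lam``
    and the facilitator's otherwise.  Returns ``(indices, from_user)``
    where ``from_user`` is a boolean ground-truth array.
    """
    from_user = rng.random(length) < lam
    V = len(user_profile.probs)
    idx = np.where(
        from_user,
        rng.choice(V, size=length, p=user_profile.probs),
        rng.choice(V, size=length, p=facilitator_profile.probs),
    )
    return idx, from_user


@dataclass
class SyntheticCorpus:
    """A generated corpus plus its ground truth."""

    config: SynthConfig
    pairs: list[PairText]
    metadata: dict[str, tuple[str, str]]
    #: label -> boolean array, True where the token came from the user
    sources: dict[str, np.ndarray]
    profiles: dict[str, StyleProfile]
    base: np.ndarray

    def samples(self) -> dict[str, str]:
        return {p.label: p.text for p in self.pairs}

    def user_fraction(self, label: str) -> float:
        src = self.sources[label]
        return float(np.mean(src))


def generate_corpus(config: SynthConfig) -> SyntheticCorpus:
    """Generate all pairing texts for a design under one master seed.

    Every pairing draws from its own generator spawned off the master
    seed, so individual texts are reproducible independently of how many
    pairings the design contains.
    """
    ss = np.random.SeedSequence(config.seed)
    profile_rng = np.random.default_rng(ss.spawn(1)[0])
    base, profiles = make_profiles(config, profile_rng)
    metadata = config.metadata()
    budgets = dict(config.word_budgets or {})
    pair_seeds = ss.spawn(len(metadata))
    pairs, sources = [], {}
    for (label, (user, fac)), child in zip(metadata.items(), pair_seeds):
        rng = np.random.default_rng(child)
        length = budgets.get(label, config.words_per_pair)
        idx, from_user = generate_pair_text(
            profiles[user], profiles[fac], config.lam, length, rng
        )
        tokens = _vocab_forms(config.vocab_size)[idx]
        pairs.append(
            PairText(
                user_id=user,
                facilitator_id=fac,
                text=" ".join(tokens),
                word_count=len(tokens),
                n_sessions=config.sessions_per_pair,
            )
        )
        sources[label] = from_user
    return SyntheticCorpus(
        config=config,
        pairs=pairs,
        metadata=metadata,
        sources=sources,
        profiles=profiles,
        base=base,
    )


def render_sessions(
    pair: PairText,
    sessions_per_pair: int,
    facilitator_profile: StyleProfile,
    rng: np.random.Generator,
    tokens_per_line: int = 10,
    prompt_every: int = 3,
    prompt_length: int = 5,
) -> list[str]:
    """Render a pairing text as caps-lock dialogue session files.

    The user's tokens are split into ``sessions_per_pair`` contiguous
    blocks and wrapped at ``tokens_per_line``; facilitator prompt lines
    (sampled from the facilitator's profile, uppercased) are interleaved
    every ``prompt_every`` user lines.  Parsing a rendered session with
    the dialogue splitter recovers the user token stream exactly.

    Returns one file-content string per session.
    """
    tokens = pair.text.split()
    blocks = np.array_split(np.array(tokens, dtype=object), sessions_per_pair)
    V = len(facilitator_profile.probs)
    out = []
    for block in blocks:
        lines = []
        for i in range(0, len(block), tokens_per_line):
            if prompt_every and (i // tokens_per_line) % prompt_every == 0:
                prompt_idx = rng.choice(V, size=prompt_length, p=facilitator_profile.probs)
                lines.append(" ".join(word_form(j) for j in prompt_idx).upper())
            lines.append(" ".join(block[i : i + tokens_per_line]))
        out.append("\n".join(lines) + "\n")
    return out


def write_corpus(corpus: SyntheticCorpus, root: str | Path) -> Path:
    """Write session files in the layout the corpus reader consumes.

    ``<root>/<user>/<NNN>_<facilitator>.txt`` plus ``manifest.json``
    recording the seed, mixing weight, and per-pair source counts.
    Returns the manifest path.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence((corpus.config.seed, 1))
    rng = np.random.default_rng(ss)
    manifest: dict = {
        "seed": corpus.config.seed,
        "lam": corpus.config.lam,
        "sigma": corpus.config.sigma,
        "vocab_size": corpus.config.vocab_size,
        "zipf_s": corpus.config.zipf_s,
        "sessions": [],
        "pairs": {},
    }
    counter: dict[str, int] = {}
    for pair in corpus.pairs:
        userdir = root / pair.user_id
        userdir.mkdir(exist_ok=True)
        files = render_sessions(
            pair,
            corpus.config.sessions_per_pair,
            corpus.profiles[pair.facilitator_id],
            rng,
        )
        for content in files:
            counter[pair.user_id] = counter.get(pair.user_id, 0) + 1
            name = f"{counter[pair.user_id]:03d}_{pair.facilitator_id}.txt"
            (userdir / name).write_text(content, encoding="utf-8")
            manifest["sessions"].append(
                {
                    "session_id": f"{pair.user_id}/{name}",
                    "user_id": pair.user_id,
                    "facilitator_id": pair.facilitator_id,
                }
            )
        manifest["pairs"][pair.label] = {
            "word_count": pair.word_count,
            "user_source_tokens": int(np.sum(corpus.sources[pair.label])),
        }
    path = root / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return path


def center1_config(**overrides) -> SynthConfig:
    """Design emulating the single-facilitator center (7 users x 1 facilitator)."""
    design = {CENTER1_FACILITATOR: CENTER1_USERS}
    return replace(SynthConfig(design=design), **overrides)


def center2_config(**overrides) -> SynthConfig:
    """Design emulating the multi-facilitator center (10 users x 7 facilitators,
    28 unbalanced pairings, F1 assisting every user)."""
    return replace(SynthConfig(design=dict(CENTER2_DESIGN)), **overrides)
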