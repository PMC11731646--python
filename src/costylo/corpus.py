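"""Session-transcript parsing and per-pairing corpus assembly.

Facilitated-communication (FC) sessions are stored as one UTF-8 text file
per session, in dialogue form: the user's typed lines in ordinary case and
the facilitator's prompts highlighted in caps lock.  This module separates
the two voices, concatenates each user--facilitator pairing into a single
text (the unit of every downstream analysis), applies the minimum-length
filter, and produces the four-fragment chunk recombinations used to compare
a user's text against itself.

Expected directory layout: one folder per user, one ``.txt`` file per
session inside it, with the facilitator code embedded in the file name
(``U1/003_F2.txt``).  Chronological order is lexicographic file-name order
unless a manifest overrides it.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .features import tokenize

__all__ = [
    "SessionDocument",
    "PairText",
    "ChunkPair",
    "EmptyDocumentError",
    "MalformedMetadataError",
    "split_dialogue",
    "strip_names",
    "assemble_pairs",
    "filter_min_words",
    "chunk_four_way",
    "chunk_all",
    "read_corpus",
    "write_pairs",
]

Scheme = Literal["A", "B", "C"]

#: Which fragment indices (0-based) form the two chunks under each scheme.
SCHEME_FRAGMENTS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "A": ((0, 1), (2, 3)),
    "B": ((0, 2), (1, 3)),
    "C": ((0, 3), (1, 2)),
}


class EmptyDocumentError(ValueError):
    """Raised for a session file with no non-empty lines."""


class MalformedMetadataError(ValueError):
    """Raised when session metadata is inconsistent or missing."""


@dataclass
class SessionDocument:
    """One FC session: an ordered dialogue between a user and a facilitator."""

    session_id: str
    user_id: str
    facilitator_id: str
    #: ordered (speaker, line) with speaker in {"user", "facilitator"}
    turns: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.user_id or not self.facilitator_id:
            raise MalformedMetadataError(
                f"session {self.session_id!r}: user_id and facilitator_id required"
            )
        for speaker, _ in self.turns:
            if speaker not in ("user", "facilitator"):
                raise MalformedMetadataError(
                    f"session {self.session_id!r}: bad speaker {speaker!r}"
                )

    def user_text(self) -> str:
        return "\n".join(line for spk, line in self.turns if spk == "user")

    def facilitator_text(self) -> str:
        return "\n".join(line for spk, line in self.turns if spk == "facilitator")


@dataclass
class PairText:
    """The user-side text of one user--facilitator pairing."""

    user_id: str
    facilitator_id: str
    text: str
    word_count: int = 0
    n_sessions: int = 1

    @property
    def label(self) -> str:
        return f"{self.user_id}_{self.facilitator_id}"


@dataclass
class ChunkPair:
    """Two near-equal halves of a pairing text under one recombination scheme."""

    user_id: str
    facilitator_id: str
    scheme: Scheme
    labels: tuple[str, str]
    texts: tuple[str, str]

    def chunk_labels(self) -> tuple[str, str]:
        """Full sample labels, e.g. ``("U1_1-2", "U1_3-4")``."""
        return tuple(f"{self.user_id}_{lab}" for lab in self.labels)  # type: ignore[return-value]


def _upper_fraction(line: str) -> float | None:
    """Fraction of alphabetic characters that are uppercase; None if no letters."""
    letters = [c for c in line if c.isalpha()]
    if not letters:
        return None
    return sum(1 for c in letters if c.isupper()) / len(letters)


def split_dialogue(
    raw_lines: Iterable[str], caps_threshold: float = 0.8
) -> tuple[str, str]:
    """Separate user lines from facilitator (caps-lock) lines.

    A line belongs to the facilitator iff the fraction of its alphabetic
    characters that are uppercase is at least ``caps_threshold``.  The
    threshold tolerates punctuation, digits and stray lowercase accents in
    otherwise caps-locked prompts.  Lines without letters follow the user.

    Returns ``(user_text, facilitator_text)`` with original line order
    preserved inside each voice.

    Raises
    ------
    EmptyDocumentError
        If no line has any non-whitespace content.
    """
    user_lines: list[str] = []
    fac_lines: list[str] = []
    seen = False
    for line in raw_lines:
        stripped = line.strip()
        if not stripped:
            continue
        seen = True
        frac = _upper_fraction(stripped)
        if frac is not None and frac >= caps_threshold:
            fac_lines.append(stripped)
        else:
            user_lines.append(stripped)
    if not seen:
        raise EmptyDocumentError("document contains no non-empty lines")
    return "\n".join(user_lines), "\n".join(fac_lines)


def strip_names(text: str, name_list: Sequence[str]) -> str:
    """Remove literal names (case-insensitive, whole-word) from ``text``."""
    out = text
    for name in name_list:
        if not name:
            continue
        pattern = re.compile(rf"(?<!\w){re.escape(name)}(?!\w)", re.IGNORECASE)
        out = pattern.sub(" ", out)
    return out


def assemble_pairs(sessions: Sequence[SessionDocument]) -> list[PairText]:
    """Concatenate sessions into one :class:`PairText` per (user, facilitator).

    Session order is preserved as given (callers sort chronologically before
    calling).  ``word_count`` is populated with the tokenizer's count.
    """
    order: list[tuple[str, str]] = []
    texts: dict[tuple[str, str], list[str]] = {}
    for s in sessions:
        key = (s.user_id, s.facilitator_id)
        if key not in texts:
            texts[key] = []
            order.append(key)
        ut = s.user_text()
        if ut:
            texts[key].append(ut)
    pairs = []
    for user, fac in order:
        text = "\n".join(texts[(user, fac)])
        pairs.append(
            PairText(
                user_id=user,
                facilitator_id=fac,
                text=text,
                word_count=len(tokenize(text)),
                n_sessions=len(texts[(user, fac)]),
            )
        )
    return pairs


def filter_min_words(
    pairs: Sequence[PairText], threshold: int = 5000
) -> tuple[list[PairText], list[str]]:
    """Keep pairings strictly longer than ``threshold`` words.

    Returns ``(kept, excluded_labels)``.  The boundary is exclusive: a text
    of exactly ``threshold`` words is dropped.
    """
    kept = [p for p in pairs if p.word_count > threshold]
    excluded = [p.label for p in pairs if p.word_count <= threshold]
    return kept, excluded


def _quarters(tokens: Sequence[str]) -> list[list[str]]:
    n = len(tokens)
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    out, pos = [], 0
    for size in sizes:
        out.append(list(tokens[pos : pos + size]))
        pos += size
    return out


def chunk_four_way(pair: PairText, scheme: Scheme) -> ChunkPair:
    """Split a pairing text into 4 consecutive quarters and recombine.

    Scheme ``A`` joins quarters (1,2) and (3,4); ``B`` joins (1,3) and
    (2,4); ``C`` joins (1,4) and (2,3).  Remainder tokens go to the earliest
    quarters, so the two chunks differ by at most 3 tokens.
    """
    if scheme not in SCHEME_FRAGMENTS:
        raise ValueError(f"unknown scheme {scheme!r}")
    tokens = tokenize(pair.text)
    if len(tokens) < 4:
        raise ValueError(
            f"pair {pair.label}: need at least 4 tokens to chunk, got {len(tokens)}"
        )
    quarters = _quarters(tokens)
    (i, j), (k, l) = SCHEME_FRAGMENTS[scheme]
    chunk1 = quarters[i] + quarters[j]
    chunk2 = quarters[k] + quarters[l]
    labels = (f"{i + 1}-{j + 1}", f"{k + 1}-{l + 1}")
    return ChunkPair(
        user_id=pair.user_id,
        facilitator_id=pair.facilitator_id,
        scheme=scheme,
        labels=labels,
        texts=(" ".join(chunk1), " ".join(chunk2)),
    )


def chunk_all(
    pairs: Sequence[PairText], scheme: Scheme, min_chunk_words: int = 5000
) -> tuple[dict[str, str], list[str]]:
    """Chunk every pairing; drop users whose chunks fall at/below the filter.

    Returns ``(samples, excluded_labels)`` where samples maps chunk label
    (``U1_1-2``) to chunk text.  A pairing is excluded when either of its
    chunks has ``<= min_chunk_words`` tokens, mirroring the rule that
    dropped too-short users from the chunked cluster analyses.
    """
    samples: dict[str, str] = {}
    excluded: list[str] = []
    for pair in pairs:
        cp = chunk_four_way(pair, scheme)
        lens = [len(tokenize(t)) for t in cp.texts]
        if min_chunk_words and min(lens) <= min_chunk_words:
            excluded.append(pair.label)
            continue
        for lab, text in zip(cp.chunk_labels(), cp.texts):
            samples[lab] = text
    return samples, excluded


# ---------------------------------------------------------------------------
# directory I/O

_FILENAME_RE = re.compile(r"(?P<order>.*?)_?(?P<fac>F\d+)\.txt$", re.IGNORECASE)


def _load_manifest(path: Path) -> list[dict[str, str]]:
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    required = {"session_id", "user_id", "facilitator_id"}
    for row in rows:
        if not required <= set(row):
            raise MalformedMetadataError(f"manifest row missing fields: {row}")
    return rows


def read_corpus(
    root: str | Path,
    manifest: str | Path | None = None,
    caps_threshold: float = 0.8,
    name_list: Sequence[str] = (),
) -> list[SessionDocument]:
    """Read a directory tree of session transcripts.

    Without a manifest, each sub-directory of ``root`` is a user, each
    ``.txt`` file inside it a session whose name carries the facilitator
    code (``<anything>_<F-code>.txt``); sessions are ordered by file name.
    A JSON/CSV manifest with columns ``session_id, user_id, facilitator_id``
    (and optional ``order``) overrides the convention; ``session_id`` is the
    path relative to ``root``.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"corpus directory not found: {root}")

    entries: list[tuple[str, str, str, Path]] = []  # (order_key, user, fac, path)
    if manifest is not None:
        for row in _load_manifest(Path(manifest)):
            path = root / row["session_id"]
            key = str(row.get("order", row["session_id"]))
            entries.append((key, row["user_id"], row["facilitator_id"], path))
    else:
        for userdir in sorted(p for p in root.iterdir() if p.is_dir()):
            for f in sorted(userdir.glob("*.txt")):
                m = _FILENAME_RE.match(f.name)
                if not m:
                    raise MalformedMetadataError(
                        f"cannot parse facilitator code from file name {f.name!r}"
                    )
                entries.append((f.name, userdir.name, m.group("fac").upper(), f))
    entries.sort(key=lambda e: (e[1], e[0]))

    sessions = []
    for _, user, fac, path in entries:
        raw = path.read_text(encoding="utf-8").splitlines()
        try:
            user_text, fac_text = split_dialogue(raw, caps_threshold)
        except EmptyDocumentError:
            continue
        if name_list:
            user_text = strip_names(user_text, name_list)
            fac_text = strip_names(fac_text, name_list)
        turns = [("user", ln) for ln in user_text.splitlines() if ln.strip()]
        turns += [("facilitator", ln) for ln in fac_text.splitlines() if ln.strip()]
        sessions.append(
            SessionDocument(
                session_id=str(path.relative_to(root)),
                user_id=user,
                facilitator_id=fac,
                turns=turns,
            )
        )
    return sessions


def write_pairs(pairs: Sequence[PairText], outdir: str | Path) -> Path:
    """Write one ``.txt`` per pairing plus a metadata CSV; returns the CSV path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in pairs:
        (outdir / f"{p.label}.txt").write_text(p.text, encoding="utf-8")
    meta = outdir / "pairs.csv"
    with open(meta, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["user_id", "facilitator_id", "word_count", "n_sessions"])
        for p in pairs:
            w.writerow([p.user_id, p.facilitator_id, p.word_count, p.n_sessions])
    return meta
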