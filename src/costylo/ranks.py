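"""Neighbour-rank analysis of a distance table and the facilitator red line.

For every text ("column") the remaining texts are sorted by ascending
stylistic distance.  If a text's facilitator assisted ``n`` texts in the
corpus, then under the hypothesis that the facilitator is the sole
stylistic source, only the ``n - 1`` other texts sharing that facilitator
should occupy the first ``n - 1`` rank positions — the "red line"
``r = n - 1``.  A same-user text (same user, different facilitator)
appearing at rank ``<= r`` *breaches* the line: evidence of a user-borne
stylistic signal.  The null model treats rankings as uniformly random
permutations, which makes per-column breach counts hypergeometric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import DistanceTable

__all__ = [
    "RankEntry",
    "RankColumn",
    "RedLineSummary",
    "build_rank_table",
    "red_line_summary",
    "null_expected_breaches",
    "permutation_null",
    "rank_table_wide",
    "rank_table_tidy",
]


@dataclass
class RankEntry:
    label: str
    rank: int
    distance: float
    same_user: bool
    same_facilitator: bool
    similar_user: bool


@dataclass
class RankColumn:
    """One text's neighbour ranking with its facilitator red line."""

    focal: str
    user: str
    facilitator: str
    red_line: int  # r = n - 1 where n = texts written with this facilitator
    entries: list[RankEntry]

    def breaches(self) -> list[RankEntry]:
        return [e for e in self.entries if e.same_user and e.rank <= self.red_line]

    def same_user_entries(self) -> list[RankEntry]:
        return [e for e in self.entries if e.same_user]


@dataclass
class RedLineSummary:
    """Corpus-wide totals over all same-user rank observations."""

    breaches: int
    top3: int
    top5: int
    top10: int
    first_among_facilitator: int
    second_among_facilitator: int
    denominator: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def build_rank_table(
    d: DistanceTable,
    metadata: Mapping[str, tuple[str, str]],
    simmap: Mapping[str, Sequence[str]] | None = None,
) -> list[RankColumn]:
    """One ranked column per text, with relationship flags populated.

    ``metadata`` maps every label to ``(user, facilitator)``; a missing
    label is a hard error.  Distance ties are broken by label order so the
    ranking is deterministic.  ``simmap`` (user -> similar users) feeds the
    ``similar_user`` flag; without it the flag is False everywhere.
    """
    missing = [lab for lab in d.labels if lab not in metadata]
    if missing:
        raise KeyError(f"labels without metadata: {missing}")
    simmap = simmap or {}
    fac_counts: dict[str, int] = {}
    for lab in d.labels:
        fac_counts[metadata[lab][1]] = fac_counts.get(metadata[lab][1], 0) + 1

    columns = []
    for focal in d.labels:
        fuser, ffac = metadata[focal]
        others = sorted(
            (lab for lab in d.labels if lab != focal),
            key=lambda lab: (float(d.frame.loc[focal, lab]), lab),
        )
        entries = []
        for rank, lab in enumerate(others, start=1):
            ouser, ofac = metadata[lab]
            entries.append(
                RankEntry(
                    label=lab,
                    rank=rank,
                    distance=float(d.frame.loc[focal, lab]),
                    same_user=ouser == fuser,
                    same_facilitator=ofac == ffac,
                    similar_user=ouser in simmap.get(fuser, ())
                    or fuser in simmap.get(ouser, ()),
                )
            )
        columns.append(
            RankColumn(
                focal=focal,
                user=fuser,
                facilitator=ffac,
                red_line=fac_counts[ffac] - 1,
                entries=entries,
            )
        )
    return columns


def red_line_summary(
    columns: Sequence[RankColumn],
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> RedLineSummary:
    """Aggregate breach and top-k counts over all same-user observations.

    A same-user observation is one (column, other text of the same user)
    pair.  ``first_among_facilitator`` counts, for each column and each
    other facilitator the focal user wrote with, whether the user's own
    text ranks closest among all texts sharing that facilitator (and
    ``second_among_facilitator`` whether it ranks in the top two).
    Grouping by facilitator requires ``metadata``; without it those two
    counts are reported as 0.
    """
    breaches = top3 = top5 = top10 = denom = 0
    firsts = seconds = 0
    for col in columns:
        for e in col.same_user_entries():
            denom += 1
            if e.rank <= col.red_line:
                breaches += 1
            if e.rank <= 3:
                top3 += 1
            if e.rank <= 5:
                top5 += 1
            if e.rank <= 10:
                top10 += 1
        if metadata is not None:
            groups: dict[str, list[RankEntry]] = {}
            for e in col.entries:
                groups.setdefault(metadata[e.label][1], []).append(e)
            for fac, entries in groups.items():
                if fac == col.facilitator:
                    continue
                mine = [e for e in entries if e.same_user]
                if not mine:
                    continue  # focal user did not write with this facilitator
                entries_sorted = sorted(entries, key=lambda e: e.rank)
                position = entries_sorted.index(mine[0]) + 1
                if position == 1:
                    firsts += 1
                if position <= 2:
                    seconds += 1
    return RedLineSummary(
        breaches=breaches,
        top3=top3,
        top5=top5,
        top10=top10,
        first_among_facilitator=firsts,
        second_among_facilitator=seconds,
        denominator=denom,
    )


def _column_params(
    metadata: Mapping[str, tuple[str, str]]
) -> list[tuple[str, int, int, int]]:
    """Per column: (label, M non-focal texts, m same-user, r red line)."""
    labels = sorted(metadata)
    user_counts: dict[str, int] = {}
    fac_counts: dict[str, int] = {}
    for u, f in metadata.values():
        user_counts[u] = user_counts.get(u, 0) + 1
        fac_counts[f] = fac_counts.get(f, 0) + 1
    out = []
    for lab in labels:
        u, f = metadata[lab]
        out.append((lab, len(labels) - 1, user_counts[u] - 1, fac_counts[f] - 1))
    return out


def null_expected_breaches(metadata: Mapping[str, tuple[str, str]]) -> dict:
    """Random-ranking expectation and variance of red-line breach counts.

    Under exchangeable (uniformly random) rankings the number of same-user
    texts above the red line in one column is hypergeometric: ``m`` marked
    texts among ``M``, ``r`` drawn.  Mean ``m*r/M``; variance
    ``m*(r/M)*(1-r/M)*(M-m)/(M-1)``.  Column totals are summed (columns
    treated as independent, an approximation for the total's variance).
    """
    per_column = {}
    total_mean = total_var = 0.0
    for lab, M, m, r in _column_params(metadata):
        mean = m * r / M if M else 0.0
        var = m * (r / M) * (1 - r / M) * (M - m) / (M - 1) if M > 1 else 0.0
        per_column[lab] = {"mean": mean, "variance": var}
        total_mean += mean
        total_var += var
    return {
        "per_column": per_column,
        "total_mean": total_mean,
        "total_variance": total_var,
    }


def permutation_null(
    metadata: Mapping[str, tuple[str, str]],
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo distribution of total breaches under random rankings.

    Each draw shuffles every column's ranking independently; the number of
    same-user texts above the red line is then a hypergeometric sample per
    column, summed across columns.  Returns the array of totals.
    """
    rng = np.random.default_rng() if rng is None else rng
    totals = np.zeros(n_draws, dtype=int)
    for _, M, m, r in _column_params(metadata):
        if m == 0 or r == 0:
            continue
        totals += rng.hypergeometric(ngood=m, nbad=M - m, nsample=r, size=n_draws)
    return totals


def rank_table_wide(columns: Sequence[RankColumn]) -> pd.DataFrame:
    """Wide layout: columns = focal texts, rows = rank positions."""
    data = {c.focal: [e.label for e in c.entries] for c in columns}
    n = max(len(v) for v in data.values())
    idx = pd.Index(range(1, n + 1), name="rank")
    return pd.DataFrame(data, index=idx)


def rank_table_tidy(columns: Sequence[RankColumn]) -> pd.DataFrame:
    """Long format with one row per (focal, neighbour) and all flags."""
    rows = []
    for c in columns:
        for e in c.entries:
            rows.append(
                {
                    "focal": c.focal,
                    "red_line": c.red_line,
                    "rank": e.rank,
                    "label": e.label,
                    "distance": e.distance,
                    "same_user": e.same_user,
                    "same_facilitator": e.same_facilitator,
                    "similar_user": e.similar_user,
                    "breach": e.same_user and e.rank <= c.red_line,
                }
            )
    return pd.DataFrame(rows)
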