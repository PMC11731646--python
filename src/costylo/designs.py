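"""Reference metadata for the two FC-center corpora.

The deposited corpora (Zenodo, DOI 10.5281/zenodo.7273147) come from two
Italian facilitated-communication centers.  Center 1 has seven users who
all wrote with a single facilitator; Center 2 has ten users (U8..U17)
writing with seven facilitators (F1..F5, F7, F8) in 28 user--facilitator
pairings, heavily unbalanced: F1 assisted every user, F7 a single one.

``CENTER2_DESIGN`` encodes which user wrote with which facilitator.  The
full matrix is reconstructed from the published corpus description: the
per-facilitator user counts (10/6/4/2/2/1/3), the pairings named in the
corpus examples, and the relationship-group totals the design implies.

``CENTER2_SIMILARITY`` is the inter-user stylistic similarity map derived
from the cluster analyses: up to two similar users per user, directional
(not necessarily mutual).
"""

from __future__ import annotations

from typing import Mapping

__all__ = [
    "CENTER1_USERS",
    "CENTER1_FACILITATOR",
    "CENTER2_DESIGN",
    "CENTER2_SIMILARITY",
    "center1_metadata",
    "center2_metadata",
    "design_to_metadata",
]

#: Center 1: seven users, one facilitator.
CENTER1_USERS: tuple[str, ...] = tuple(f"U{i}" for i in range(1, 8))
CENTER1_FACILITATOR = "F1"

#: Center 2: facilitator -> users assisted (users-per-facilitator 10/6/4/2/2/1/3).
CENTER2_DESIGN: dict[str, tuple[str, ...]] = {
    "F1": tuple(f"U{i}" for i in range(8, 18)),
    "F2": ("U8", "U9", "U10", "U11", "U12", "U16"),
    "F3": ("U8", "U13", "U15", "U16"),
    "F4": ("U9", "U10"),
    "F5": ("U12", "U14"),
    "F7": ("U12",),
    "F8": ("U10", "U12", "U17"),
}

#: Directional inter-user similarity: user -> up to two stylistically similar users.
CENTER2_SIMILARITY: dict[str, tuple[str, ...]] = {
    "U8": ("U16", "U14"),
    "U9": ("U11",),
    "U10": ("U11", "U12"),
    "U11": ("U10", "U12"),
    "U12": ("U10", "U11"),
    "U13": ("U14", "U8"),
    "U14": ("U13", "U8"),
    "U15": ("U16",),
    "U16": ("U8", "U14"),
    "U17": ("U8", "U16"),
}


def design_to_metadata(design: Mapping[str, tuple[str, ...]]) -> dict[str, tuple[str, str]]:
    """Expand a facilitator->users design into label -> (user, facilitator)."""
    meta = {}
    for fac in sorted(design):
        for user in design[fac]:
            meta[f"{user}_{fac}"] = (user, fac)
    return dict(sorted(meta.items()))


def center2_metadata() -> dict[str, tuple[str, str]]:
    """Label -> (user, facilitator) for the 28 Center-2 pairings."""
    return design_to_metadata(CENTER2_DESIGN)


def center1_metadata() -> dict[str, tuple[str, str]]:
    """Label -> (user, facilitator) for the 7 Center-1 pairings."""
    return {f"{u}_{CENTER1_FACILITATOR}": (u, CENTER1_FACILITATOR) for u in CENTER1_USERS}
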