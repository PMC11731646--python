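"""Bootstrap consensus networks over feature-size sweeps.

Rather than committing to one feature-vector size, the consensus network
repeats the distance analysis for a sweep of sizes (100, 200, ..., 5,000
most frequent words by default) and, in each run, connects every text to
its ``k_nn`` nearest neighbours with rank-decreasing weights (3, 2, 1 for
``k_nn = 3``).  Edge weights accumulate across runs into an undirected
weighted graph whose heavy edges are similarities stable across feature
scales.

Link accounting follows the per-node ("directed") convention: each text
can establish a link to every eligible partner, so an undirected edge is
counted once from each side in category tables and red-line rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .distance import burrows_delta, cosine_delta
from .features import FeatureSpec, extract_features, zscore

__all__ = [
    "BCNConfig",
    "run_bcn",
    "nearest_neighbour_edges",
    "edge_table",
    "category_summary",
    "possible_links",
    "write_graphml",
    "write_edge_list",
]


@dataclass(frozen=True)
class BCNConfig:
    """Sweep and edge-rule configuration for the consensus network."""

    mode: str = "word"
    n: int = 3
    sizes: tuple[int, ...] = tuple(range(100, 5001, 100))
    k_nn: int = 3
    weights: tuple[int, ...] | None = None  # default: k_nn + 1 - j for rank j
    metric: str = "cosine_delta"

    def __post_init__(self) -> None:
        if not self.sizes or list(self.sizes) != sorted(set(self.sizes)):
            raise ValueError("sizes must be non-empty and strictly increasing")
        if self.k_nn < 1:
            raise ValueError("k_nn must be >= 1")
        w = self.rank_weights
        if any(x <= 0 for x in w) or any(a > b for a, b in zip(w[1:], w[:-1])):
            raise ValueError("weights must be positive and non-increasing")

    @property
    def rank_weights(self) -> tuple[int, ...]:
        if self.weights is not None:
            return tuple(self.weights)
        return tuple(self.k_nn + 1 - j for j in range(1, self.k_nn + 1))


def nearest_neighbour_edges(
    frame: pd.DataFrame, k_nn: int, weights: Sequence[int]
) -> list[tuple[str, str, int]]:
    """Directed (node, j-th neighbour, weight) triples for one distance table.

    Ties in distance are broken by label order, as elsewhere.
    """
    out = []
    for focal in frame.index:
        others = sorted(
            (lab for lab in frame.index if lab != focal),
            key=lambda lab: (float(frame.loc[focal, lab]), lab),
        )
        for j, lab in enumerate(others[:k_nn]):
            out.append((focal, lab, int(weights[j])))
    return out


def run_bcn(
    samples: Mapping[str, str | Sequence[str]], config: BCNConfig
) -> nx.Graph:
    """Accumulate nearest-neighbour links over the feature-size sweep.

    For each sweep size: extract the top-k features, z-score, compute the
    configured delta distance, and add weight ``w_j`` to the undirected
    edge between every node and its j-th nearest neighbour.  When two
    nodes select each other their contributions sum.  Sweep sizes beyond
    the corpus's feature inventory are skipped with a warning.

    The graph records the executed sweep in ``G.graph["runs"]``; total
    edge weight equals ``runs * nodes * sum(weights)`` exactly.
    """
    if len(samples) < config.k_nn + 1:
        raise ValueError("need at least k_nn + 1 samples")
    metric = cosine_delta if config.metric == "cosine_delta" else burrows_delta
    g = nx.Graph()
    g.add_nodes_from(samples)
    runs = 0
    for size in config.sizes:
        spec = FeatureSpec(mode=config.mode, n=config.n, k=size)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            freq = extract_features(samples, spec)
            truncated = any("truncating" in str(w.message) for w in caught)
        if truncated:
            warnings.warn(
                f"sweep size {size} exceeds available features; run skipped",
                stacklevel=2,
            )
            continue
        z, _ = zscore(freq)
        d = metric(z)
        for a, b, w in nearest_neighbour_edges(d.frame, config.k_nn, config.rank_weights):
            if g.has_edge(a, b):
                g[a][b]["weight"] += w
            else:
                g.add_edge(a, b, weight=w)
        runs += 1
    g.graph["runs"] = runs
    g.graph["config"] = config
    return g


def edge_table(
    net: nx.Graph,
    metadata: Mapping[str, tuple[str, str]],
    simmap: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-node links ranked by descending weight, with red-line flags.

    Long format: one row per (node, linked node).  The red line is the
    same convention as in the distance-table rank analysis: ``n - 1``
    where ``n`` is the number of texts written with the node's
    facilitator.  Nodes without links produce no rows.
    """
    simmap = simmap or {}
    fac_counts: dict[str, int] = {}
    for lab in net.nodes:
        fac_counts[metadata[lab][1]] = fac_counts.get(metadata[lab][1], 0) + 1
    rows = []
    for node in sorted(net.nodes):
        user, fac = metadata[node]
        red = fac_counts[fac] - 1
        links = sorted(
            net[node].items(), key=lambda kv: (-kv[1]["weight"], kv[0])
        )
        for rank, (other, attrs) in enumerate(links, start=1):
            ouser, ofac = metadata[other]
            rows.append(
                {
                    "node": node,
                    "red_line": red,
                    "rank": rank,
                    "linked": other,
                    "weight": attrs["weight"],
                    "same_user": ouser == user,
                    "same_facilitator": ofac == fac,
                    "similar_user": ouser in simmap.get(user, ())
                    or user in simmap.get(ouser, ()),
                    "breach": ouser == user and rank <= red,
                }
            )
    return pd.DataFrame(rows)


def edge_table_summary(table: pd.DataFrame) -> dict:
    """Same-user placement counts over an edge table's rows."""
    same = table[table["same_user"]]
    return {
        "above_red_line": int(same["breach"].sum()),
        "top3": int((same["rank"] <= 3).sum()),
        "top5": int((same["rank"] <= 5).sum()),
        "denominator": int(len(same)),
    }


def category_summary(
    net: nx.Graph, metadata: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Links, weight totals, weight share, and mean weight per category.

    Categories: ``same_user`` (precedence), ``same_facilitator``,
    ``neither``.  Counted per node, so every undirected edge contributes
    to two rows of the underlying link list; shares sum to 100%.
    """
    cats = {"same_user": [], "same_facilitator": [], "neither": []}
    for a, b, attrs in net.edges(data=True):
        ua, fa = metadata[a]
        ub, fb = metadata[b]
        if ua == ub:
            cat = "same_user"
        elif fa == fb:
            cat = "same_facilitator"
        else:
            cat = "neither"
        cats[cat].extend([attrs["weight"]] * 2)  # one link per endpoint
    total = sum(sum(v) for v in cats.values())
    rows = []
    for cat, ws in cats.items():
        tw = sum(ws)
        rows.append(
            {
                "category": cat,
                "n_links": len(ws),
                "total_weight": tw,
                "weight_share": 100.0 * tw / total if total else float("nan"),
                "mean_weight": float(np.mean(ws)) if ws else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def possible_links(metadata: Mapping[str, tuple[str, str]]) -> dict[str, int]:
    """Theoretical per-node link maxima for each category.

    Each text can link to every other text; the pair's category follows
    the same precedence as :func:`category_summary`.  For the
    multi-facilitator reference design this gives 60 same-user, 142
    same-facilitator, and 554 neither (summing to 28 x 27 = 756).
    """
    from .groups import possible_pair_counts

    return possible_pair_counts(metadata)


def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    g.graph.pop("config", None)  # dataclass not serializable to GraphML
    nx.write_graphml(g, path)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"source": a, "target": b, "weight": attrs["weight"]}
        for a, b, attrs in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
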