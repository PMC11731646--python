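"""Pair-relationship groups and the statistics run on their distances.

Every ordered pair of texts falls into exactly one of five groups:

* ``IU`` — the two texts share the same user;
* ``FU`` — same facilitator, and the focal text's user is stylistically
  similar to the other's (per the similarity map);
* ``F``  — same facilitator only;
* ``RU`` — similar users only (different facilitator);
* ``NR`` — no shared user, facilitator, or similarity.

The similarity map lists up to two similar users per user and is
directional; group assignment follows the focal text's direction by
default (``mutual=False``), which is the reading under which the
published group counts for the multi-facilitator corpus are reproduced
exactly.  ``mutual=True`` gives the symmetrized variant.

Statistics: a one-sample t-test of each group's distances against a
reference value (1 as the neutral midpoint of the cosine-delta range, or
the corpus's grand mean), an iterated equal-size subsample two-sample
t-test between groups (mean p over repetitions), and a cross-validated
classification of pair distances into groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .distance import DistanceTable

__all__ = [
    "GROUPS",
    "assign_relation",
    "relation_table",
    "group_summary",
    "one_sample_test",
    "iterated_subsample_test",
    "classify_relations",
    "possible_pair_counts",
    "similarity_from_distance",
]

GROUPS = ("IU", "FU", "F", "RU", "NR")

SimilarityMap = Mapping[str, Sequence[str]]


def assign_relation(
    focal: tuple[str, str],
    other: tuple[str, str],
    simmap: SimilarityMap,
    mutual: bool = False,
) -> str:
    """Group of the ordered pair (focal, other); both are (user, facilitator)."""
    if simmap is None:
        raise ValueError("similarity map required for FU/RU assignment")
    fu, ff = focal
    ou, of = other
    if fu == ou:
        return "IU"
    similar = ou in simmap.get(fu, ())
    if mutual:
        similar = similar or fu in simmap.get(ou, ())
    if ff == of:
        return "FU" if similar else "F"
    return "RU" if similar else "NR"


def relation_table(
    metadata: Mapping[str, tuple[str, str]],
    simmap: SimilarityMap,
    mutual: bool = False,
) -> pd.DataFrame:
    """All ordered pairs of labels with their relationship group."""
    labels = sorted(metadata)
    rows = [
        {
            "focal": a,
            "other": b,
            "group": assign_relation(metadata[a], metadata[b], simmap, mutual),
        }
        for a in labels
        for b in labels
        if a != b
    ]
    return pd.DataFrame(rows)


def possible_pair_counts(metadata: Mapping[str, tuple[str, str]]) -> dict[str, int]:
    """Ordered-pair maxima per coarse category: same_user / same_facilitator / neither.

    Counted per text (each unordered pair contributes twice), the
    convention under which every text can "establish a link" with each of
    its eligible partners.
    """
    labels = sorted(metadata)
    counts = {"same_user": 0, "same_facilitator": 0, "neither": 0}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            ua, fa = metadata[a]
            ub, fb = metadata[b]
            if ua == ub:
                counts["same_user"] += 1
            elif fa == fb:
                counts["same_facilitator"] += 1
            else:
                counts["neither"] += 1
    return counts


def group_summary(d: DistanceTable, relations: pd.DataFrame) -> pd.DataFrame:
    """Count, mean, and SD of distances per relationship group.

    ``relations`` must cover all ordered pairs of the table's labels.
    Empty groups are reported with count 0 and NaN moments.
    """
    rel = relations.copy()
    rel["distance"] = [
        float(d.frame.loc[f, o]) for f, o in zip(rel["focal"], rel["other"])
    ]
    out = []
    for g in GROUPS:
        vals = rel.loc[rel["group"] == g, "distance"].to_numpy()
        out.append(
            {
                "group": g,
                "count": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(out).set_index("group")


def one_sample_test(
    values: Sequence[float], mu: float, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sample t-test of a group's distances against ``mu``.

    Returns ``(statistic, p, reject)``; two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(values, popmean=mu)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def iterated_subsample_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.005,
) -> dict:
    """Equal-size subsample t-test between two groups, iterated.

    Each repetition subsamples both groups without replacement down to the
    smaller group's size, runs an unpaired two-sample t-test, and the mean
    p-value over repetitions drives the decision.  This equalizes the
    otherwise heavily unbalanced group sizes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n = min(len(a), len(b))
    if n < 2:
        raise ValueError("need at least 2 values in each group")
    pvals = []
    for _ in range(reps):
        sa = rng.choice(a, size=n, replace=False)
        sb = rng.choice(b, size=n, replace=False)
        pvals.append(float(stats.ttest_ind(sa, sb).pvalue))
    mean_p = float(np.mean(pvals))
    return {
        "mean_p": mean_p,
        "reject": mean_p < alpha,
        "p_values": pvals,
        "subsample_size": n,
        "reps": reps,
    }


def classify_relations(
    distances: Sequence[float],
    groups: Sequence[str],
    method: Literal["weighted-knn", "svm"] = "weighted-knn",
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Cross-validated classification of scalar pair distances into groups.

    The feature is the pair's distance value alone — the only quantity
    attached to each observation — so this measures how separable the
    groups' distance distributions are, not a full authorship model.
    Returns accuracy, the pooled confusion matrix (rows = true groups in
    ``GROUPS`` order), and the set of predicted classes.
    """
    X = np.asarray(distances, dtype=float).reshape(-1, 1)
    y = np.asarray(groups)
    if method == "weighted-knn":
        clf = KNeighborsClassifier(n_neighbors=10, weights="distance")
    elif method == "svm":
        clf = SVC(kernel="rbf")
    else:
        raise ValueError(f"unknown method {method!r}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        clf.fit(X[train], y[train])
        preds[test] = clf.predict(X[test])
    acc = float(np.mean(preds == y))
    cm = confusion_matrix(y, preds.astype(str), labels=list(GROUPS))
    return {
        "accuracy": acc,
        "confusion": pd.DataFrame(cm, index=list(GROUPS), columns=list(GROUPS)),
        "predicted_classes": sorted(set(preds.astype(str))),
        "method": method,
        "folds": folds,
        "seed": seed,
    }


def similarity_from_distance(
    d: DistanceTable,
    metadata: Mapping[str, tuple[str, str]],
    max_similar: int = 2,
) -> dict[str, tuple[str, ...]]:
    """Derive a similarity map from mean inter-user distances.

    Helper for synthetic corpora, where no curated map exists: each user's
    ``max_similar`` nearest other users (by mean pairwise text distance)
    are declared similar.  Directional by construction.
    """
    users = sorted({u for u, _ in metadata.values()})
    by_user: dict[str, list[str]] = {u: [] for u in users}
    for lab, (u, _) in metadata.items():
        by_user[u].append(lab)
    simmap = {}
    for u in users:
        means = []
        for v in users:
            if v == u:
                continue
            vals = [
                float(d.frame.loc[a, b]) for a in by_user[u] for b in by_user[v]
            ]
            means.append((float(np.mean(vals)), v))
        means.sort()
        simmap[u] = tuple(v for _, v in means[:max_similar])
    return simmap
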