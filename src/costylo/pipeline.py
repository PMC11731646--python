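"""End-to-end orchestration of the two study workflows.

Study 1 asks whether users assisted by a *single* facilitator leave a
detectable stylistic signature: each user's pairing text is split into
four fragments, recombined into two chunks under three schemes, and the
chunked corpus is clustered; the leaf-pairing rate measures how often a
user's two chunks are dendrogram siblings.

Study 2 asks whether the signature survives *multiple* facilitators: the
multi-facilitator corpus is profiled at 1,000 most-frequent words, ranked
against the facilitator red line, grouped into pair-relationship classes
with their statistics, and aggregated into a bootstrap consensus network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import groups as grp
from . import network as net
from .corpus import PairText, assemble_pairs, chunk_all, filter_min_words, read_corpus
from .distance import DistanceTable, burrows_delta, cosine_delta, hcluster, same_user_leaf_pairing
from .features import FeatureSpec, extract_features, zscore
from .ranks import (
    build_rank_table,
    null_expected_breaches,
    rank_table_tidy,
    rank_table_wide,
    red_line_summary,
)

log = logging.getLogger("costylo")

__all__ = ["RunConfig", "run_study1", "run_study2", "load_pairs", "distance_from_samples"]


@dataclass
class RunConfig:
    """Configuration for a full study run."""

    input_dir: str | None = None
    output_dir: str = "costylo_out"
    manifest: str | None = None
    caps_threshold: float = 0.8
    min_words: int = 5000
    mfw: int = 1000
    trigram_k: int = 1000
    metric: str = "cosine_delta"
    linkage: str = "ward"
    bcn_sizes: tuple[int, ...] = tuple(range(100, 5001, 100))
    bcn_k_nn: int = 3
    similarity_map: dict[str, tuple[str, ...]] | None = None
    name_list: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("bcn_sizes", "name_list"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "similarity_map" in raw and raw["similarity_map"] is not None:
            raw["similarity_map"] = {
                k: tuple(v) for k, v in raw["similarity_map"].items()
            }
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_pairs(config: RunConfig) -> list[PairText]:
    if config.input_dir is None:
        raise ValueError("config.input_dir is not set")
    sessions = read_corpus(
        config.input_dir,
        manifest=config.manifest,
        caps_threshold=config.caps_threshold,
        name_list=config.name_list,
    )
    return assemble_pairs(sessions)


def distance_from_samples(
    samples: Mapping[str, str], spec: FeatureSpec, metric: str = "cosine_delta"
) -> DistanceTable:
    """samples -> frequency matrix -> z-scores -> delta distance table."""
    freq = extract_features(samples, spec)
    z, dropped = zscore(freq)
    if dropped:
        log.info("dropped %d zero-variance features", len(dropped))
    fn = cosine_delta if metric == "cosine_delta" else burrows_delta
    return fn(z, feature_desc=spec.describe())


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str), encoding="utf-8")


def run_study1(
    config: RunConfig, pairs: Sequence[PairText] | None = None
) -> dict:
    """Chunked single-facilitator analysis: 3 schemes x 2 feature modes.

    Writes distance tables, newick dendrograms, and a pairing report per
    condition; returns the report dictionary.
    """
    pairs = list(pairs) if pairs is not None else load_pairs(config)
    facs = {p.facilitator_id for p in pairs}
    if len(facs) != 1:
        raise ValueError(f"chunk analysis expects a single facilitator, got {sorted(facs)}")
    pairs, excluded = filter_min_words(pairs, config.min_words)
    if not pairs:
        raise ValueError("no pairing passes the minimum-word filter")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "excluded_short_pairs": excluded,
        "conditions": {},
    }
    specs = {
        "words": FeatureSpec(mode="word", k=config.mfw),
        "trigrams": FeatureSpec(mode="char_ngram", n=3, k=config.trigram_k),
    }
    for scheme in ("A", "B", "C"):
        samples, dropped = chunk_all(pairs, scheme, min_chunk_words=config.min_words)
        for mode, spec in specs.items():
            cond = f"{scheme}_{mode}"
            d = distance_from_samples(samples, spec, config.metric)
            dend = hcluster(d, method=config.linkage)
            meta = {lab: lab.rsplit("_", 1)[0] for lab in samples}
            rate, exceptions = same_user_leaf_pairing(dend, meta)
            d.to_csv(outdir / f"distance_{cond}.csv")
            (outdir / f"dendrogram_{cond}.nwk").write_text(
                dend.to_newick(), encoding="utf-8"
            )
            report["conditions"][cond] = {
                "excluded_short_chunks": dropped,
                "n_samples": len(samples),
                "leaf_pairing_rate": rate,
                "exceptions": exceptions,
            }
    _write_json(report, outdir / "study1_report.json")
    return report


def run_study2(
    config: RunConfig,
    pairs: Sequence[PairText] | None = None,
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> dict:
    """Full multi-facilitator analysis on the pairing texts.

    Produces the 1,000-MFW distance table, rank analysis against the red
    line (with the random-ranking null), relationship-group statistics and
    tests, distance-based classification, and the bootstrap consensus
    network with its category summary.  Returns the collated report.
    """
    pairs = list(pairs) if pairs is not None else load_pairs(config)
    pairs, excluded = filter_min_words(pairs, config.min_words)
    if metadata is None:
        metadata = {p.label: (p.user_id, p.facilitator_id) for p in pairs}
    samples = {p.label: p.text for p in pairs}
    if len({f for _, f in metadata.values()}) < 2:
        raise ValueError("multi-facilitator corpus required")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    spec = FeatureSpec(mode="word", k=config.mfw)
    d = distance_from_samples(samples, spec, config.metric)
    d.to_csv(outdir / "distance_words.csv")

    dend = hcluster(d, method=config.linkage)
    (outdir / "dendrogram_words.nwk").write_text(dend.to_newick(), encoding="utf-8")

    simmap = config.similarity_map
    if simmap is None:
        simmap = grp.similarity_from_distance(d, metadata)
        log.info("derived similarity map from distance table: %s", simmap)

    columns = build_rank_table(d, metadata, simmap)
    summary = red_line_summary(columns, metadata)
    null = null_expected_breaches(metadata)
    rank_table_wide(columns).to_csv(outdir / "rank_table_wide.csv")
    rank_table_tidy(columns).to_csv(outdir / "rank_table_tidy.csv", index=False)

    relations = grp.relation_table(metadata, simmap)
    gsum = grp.group_summary(d, relations)
    gsum.to_csv(outdir / "group_stats.csv")
    rel = relations.copy()
    rel["distance"] = [
        float(d.frame.loc[f, o]) for f, o in zip(rel["focal"], rel["other"])
    ]
    grand_mean = float(rel["distance"].mean())
    tests = {}
    for g in grp.GROUPS:
        vals = rel.loc[rel["group"] == g, "distance"].to_numpy()
        if len(vals) < 2:
            continue
        tests[g] = {}
        for name, mu in (("neutral", 1.0), ("grand_mean", round(grand_mean, 2))):
            t, p, rejectd = grp.one_sample_test(vals, mu)
            tests[g][name] = {"mu": mu, "t": t, "p": p, "reject": rejectd}
    iu = rel.loc[rel["group"] == "IU", "distance"].to_numpy()
    subsample = {}
    for g in ("FU", "F", "RU", "NR"):
        vals = rel.loc[rel["group"] == g, "distance"].to_numpy()
        if len(vals) >= 2 and len(iu) >= 2:
            subsample[f"IU_vs_{g}"] = grp.iterated_subsample_test(
                iu, vals, reps=10, seed=rng
            )
    classification = {}
    for method in ("weighted-knn", "svm"):
        res = grp.classify_relations(
            rel["distance"], rel["group"], method=method, seed=config.seed
        )
        res["confusion"] = res["confusion"].to_dict()
        classification[method] = res

    bcn = net.run_bcn(
        samples,
        net.BCNConfig(
            mode="word", sizes=config.bcn_sizes, k_nn=config.bcn_k_nn,
            metric=config.metric,
        ),
    )
    net.write_graphml(bcn, outdir / "consensus_network.graphml")
    net.write_edge_list(bcn, outdir / "consensus_edges.csv")
    etable = net.edge_table(bcn, metadata, simmap)
    etable.to_csv(outdir / "consensus_edge_table.csv", index=False)
    esummary = net.edge_table_summary(etable)
    csummary = net.category_summary(bcn, metadata)
    csummary.to_csv(outdir / "consensus_categories.csv")

    report = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_pairs": len(pairs),
        "excluded_short_pairs": excluded,
        "red_line": summary.to_dict(),
        "null_total_expected_breaches": null["total_mean"],
        "group_stats": gsum.reset_index().to_dict(orient="records"),
        "one_sample_tests": tests,
        "iterated_subsample_tests": {
            k: {kk: vv for kk, vv in v.items() if kk != "p_values"}
            for k, v in subsample.items()
        },
        "classification": {
            m: {"accuracy": r["accuracy"], "predicted_classes": r["predicted_classes"]}
            for m, r in classification.items()
        },
        "consensus": {
            "runs": bcn.graph["runs"],
            "edge_summary": esummary,
            "categories": csummary.to_dict(orient="index"),
            "possible_links": net.possible_links(metadata),
        },
        "similarity_map": {k: list(v) for k, v in simmap.items()},
    }
    _write_json(report, outdir / "study2_report.json")
    return report
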