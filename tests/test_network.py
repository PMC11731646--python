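"""Bootstrap consensus network construction and link accounting."""

import math
from collections import Counter

import numpy as np
import pytest

from costylo.network import (
    BCNConfig,
    category_summary,
    edge_table,
    edge_table_summary,
    nearest_neighbour_edges,
    possible_links,
    run_bcn,
    write_edge_list,
    write_graphml,
)


def _toy_samples(rng, n_texts=5, length=400, vocab=40):
    words = [chr(97 + i) + chr(97 + j) for i in range(8) for j in range(5)][:vocab]
    out = {}
    for i in range(n_texts):
        probs = rng.dirichlet(np.ones(vocab) * 2)
        out[f"t{i}"] = " ".join(rng.choice(words, size=length, p=probs))
    return out


def _bruteforce_network(samples, config):
    """Independent recomputation: Counter-based freqs, manual z and cosine."""
    edges: Counter = Counter()
    for size in config.sizes:
        counts = {lab: Counter(text.split()) for lab, text in samples.items()}
        totals = {lab: sum(c.values()) for lab, c in counts.items()}
        corpus = Counter()
        for c in counts.values():
            corpus.update(c)
        feats = sorted(corpus, key=lambda w: (-corpus[w], w))[:size]
        rows = {
            lab: [counts[lab][f] / totals[lab] for f in feats] for lab in samples
        }
        z = {}
        for j, f in enumerate(feats):
            col = [rows[lab][j] for lab in samples]
            mu = sum(col) / len(col)
            sd = math.sqrt(sum((x - mu) ** 2 for x in col) / len(col))
            if sd == 0:
                continue
            for lab in samples:
                z.setdefault(lab, []).append((rows[lab][j] - mu) / sd)

        def cos_d(a, b):
            num = sum(x * y for x, y in zip(z[a], z[b]))
            na = math.sqrt(sum(x * x for x in z[a]))
            nb = math.sqrt(sum(x * x for x in z[b]))
            return 1 - num / (na * nb)

        for focal in samples:
            others = sorted(
                (lab for lab in samples if lab != focal),
                key=lambda lab: (cos_d(focal, lab), lab),
            )
            for j, lab in enumerate(others[: config.k_nn]):
                edges[frozenset((focal, lab))] += config.rank_weights[j]
    return edges


class TestConfig:
    def test_default_linear_weights(self):
        assert BCNConfig(k_nn=3).rank_weights == (3, 2, 1)

    def test_invalid_sweep_rejected(self):
        with pytest.raises(ValueError):
            BCNConfig(sizes=(200, 100))

    def test_increasing_weights_rejected(self):
        with pytest.raises(ValueError):
            BCNConfig(k_nn=2, weights=(1, 2))


class TestRunBCN:
    def test_three_nodes_one_run_folds_links(self, rng):
        samples = _toy_samples(rng, n_texts=3)
        net = run_bcn(samples, BCNConfig(sizes=(20,), k_nn=1))
        assert net.number_of_edges() <= 3
        assert sum(d["weight"] for _, _, d in net.edges(data=True)) == 3

    def test_repeated_runs_accumulate_double_weights(self, rng):
        samples = _toy_samples(rng)
        config = BCNConfig(sizes=(20,), k_nn=2)
        single = run_bcn(samples, config)
        # two runs of identical data: every edge weight doubles
        doubled = Counter()
        import pandas as pd

        from costylo.pipeline import distance_from_samples
        from costylo.features import FeatureSpec

        d = distance_from_samples(samples, FeatureSpec(mode="word", k=20))
        for _ in range(2):
            for a, b, w in nearest_neighbour_edges(d.frame, 2, config.rank_weights):
                doubled[frozenset((a, b))] += w
        for a, b, attrs in single.edges(data=True):
            assert doubled[frozenset((a, b))] == 2 * attrs["weight"]

    def test_deterministic_given_input(self, rng):
        samples = _toy_samples(rng)
        config = BCNConfig(sizes=(10, 25), k_nn=2)
        g1 = run_bcn(samples, config)
        g2 = run_bcn(samples, config)
        assert {frozenset(e): d["weight"] for *e, d in g1.edges(data=True)} == {
            frozenset(e): d["weight"] for *e, d in g2.edges(data=True)
        }

    def test_weight_conservation_exact(self, rng):
        samples = _toy_samples(rng)
        config = BCNConfig(sizes=(10, 20, 30), k_nn=3)
        net = run_bcn(samples, config)
        total = sum(d["weight"] for _, _, d in net.edges(data=True))
        assert total == net.graph["runs"] * len(samples) * sum(config.rank_weights)

    def test_edge_set_matches_bruteforce_oracle(self, rng):
        samples = _toy_samples(rng)
        config = BCNConfig(sizes=(10, 25), k_nn=3)
        net = run_bcn(samples, config)
        expected = _bruteforce_network(samples, config)
        got = {
            frozenset((a, b)): d["weight"] for a, b, d in net.edges(data=True)
        }
        assert got == dict(expected)

    def test_oversized_sweep_skipped_with_warning(self, rng):
        samples = _toy_samples(rng, vocab=30)
        with pytest.warns(UserWarning, match="skipped"):
            net = run_bcn(samples, BCNConfig(sizes=(10, 10_000), k_nn=1))
        assert net.graph["runs"] == 1

    def test_too_few_samples_rejected(self, rng):
        samples = _toy_samples(rng, n_texts=3)
        with pytest.raises(ValueError):
            run_bcn(samples, BCNConfig(sizes=(10,), k_nn=3))


class TestNearestNeighbourEdges:
    def test_ties_broken_by_label(self):
        import pandas as pd

        frame = pd.DataFrame(
            [[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]],
            index=list("cab"),
            columns=list("cab"),
        )
        edges = nearest_neighbour_edges(frame, k_nn=1, weights=(1,))
        assert ("c", "a", 1) in edges  # 'a' beats 'b' on the tie


class TestAccounting:
    @pytest.fixture
    def toy_net(self, rng):
        samples = _toy_samples(rng)
        return run_bcn(samples, BCNConfig(sizes=(10, 25), k_nn=2))

    def _meta(self, net):
        users = {"t0": "U1", "t1": "U1", "t2": "U2", "t3": "U2", "t4": "U3"}
        facs = {"t0": "F1", "t1": "F2", "t2": "F1", "t3": "F2", "t4": "F1"}
        return {n: (users[n], facs[n]) for n in net.nodes}

    def test_edge_table_manual_sort(self, toy_net):
        meta = self._meta(toy_net)
        table = edge_table(toy_net, meta)
        for node in toy_net.nodes:
            sub = table[table["node"] == node]
            weights = sub.sort_values("rank")["weight"].tolist()
            assert weights == sorted(weights, reverse=True)
            assert set(sub["linked"]) == set(toy_net[node])

    def test_isolated_node_absent(self, rng):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(["t0", "t1", "t2"])
        g.add_edge("t0", "t1", weight=3)
        meta = {"t0": ("U1", "F1"), "t1": ("U1", "F2"), "t2": ("U2", "F1")}
        table = edge_table(g, meta)
        assert "t2" not in set(table["node"])
        summary = edge_table_summary(table)
        # t0's red line is 1 (F1 has 2 texts) and its same-user link ranks 1;
        # t1's red line is 0 (F2 has 1 text), so its link cannot breach
        assert summary["above_red_line"] == 1
        assert summary["denominator"] == 2

    def test_category_summary_hand_tally(self, toy_net):
        meta = self._meta(toy_net)
        summary = category_summary(toy_net, meta)
        # recount directly over edges
        tally = {"same_user": 0, "same_facilitator": 0, "neither": 0}
        weight = dict.fromkeys(tally, 0)
        for a, b, d in toy_net.edges(data=True):
            (ua, fa), (ub, fb) = meta[a], meta[b]
            cat = (
                "same_user"
                if ua == ub
                else "same_facilitator" if fa == fb else "neither"
            )
            tally[cat] += 2
            weight[cat] += 2 * d["weight"]
        for cat in tally:
            assert summary.loc[cat, "n_links"] == tally[cat]
            assert summary.loc[cat, "total_weight"] == weight[cat]
        assert summary["weight_share"].sum() == pytest.approx(100.0)

    def test_single_edge_full_share(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("t0", "t1", weight=5)
        meta = {"t0": ("U1", "F1"), "t1": ("U1", "F2")}
        summary = category_summary(g, meta)
        assert summary.loc["same_user", "weight_share"] == pytest.approx(100.0)

    def test_counts_bounded_by_possible_links(self, toy_net):
        meta = self._meta(toy_net)
        summary = category_summary(toy_net, meta)
        maxima = possible_links(meta)
        for cat in maxima:
            assert summary.loc[cat, "n_links"] <= maxima[cat]

    def test_possible_links_single_facilitator(self):
        meta = {f"U{i}_F1": (f"U{i}", "F1") for i in range(6)}
        assert possible_links(meta)["same_facilitator"] == 6 * 5

    def test_reference_design_possible_links(self, center2_meta):
        assert possible_links(center2_meta) == {
            "same_user": 60,
            "same_facilitator": 142,
            "neither": 554,
        }


class TestExports:
    def test_graphml_and_edge_list(self, tmp_path, rng):
        import networkx as nx
        import pandas as pd

        samples = _toy_samples(rng)
        net = run_bcn(samples, BCNConfig(sizes=(10,), k_nn=2))
        write_graphml(net, tmp_path / "net.graphml")
        write_edge_list(net, tmp_path / "edges.csv")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_edges() == net.number_of_edges()
        df = pd.read_csv(tmp_path / "edges.csv")
        assert set(df.columns) == {"source", "target", "weight"}
        assert df["weight"].sum() == sum(
            d["weight"] for _, _, d in net.edges(data=True)
        )
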