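"""Delta metrics, clustering, and leaf-pairing scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from costylo.distance import (
    DistanceTable,
    burrows_delta,
    cosine_delta,
    hcluster,
    same_user_leaf_pairing,
)


class TestCosineDelta:
    def test_identical_rows_distance_zero(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert cosine_delta(z).frame.loc["a", "b"] == pytest.approx(0, abs=1e-12)

    def test_antipodal_rows_distance_two(self):
        z = pd.DataFrame([[1.0, -2.0], [-1.0, 2.0]], index=["a", "b"])
        assert cosine_delta(z).frame.loc["a", "b"] == pytest.approx(2, abs=1e-12)

    def test_symmetric_toy_closed_form(self, toy_z):
        # rows are permutations of (1,2,2): cos = 8/9 for every pair
        d = cosine_delta(toy_z).frame
        for a in "abc":
            for b in "abc":
                expected = 0.0 if a == b else 1 / 9
                assert d.loc[a, b] == pytest.approx(expected, abs=1e-10)

    def test_zero_norm_row_rejected(self):
        z = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="degenerate"):
            cosine_delta(z)

    @given(st.floats(0.1, 100.0))
    def test_positive_scaling_invariance(self, scale):
        z = pd.DataFrame([[1.0, 2.0, -1.0], [0.5, -1.0, 2.0]], index=["a", "b"])
        d1 = cosine_delta(z).frame.loc["a", "b"]
        z2 = z.copy()
        z2.loc["a"] *= scale
        d2 = cosine_delta(z2).frame.loc["a", "b"]
        assert d2 == pytest.approx(d1, abs=1e-9)

    @given(
        st.tuples(
            st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5)
        )
    )
    def test_two_feature_analytic_angle(self, vals):
        x1, y1, x2, y2 = vals
        if math.hypot(x1, y1) < 1e-3 or math.hypot(x2, y2) < 1e-3:
            return
        z = pd.DataFrame([[x1, y1], [x2, y2]], index=["a", "b"])
        angle = math.atan2(y2, x2) - math.atan2(y1, x1)
        expected = 1 - math.cos(angle)
        assert cosine_delta(z).frame.loc["a", "b"] == pytest.approx(expected, abs=1e-9)


class TestBurrowsDelta:
    def test_identical_rows(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert burrows_delta(z).frame.loc["a", "b"] == 0

    def test_single_feature_difference_closed_form(self):
        # differ by dz on one of k features -> delta = dz / k
        z = pd.DataFrame([[0.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 3.0]], index=["a", "b"])
        assert burrows_delta(z).frame.loc["a", "b"] == pytest.approx(3 / 4, abs=1e-12)

    def test_symmetric_toy_closed_form(self, toy_z):
        d = burrows_delta(toy_z).frame
        for a in "abc":
            for b in "abc":
                expected = 0.0 if a == b else 2 / 3
                assert d.loc[a, b] == pytest.approx(expected, abs=1e-10)


class TestTableInvariants:
    @pytest.mark.parametrize("metric", [cosine_delta, burrows_delta])
    def test_symmetry_zero_diagonal(self, metric, rng):
        z = pd.DataFrame(
            rng.normal(size=(6, 10)), index=[f"s{i}" for i in range(6)]
        )
        d = metric(z).frame.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_square_labels_enforced(self):
        with pytest.raises(ValueError):
            DistanceTable(
                pd.DataFrame([[0, 1]], index=["a"], columns=["a", "b"]), metric="x"
            )


def _complete_linkage_oracle(frame: pd.DataFrame):
    """Naive agglomeration under complete linkage: merge heights sequence."""
    clusters = {i: {lab} for i, lab in enumerate(frame.index)}
    heights = []
    next_id = len(clusters)
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if i >= j:
                    continue
                dist = max(
                    frame.loc[a, b] for a in clusters[i] for b in clusters[j]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return heights


class TestHCluster:
    def test_two_samples_single_merge(self):
        frame = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=list("ab"), columns=list("ab"))
        dend = hcluster(DistanceTable(frame, "cosine_delta"))
        assert dend.linkage_matrix.shape == (1, 4)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.4)

    def test_block_structure_top_split(self, rng):
        labels = [f"s{i}" for i in range(6)]
        d = np.full((6, 6), 1.0)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        frame = pd.DataFrame(d, index=labels, columns=labels)
        dend = hcluster(DistanceTable(frame, "cosine_delta"), method="complete")
        # last merge joins the two blocks: its children cover {0,1,2} and {3,4,5}
        from scipy.cluster.hierarchy import fcluster

        two = fcluster(dend.linkage_matrix, t=2, criterion="maxclust")
        assert len(set(two[:3])) == 1 and len(set(two[3:])) == 1
        assert two[0] != two[3]

    def test_merge_heights_match_bruteforce_oracle(self, rng):
        labels = [f"s{i}" for i in range(6)]
        m = rng.uniform(0.2, 1.8, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        frame = pd.DataFrame(m, index=labels, columns=labels)
        dend = hcluster(DistanceTable(frame, "cosine_delta"), method="complete")
        assert dend.linkage_matrix[:, 2].tolist() == pytest.approx(
            _complete_linkage_oracle(frame)
        )

    def test_heights_nondecreasing(self, rng):
        z = pd.DataFrame(rng.normal(size=(8, 20)), index=[f"s{i}" for i in range(8)])
        dend = hcluster(cosine_delta(z))
        heights = dend.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_deterministic_and_parseable(self, rng):
        z = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"s {i}:x" for i in range(5)])
        d = cosine_delta(z)
        n1 = hcluster(d).to_newick()
        n2 = hcluster(d).to_newick()
        assert n1 == n2
        assert n1.endswith(";") and n1.count("(") == n1.count(")")
        # sanitized labels: no spaces or colons inside names
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(n1), "newick")
        assert tree.count_terminals() == 5


class TestLeafPairing:
    def test_perfect_pairing(self):
        labels = ["U1_a", "U1_b", "U2_a", "U2_b"]
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        frame = pd.DataFrame(d, index=labels, columns=labels)
        dend = hcluster(DistanceTable(frame, "cosine_delta"))
        meta = {lab: lab.split("_")[0] for lab in labels}
        rate, exceptions = same_user_leaf_pairing(dend, meta)
        assert rate == 1.0 and exceptions == []

    def test_chained_sample_counts_against_rate(self):
        # s2 merges into the (s0, s1) cluster -> no sibling -> exception
        labels = ["U1_a", "U1_b", "U2_a", "U3_a", "U3_b"]
        d = np.array(
            [
                [0.0, 0.1, 0.3, 0.9, 0.9],
                [0.1, 0.0, 0.35, 0.9, 0.9],
                [0.3, 0.35, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.9, 0.1, 0.0],
            ]
        )
        frame = pd.DataFrame(d, index=labels, columns=labels)
        dend = hcluster(DistanceTable(frame, "cosine_delta"), method="complete")
        meta = {lab: lab.split("_")[0] for lab in labels}
        rate, exceptions = same_user_leaf_pairing(dend, meta)
        assert "U2_a" in exceptions
        assert rate == pytest.approx(4 / 5)
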