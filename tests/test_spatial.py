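import numpy as np
import pandas as pd
import pytest

import cihkit as ck
from cihkit.errors import WeightsFormatError, ZeroVarianceError


def chain_weights(n=4):
    ids = [f"u{i}" for i in range(1, n + 1)]
    neighbors = {
        ids[i]: [ids[j] for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)
    }
    return ck.SpatialWeights(unit_ids=ids, neighbors=neighbors)


def brute_force_global(values, W):
    """Dense double-sum evaluation of Moran's I."""
    ids = W.unit_ids
    x = np.array([values[u] for u in ids], dtype=float)
    z = (x - x.mean()) / x.std()
    Wm = W.to_dense()
    n = len(ids)
    S0 = Wm.sum()
    num = sum(
        Wm[i, j] * z[i] * z[j] for i in range(n) for j in range(n)
    )
    return (n / S0) * num / (z @ z)


def brute_force_local(values, W):
    ids = W.unit_ids
    x = np.array([values[u] for u in ids], dtype=float)
    z = (x - x.mean()) / x.std()
    Wm = W.to_dense()
    n = len(ids)
    m2 = (z @ z) / n
    return [
        (z[i] / m2) * sum(Wm[i, j] * z[j] for j in range(n)) for i in range(n)
    ]


class TestWeights:
    def test_gal_round_trip_and_counts(self, tmp_path):
        path = tmp_path / "w.gal"
        path.write_text("0 4 synthetic unit\nu1 1\nu2\nu2 2\nu1 u3\nu3 2\nu2 u4\nu4 1\nu3\n")
        W = ck.read_gal(path)
        assert W.neighbor_counts() == {"u1": 1, "u2": 2, "u3": 2, "u4": 1}
        out = tmp_path / "o.gal"
        ck.write_gal(W, out)
        W2 = ck.read_gal(out)
        assert W2.neighbors == W.neighbors

    def test_row_standardization(self):
        W = chain_weights(4)
        Wm = W.to_dense()
        np.testing.assert_allclose(Wm.sum(axis=1), 1.0)
        assert Wm[1, 0] == Wm[1, 2] == 0.5

    def test_undeclared_neighbor_is_format_error(self, tmp_path):
        path = tmp_path / "w.gal"
        path.write_text("2\nu1 1\nu9\nu2 1\nu1\n")
        with pytest.raises(WeightsFormatError, match="u9"):
            ck.read_gal(path)

    def test_neighbor_count_mismatch(self, tmp_path):
        path = tmp_path / "w.gal"
        path.write_text("2\nu1 2\nu2\nu2 1\nu1\n")
        with pytest.raises(WeightsFormatError, match="declares 2"):
            ck.read_gal(path)

    def test_asymmetric_input_symmetrized_with_warning(self):
        with pytest.warns(UserWarning, match="symmetriz"):
            W = ck.SpatialWeights(
                unit_ids=["a", "b", "c"],
                neighbors={"a": ["b"], "b": [], "c": ["b"]},
            )
        assert "a" in W.neighbors["b"] and "c" in W.neighbors["b"]

    def test_edge_list_reader(self, tmp_path):
        path = tmp_path / "edges.csv"
        path.write_text("unit_a,unit_b\nu1,u2\nu2,u3\n")
        W = ck.read_edge_list(path)
        assert W.neighbor_counts() == {"u1": 1, "u2": 2, "u3": 1}

    def test_lattice_rook_counts_and_edges(self):
        W = ck.lattice_weights(4, 4, "rook")
        counts = W.neighbor_counts()
        assert counts["u1"] == 2  # corner
        assert W.n_edges() == 24  # 2*r*c - r - c

    def test_lattice_queen_2x2(self):
        W = ck.lattice_weights(2, 2, "queen")
        assert all(k == 3 for k in W.neighbor_counts().values())


class TestGlobalMoran:
    def test_constant_surface_rejected(self):
        W = chain_weights(4)
        values = pd.Series(1.0, index=W.unit_ids)
        with pytest.raises(ZeroVarianceError):
            ck.global_moran(values, W, n_permutations=0)

    def test_chain_hand_value(self):
        W = chain_weights(4)
        values = pd.Series([1.0, 1.0, -1.0, -1.0], index=W.unit_ids)
        res = ck.global_moran(values, W, n_permutations=0)
        assert res.I == pytest.approx(0.5)
        assert res.expected == pytest.approx(-1.0 / 3.0)

    def test_checkerboard_is_minus_one(self):
        W = ck.lattice_weights(4, 4, "rook")
        values = pd.Series(
            [1.0 if (i // 4 + i % 4) % 2 == 0 else -1.0 for i in range(16)],
            index=W.unit_ids,
        )
        res = ck.global_moran(values, W, n_permutations=0)
        assert res.I == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_brute_force_oracle(self, n, rng):
        W = chain_weights(n) if n % 2 else ck.lattice_weights(2, n // 2)
        values = pd.Series(rng.normal(size=n), index=W.unit_ids)
        res = ck.global_moran(values, W, n_permutations=0)
        assert res.I == pytest.approx(brute_force_global(values, W), abs=1e-12)

    def test_permutation_reproducibility(self, rng):
        W = ck.lattice_weights(3, 3)
        values = pd.Series(rng.normal(size=9), index=W.unit_ids)
        a = ck.global_moran(values, W, n_permutations=199, seed=7)
        b = ck.global_moran(values, W, n_permutations=199, seed=7)
        assert a.pseudo_p == b.pseudo_p
        assert 0 < a.pseudo_p <= 1

    def test_strong_cluster_is_significant(self):
        W = ck.lattice_weights(5, 5)
        values = pd.Series(
            [1.0 if i < 10 else -1.0 for i in range(25)], index=W.unit_ids
        )
        res = ck.global_moran(values, W, n_permutations=999, seed=3)
        assert res.I > 0.4
        assert res.pseudo_p < 0.05

    def test_islands_rejected_unless_allowed(self, rng):
        W = ck.SpatialWeights(
            unit_ids=["a", "b", "c", "d", "e"],
            neighbors={"a": ["b"], "b": ["a", "c"], "c": ["b"], "d": [], "e": []},
        )
        values = pd.Series(rng.normal(size=5), index=W.unit_ids)
        with pytest.raises(ValueError, match="island"):
            ck.global_moran(values, W)
        res = ck.global_moran(values, W, n_permutations=0, allow_islands=True)
        assert len(res.z_values) == 3


class TestLocalMoran:
    def test_additivity_mean_local_equals_global(self, rng):
        W = ck.lattice_weights(5, 4)
        values = pd.Series(rng.normal(size=20), index=W.unit_ids)
        glob = ck.global_moran(values, W, n_permutations=0)
        lisa = ck.local_moran(values, W, n_permutations=19, seed=0)
        assert lisa["local_I"].mean() == pytest.approx(glob.I, abs=1e-10)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_brute_force_oracle(self, n, rng):
        W = chain_weights(n)
        values = pd.Series(rng.normal(size=n), index=W.unit_ids)
        lisa = ck.local_moran(values, W, n_permutations=19, seed=1)
        np.testing.assert_allclose(
            lisa["local_I"], brute_force_local(values, W), atol=1e-12
        )

    def test_checkerboard_all_negative_local(self):
        W = ck.lattice_weights(8, 8)
        values = pd.Series(
            [1.0 if (i // 8 + i % 8) % 2 == 0 else -1.0 for i in range(64)],
            index=W.unit_ids,
        )
        lisa = ck.local_moran(values, W, n_permutations=999, seed=11)
        # every lag is exactly -z_i, so all local statistics are negative ...
        assert (lisa["local_I"] < 0).all()
        np.testing.assert_allclose(lisa["lag"], -values / values.std(ddof=0), atol=1e-12)
        # ... and any significant unit can only be a spatial outlier.  (With
        # two-valued data the conditional null puts sizable mass on |lag| = 1,
        # so few or no units clear alpha; none may be labeled HH or LL.)
        assert set(lisa.loc[lisa["label"] != "NS", "label"]) <= {"HL", "LH"}

    def test_quadrants_match_sign_pattern(self, rng):
        W = ck.lattice_weights(4, 4)
        values = pd.Series(rng.normal(size=16), index=W.unit_ids)
        lisa = ck.local_moran(values, W, n_permutations=19, seed=2)
        z = ck.global_moran(values, W, n_permutations=0).z_values
        for uid, row in lisa.iterrows():
            expected = ("H" if z[uid] > 0 else "L") + ("H" if row["lag"] > 0 else "L")
            assert row["quadrant"] == expected

    def test_seed_reproducibility(self, rng):
        W = ck.lattice_weights(4, 4)
        values = pd.Series(rng.normal(size=16), index=W.unit_ids)
        a = ck.local_moran(values, W, n_permutations=199, seed=9)
        b = ck.local_moran(values, W, n_permutations=199, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_island_labeled_ns_with_flag(self, rng):
        W = ck.SpatialWeights(
            unit_ids=["a", "b", "c", "d", "e"],
            neighbors={"a": ["b", "c"], "b": ["a", "c"], "c": ["a", "b"],
                       "d": [], "e": []},
        )
        values = pd.Series(rng.normal(size=5), index=W.unit_ids)
        lisa = ck.local_moran(values, W, n_permutations=19, seed=0,
                              allow_islands=True)
        assert lisa.loc["d", "island"] and lisa.loc["d", "label"] == "NS"


class TestClassification:
    def test_five_categories_and_colors(self):
        lisa = pd.DataFrame(
            {
                "pseudo_p": [0.01, 0.01, 0.01, 0.01, 0.5, np.nan],
                "quadrant": ["HH", "LL", "LH", "HL", "HH", "NS"],
                "island": [False] * 5 + [True],
            },
            index=list("abcdef"),
        )
        out = ck.classify_clusters(lisa, alpha=0.05)
        assert out["label"].tolist() == ["HH", "LL", "LH", "HL", "NS", "NS"]
        assert out["color"].tolist() == [
            "red", "blue", "light blue", "light red", "white", "white",
        ]
        assert set(ck.LISA_COLORS) == {"NS", "HH", "LL", "LH", "HL"}
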