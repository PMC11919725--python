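import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from decrypte.enrichment import (build_matrix, cluster_wpgma,
                                 combine_directions, correlation_distance,
                                 enrich_terms, linkage_to_newick,
                                 wpgma_linkage)
from decrypte.io import AnnotationMap


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct combinatorial summation (independent of scipy)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


def _ann(terms, universe):
    return AnnotationMap(terms={t: frozenset(m) for t, m in terms.items()},
                         universe=frozenset(universe))


class TestEnrichTerms:
    def test_worked_example_universe_20(self):
        universe = [f"P{i}" for i in range(20)]
        ann = _ann({"T": universe[:5]}, universe)
        query = set(universe[:3]) | {universe[10]}   # 3 of 5 term members
        rows = enrich_terms(query, ann, set(universe))
        expected = (math.comb(5, 3) * math.comb(15, 1)
                    + math.comb(5, 4) * math.comb(15, 0)) / math.comb(20, 4)
        assert rows.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.03199, abs=5e-6)

    def test_matches_exhaustive_tail_for_small_universes(self, rng):
        for trial in range(30):
            N = int(rng.integers(5, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"P{i}" for i in range(N)]
            term = set(rng.choice(universe, size=K, replace=False))
            query = set(rng.choice(universe, size=n, replace=False))
            rows = enrich_terms(query, _ann({"T": term}, universe),
                                set(universe))
            k = len(term & query)
            assert rows.loc[0, "p"] == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), abs=1e-10)

    def test_empty_query_returns_no_rows(self):
        universe = [f"P{i}" for i in range(10)]
        rows = enrich_terms(set(), _ann({"T": universe[:3]}, universe),
                            set(universe))
        assert rows.empty

    def test_disjoint_term_has_p_one(self):
        universe = [f"P{i}" for i in range(10)]
        rows = enrich_terms({"P8", "P9"}, _ann({"T": universe[:3]}, universe),
                            set(universe))
        assert rows.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_q_values_monotone_in_p_rank(self, rng):
        universe = [f"P{i}" for i in range(50)]
        terms = {f"T{j}": set(rng.choice(universe, size=8, replace=False))
                 for j in range(12)}
        query = set(rng.choice(universe, size=10, replace=False))
        rows = enrich_terms(query, _ann(terms, universe), set(universe))
        ordered = rows.sort_values("p")
        assert ordered["q"].is_monotonic_increasing

    def test_empty_background_raises(self):
        with pytest.raises(ValueError, match="background"):
            enrich_terms({"A"}, _ann({"T": {"A"}}, ["A"]), set())


class TestCombineDirections:
    def _rows(self, entries):
        return pd.DataFrame(entries, columns=["term_id", "q"])

    def test_more_significant_direction_wins(self):
        up = self._rows([("T1", 0.01)])
        down = self._rows([("T1", 0.2)])
        out = combine_directions(up, down)
        assert out.loc[0, "direction"] == 1
        assert out.loc[0, "q"] == 0.01
        assert out.loc[0, "score"] == pytest.approx(2.0)

    def test_term_only_in_down_kept_negative(self):
        out = combine_directions(self._rows([]), self._rows([("T2", 0.05)]))
        assert out.loc[0, "direction"] == -1
        assert out.loc[0, "score"] == pytest.approx(-np.log10(0.05) * -1)

    def test_exact_tie_goes_up(self):
        out = combine_directions(self._rows([("T", 0.1)]),
                                 self._rows([("T", 0.1)]))
        assert out.loc[0, "direction"] == 1


class TestBuildMatrix:
    def test_row_z_scores_standardized(self):
        cells = pd.DataFrame({
            "drug_id": ["D1", "D2", "D3"],
            "term_id": ["T"] * 3,
            "score": [1.0, 2.0, 3.0],
        })
        z, flagged = build_matrix(cells)
        np.testing.assert_allclose(z.loc["T"].to_numpy(), [-1.0, 0.0, 1.0])
        assert not flagged["T"]

    def test_constant_row_flagged_and_zeroed(self):
        cells = pd.DataFrame({
            "drug_id": ["D1", "D2"],
            "term_id": ["T", "T"],
            "score": [2.0, 2.0],
        })
        z, flagged = build_matrix(cells)
        np.testing.assert_allclose(z.loc["T"].to_numpy(), 0.0)
        assert flagged["T"]

    def test_finite_rows_have_zero_mean_unit_sd(self, rng):
        cells = pd.DataFrame({
            "drug_id": np.repeat([f"D{i}" for i in range(6)], 4),
            "term_id": np.tile([f"T{j}" for j in range(4)], 6),
            "score": rng.normal(0, 2, 24),
        })
        z, flagged = build_matrix(cells)
        assert np.all(np.abs(z.mean(axis=1)) < 1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0)

    def test_missing_drug_term_pairs_score_zero_before_z(self):
        cells = pd.DataFrame({
            "drug_id": ["D1", "D2", "D2"],
            "term_id": ["T1", "T1", "T2"],
            "score": [2.0, 4.0, 6.0],
        })
        z, _ = build_matrix(cells)
        # T2 row is (0, 6) before standardization -> z = (-0.707.., +0.707..)
        np.testing.assert_allclose(z.loc["T2"].to_numpy(),
                                   [-np.sqrt(0.5), np.sqrt(0.5)])


class TestWpgma:
    def test_hand_computed_toy_merge_heights(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=6: merge (A,B) at 2, then
        # d(AB,C) = (4+6)/2 = 5
        dist = np.array([[0.0, 2.0, 4.0],
                         [2.0, 0.0, 6.0],
                         [4.0, 6.0, 0.0]])
        Z = wpgma_linkage(dist)
        assert Z[0, 2] == pytest.approx(2.0)
        assert Z[1, 2] == pytest.approx(5.0)

    def test_duplicated_rows_merge_first_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0],
                          [1.0, 2.0, 3.0],
                          [3.0, -1.0, 0.5]],
                         index=list("abc"), columns=list("xyz"))
        res = cluster_wpgma(m)
        assert res.row_linkage[0, 2] == pytest.approx(0.0)
        assert {int(res.row_linkage[0, 0]),
                int(res.row_linkage[0, 1])} == {0, 1}

    def test_permuting_rows_preserves_merge_heights(self, rng):
        m = rng.normal(0, 1, (6, 5))
        Z1 = wpgma_linkage(correlation_distance(m))
        perm = rng.permutation(6)
        Z2 = wpgma_linkage(correlation_distance(m[perm]))
        np.testing.assert_allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]),
                                   atol=1e-12)

    def test_zero_variance_profile_gets_max_distance(self):
        m = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        d = correlation_distance(m)
        assert d[0, 1] == 2.0 and d[0, 2] == 2.0
        assert d[1, 2] == pytest.approx(2.0)  # perfectly anticorrelated

    def test_newick_output_parses_with_expected_leaves(self):
        import io as _io

        from Bio import Phylo

        m = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)),
                         index=["t1", "t2", "t3", "t4"])
        res = cluster_wpgma(m)
        nwk = linkage_to_newick(res.row_linkage, m.index)
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        leaves = sorted(term.name for term in tree.get_terminals())
        assert leaves == ["t1", "t2", "t3", "t4"]


class TestPlantedSignalRecovery:
    def test_drugs_sharing_planted_term_cluster_together(self, rng):
        """Two drugs with the same strong enrichment profile end closer to
        each other than the matrix-wide typical distance."""
        drugs = [f"D{i}" for i in range(6)]
        terms = [f"T{j}" for j in range(10)]
        rows = []
        for d_i, drug in enumerate(drugs):
            for t_j, term in enumerate(terms):
                score = rng.normal(0, 0.5)
                if drug in ("D0", "D1") and t_j < 3:
                    score += 6.0          # shared planted signature
                rows.append((drug, term, score))
        cells = pd.DataFrame(rows, columns=["drug_id", "term_id", "score"])
        z, _ = build_matrix(cells)
        d = correlation_distance(z.to_numpy().T)
        drug_idx = {d_: i for i, d_ in enumerate(z.columns)}
        pair = d[drug_idx["D0"], drug_idx["D1"]]
        upper = d[np.triu_indices_from(d, k=1)]
        assert pair < np.median(upper)
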