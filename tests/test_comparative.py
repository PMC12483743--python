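"""Alignment, consensus conventions, distances and NJ/bootstrap trees."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cathmine.core_io import CathmineError
from cathmine.comparative import (
    DistanceMatrix,
    Msa,
    PhyloTree,
    TreeNode,
    align_msa,
    bootstrap,
    consensus_profile,
    dominance_summary,
    kimura_protein_distance,
    needleman_wunsch,
    nj_tree,
    percent_identity,
    protein_distance,
)
from cathmine.locus_search import load_matrix

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_global_affine(a, b, matrix="BLOSUM62", gap_open=11.0, gap_extend=1.0):
    """Independent memoized recursion for the optimal global affine score."""
    alphabet, S = load_matrix(matrix)
    idx = {c: i for i, c in enumerate(alphabet)}
    from functools import lru_cache

    NEG = -math.inf

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        if i == 0 and j == 0:
            return 0.0 if state == "M" else NEG
        best = NEG
        if state == "M":
            if i > 0 and j > 0:
                s = S[idx[a[i - 1]], idx[b[j - 1]]]
                best = max(rec(i - 1, j - 1, p) for p in "MEF") + s
        elif state == "E":
            if j > 0:
                best = max(
                    rec(i, j - 1, "M") - gap_open,
                    rec(i, j - 1, "E") - gap_extend,
                    rec(i, j - 1, "F") - gap_open,
                )
        else:
            if i > 0:
                best = max(
                    rec(i - 1, j, "M") - gap_open,
                    rec(i - 1, j, "F") - gap_extend,
                    rec(i - 1, j, "E") - gap_open,
                )
        return best

    return max(rec(len(a), len(b), s) for s in "MEF")


class TestNeedlemanWunsch:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=st.text(alphabet=AA, min_size=1, max_size=12),
        b=st.text(alphabet=AA, min_size=1, max_size=12),
    )
    def test_matches_brute_force(self, a, b):
        score, ga, gb = needleman_wunsch(a, b)
        assert score == pytest.approx(brute_force_global_affine(a, b))
        assert ga.replace("-", "") == a and gb.replace("-", "") == b
        assert len(ga) == len(gb)


class TestAlignMsa:
    def test_identical_sequences_gap_free(self):
        msa = align_msa([("a", "MKVLW"), ("b", "MKVLW"), ("c", "MKVLW")])
        assert all("-" not in s for _, s in msa.rows)
        assert msa.ncols == 5

    def test_degapping_recovers_inputs(self):
        seqs = [("a", "MKVLWE"), ("b", "MKVWE"), ("c", "MKVLWEE")]
        msa = align_msa(seqs)
        by_id = dict(seqs)
        for i, (sid, _) in enumerate(msa.rows):
            assert msa.degapped(i) == by_id[sid]

    def test_single_insertion_gives_one_gap_column(self):
        base = "MKVLWAGHE"
        ins = base[:4] + "R" + base[4:]
        msa = align_msa([("a", base), ("b", ins), ("c", base)])
        gap_cols = [
            j for j in range(msa.ncols) if any(s[j] == "-" for _, s in msa.rows)
        ]
        assert len(gap_cols) == 1

    def test_pairwise_case_equals_global_score(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        score, ga, gb = needleman_wunsch(a, b)
        msa = align_msa([("a", a), ("b", b)])
        assert (msa.rows[0][1], msa.rows[1][1]) == (ga, gb)

    def test_empty_sequence_rejected(self):
        with pytest.raises(CathmineError):
            align_msa([("a", "MK"), ("b", "")])


class TestPercentIdentity:
    def test_paper_printed_values(self):
        # 646 columns, 5 differences -> 99.23; 137 columns, 133 identical -> 97.08
        a = "A" * 641 + "CCCCC"
        b = "A" * 641 + "GGGGG"
        assert percent_identity(a, b) == 99.23
        assert percent_identity("A" * 133 + "CCCC", "A" * 133 + "GGGG") == 97.08

    def test_identity_and_symmetry(self):
        assert percent_identity("MKVL", "MKVL") == 100.00
        a, b = "MKVLWAG", "MKVAWAG"
        assert percent_identity(a, b) == percent_identity(b, a)
        assert percent_identity(a, b) < 100.0

    def test_gap_columns_count_as_mismatch(self):
        assert percent_identity("MK-L", "MKVL") == 75.0
        assert percent_identity("M--L", "M--L") == 50.0  # shared gaps not identity

    def test_length_mismatch_rejected(self):
        with pytest.raises(CathmineError):
            percent_identity("MK", "MKV")


class TestConsensus:
    def test_display_conventions(self):
        msa = Msa(
            rows=[
                ("1", "KA-GA"),
                ("2", "KA-GC"),
                ("3", "KG-SA"),
                ("4", "KGAS-"),
                ("5", "KA-TT"),
            ]
        )
        prof = consensus_profile(msa)
        # col1 unanimous K; col2 modal a (3/5); col3 dominant gap;
        # col4 tie G/S -> '+'; col5 tie a/c/t... also '+'
        assert prof.consensus[0] == "K" and prof.dominance[0] == 1.0
        assert prof.consensus[1] == "a" and prof.dominance[1] == 0.6
        assert prof.consensus[2] == "-"
        assert prof.consensus[3] == "+"

    def test_uppercase_count_equals_unanimous_columns(self):
        rows = [("a", "MKVLWGH"), ("b", "MKVAWGH"), ("c", "MKVLWSH")]
        msa = Msa(rows=rows)
        prof = consensus_profile(msa)
        unanimous = sum(
            len(set(msa.column(j))) == 1 and msa.column(j)[0] != "-"
            for j in range(msa.ncols)
        )
        assert sum(c.isupper() for c in prof.consensus) == unanimous

    def test_dominance_summary_bounds(self):
        msa = Msa(rows=[("a", "MKV"), ("b", "MKA"), ("c", "MKV")])
        prof = consensus_profile(msa)
        assert dominance_summary(prof, 0.0) == prof.ncols
        assert dominance_summary(prof, 1.0) == 2  # M and K unanimous

    def test_constructed_102_column_profile(self):
        # 82 of 102 columns at dominance >= 0.6 (5 rows: 3/5 = 0.6)
        rows = ["", "", "", "", ""]
        for j in range(102):
            if j < 82:
                col = "KKKAG"  # dominance 0.6
            else:
                col = "KARGD"  # dominance 0.2... plus ties -> below 0.6
            for i in range(5):
                rows[i] += col[i]
        msa = Msa(rows=[(f"s{i}", r) for i, r in enumerate(rows)])
        prof = consensus_profile(msa)
        assert prof.ncols == 102
        assert dominance_summary(prof, 0.6) == 82


class TestDistances:
    def test_kimura_formula(self):
        assert kimura_protein_distance(0.0) == 0.0
        p = 0.2
        assert kimura_protein_distance(p) == pytest.approx(
            -math.log(1 - p - 0.2 * p * p), abs=1e-12
        )
        # monotone in p
        ps = [0.05 * k for k in range(0, 15)]
        ds = [kimura_protein_distance(p) for p in ps]
        assert ds == sorted(ds)

    def test_two_sequence_hand_computation(self):
        # 10 columns, 2 differences -> p = 0.2
        msa = Msa(rows=[("a", "MKVLWAGHEE"), ("b", "MKVLWAGHRR")])
        d = protein_distance(msa)
        assert d.get("a", "b") == pytest.approx(
            -math.log(1 - 0.2 - 0.2 * 0.04), abs=1e-12
        )

    def test_identical_rows_zero(self):
        msa = Msa(rows=[("a", "MKVL"), ("b", "MKVL"), ("c", "MKVL")])
        d = protein_distance(msa)
        assert np.all(d.matrix == 0)

    def test_gap_columns_excluded_pairwise(self):
        msa = Msa(rows=[("a", "MK-L"), ("b", "MKVL")])
        assert protein_distance(msa).get("a", "b") == 0.0

    def test_all_gap_pair_rejected(self):
        msa = Msa(rows=[("a", "--AA"), ("b", "KK--")])
        with pytest.raises(CathmineError):
            protein_distance(msa)


def _additive_matrix(tree_paths, ids):
    n = len(ids)
    m = np.zeros((n, n))
    for (a, b), d in tree_paths.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=ids, matrix=m)


class TestNeighborJoining:
    def test_additive_four_taxa_exact(self):
        # generating tree: ((A:2,B:3):1,C:4,D:5) — internal edge length 1
        ids = ["A", "B", "C", "D"]
        paths = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
        }
        dist = _additive_matrix(paths, ids)
        tree = nj_tree(dist)
        pl = tree.path_lengths()
        for (a, b), d in paths.items():
            assert pl[frozenset((a, b))] == pytest.approx(d, abs=1e-9)
        # topology: A+B vs C+D split present
        assert frozenset("AB") in tree.bipartitions()

    def test_additive_five_taxa_exact(self):
        # caterpillar: ((A:1,B:2):1,(C:1,(D:2,E:3):1):1) with unit inner edges
        ids = ["A", "B", "C", "D", "E"]
        paths = {
            ("A", "B"): 3,
            ("A", "C"): 4, ("B", "C"): 5,
            ("A", "D"): 6, ("B", "D"): 7, ("C", "D"): 4,
            ("A", "E"): 7, ("B", "E"): 8, ("C", "E"): 5, ("D", "E"): 5,
        }
        dist = _additive_matrix(paths, ids)
        tree = nj_tree(dist)
        pl = tree.path_lengths()
        for (a, b), d in paths.items():
            assert pl[frozenset((a, b))] == pytest.approx(d, abs=1e-9)
        bip = tree.bipartitions()
        assert frozenset("AB") in bip and frozenset("DE") in bip

    def test_three_taxa_unique_topology_full_support(self):
        msa = Msa(rows=[("a", "MKVLWAGH"), ("b", "MKVLWAGR"), ("c", "MKVLFSGR")])
        tree = bootstrap(msa, n_reps=10, seed=1)
        assert sorted(tree.leaf_names) == ["a", "b", "c"]
        # 3 taxa: no non-trivial splits, a single trifurcating root
        assert tree.bipartitions() == {}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(CathmineError):
            nj_tree(DistanceMatrix(ids=["a", "b"], matrix=np.zeros((2, 2))))

    def test_newick_serializable(self):
        ids = ["A", "B", "C", "D"]
        paths = {
            ("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9,
        }
        nwk = nj_tree(_additive_matrix(paths, ids)).to_newick()
        assert nwk.endswith(";") and all(x in nwk for x in ids)
        import dendropy

        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in t.leaf_node_iter()} == set(ids)


def _two_clade_msa(rng, n_per_clade=4, ncols=60, diverged=12):
    base1 = "".join(rng.choice(list(AA), size=ncols))
    base2 = list(base1)
    for j in rng.choice(ncols, size=diverged, replace=False):
        base2[j] = rng.choice([c for c in AA if c != base1[j]])
    rows = []
    for k in range(n_per_clade):
        for name, base in (("x", base1), ("y", "".join(base2))):
            s = list(base)
            j = int(rng.integers(ncols))
            s[j] = rng.choice(list(AA))
            rows.append((f"{name}{k}", "".join(s)))
    return Msa(rows=rows)


class TestBootstrap:
    def test_two_clade_support(self):
        rng = np.random.default_rng(42)
        msa = _two_clade_msa(rng)
        tree = bootstrap(msa, n_reps=100, seed=7)
        bip = tree.bipartitions()
        clade_x = frozenset(n for n in tree.leaf_names if n.startswith("x"))
        all_leaves = frozenset(tree.leaf_names)
        key = min(clade_x, all_leaves - clade_x, key=lambda s: (len(s), sorted(s)))
        assert key in bip
        assert bip[key].support >= 0.95

    def test_identity_resample_gives_binary_supports(self):
        rng = np.random.default_rng(1)
        msa = _two_clade_msa(rng, n_per_clade=3, ncols=30)
        tree = bootstrap(msa, n_reps=1, seed=0, resample="identity")
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and set(supports) <= {0.0, 1.0}
        assert all(s == 1.0 for s in supports)

    def test_bad_reps_rejected(self):
        msa = Msa(rows=[("a", "MKV"), ("b", "MKA"), ("c", "MRA")])
        with pytest.raises(CathmineError):
            bootstrap(msa, n_reps=0, seed=0)
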