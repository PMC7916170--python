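"""Progressive alignment, supermatrix assembly, corrected distances,
neighbor-joining (vs scikit-bio and additivity oracles), bootstrap, and
clade extraction."""

import numpy as np
import pytest

from nudimine.msa import (
    GAP,
    MultipleAlignment,
    align_gene,
    build_supermatrix,
    distance_matrix,
)
from nudimine.records import SequenceRecord
from nudimine.tree import PhyloTree, bootstrap_support, extract_clades, nj_tree

import pandas as pd

from conftest import random_protein
from oracles import nw_global_score
from nudimine.align import ALPHABET, scoring_matrix

MATRIX = scoring_matrix("BLOSUM62")
IDX = {ch: i for i, ch in enumerate(ALPHABET)}


def _lookup(x, y):
    return float(MATRIX[IDX.get(x, 20), IDX.get(y, 20)])


def _mutate(rng, seq, rate):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return seq[0] + "".join(
        aas[int(rng.integers(20))] if rng.random() < rate else c
        for c in seq[1:]
    )


class TestAlignGene:
    def test_identical_pair_gap_free(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        aln = align_gene([SequenceRecord("a", seq, alphabet="protein"),
                          SequenceRecord("b", seq, alphabet="protein")])
        assert aln.rows == [seq, seq]

    def test_ungapping_recovers_inputs(self, rng):
        seqs = {}
        base = random_protein(rng, 120)
        for name in "abcde":
            mutated = _mutate(rng, base, 0.3)
            if rng.random() < 0.5:  # also vary lengths
                cut = int(rng.integers(0, 20))
                mutated = mutated[: len(mutated) - cut]
            seqs[name] = mutated
        aln = align_gene([SequenceRecord(n, s, alphabet="protein")
                          for n, s in sorted(seqs.items())])
        for name, seq in seqs.items():
            assert aln.ungapped(name) == seq

    def test_pairwise_score_matches_global_dp_oracle(self, rng):
        from nudimine.msa import _nw_profile, _profile

        for _ in range(10):
            a = random_protein(rng, int(rng.integers(10, 40)))
            b = random_protein(rng, int(rng.integers(10, 40)))
            path_a, path_b = _nw_profile(_profile([a]), _profile([b]), -8.0)
            score = sum(
                _lookup(a[i], b[j]) if i >= 0 and j >= 0 else -8.0
                for i, j in zip(path_a, path_b)
            )
            assert score == nw_global_score(a, b, _lookup, -8.0)

    def test_single_sequence_trivial(self):
        aln = align_gene([SequenceRecord("a", "MKT", alphabet="protein")])
        assert aln.rows == ["MKT"]

    def test_deterministic(self, rng):
        base = random_protein(rng, 80)
        recs = [SequenceRecord(n, _mutate(np.random.default_rng(i), base, 0.2),
                               alphabet="protein")
                for i, n in enumerate("abcd")]
        assert align_gene(recs) == align_gene(recs)


class TestSupermatrix:
    def _aln(self, ids, length, seed=0):
        rng = np.random.default_rng(seed)
        return MultipleAlignment(
            list(ids), [random_protein(rng, length) for _ in ids]
        )

    def test_columns_and_partitions(self):
        sm = build_supermatrix(
            {"g1": self._aln("ab", 120), "g2": self._aln("ab", 80)}, ["a", "b"]
        )
        assert sm.n_columns == 200
        assert [g for g, _ in sm.partitions] == ["g1", "g2"]
        assert all(len(sm.rows[t]) == 200 for t in "ab")

    def test_missing_taxon_gap_filled(self):
        sm = build_supermatrix(
            {"g1": self._aln("ab", 50), "g2": self._aln("a", 30)},
            ["a", "b"],
        )
        start, end = dict(sm.partitions)["g2"]
        assert sm.rows["b"][start:end] == GAP * 30
        assert sm.missing["b"] == {"g2"}

    def test_duplicate_taxon_rejected(self):
        aln = MultipleAlignment(["a", "a"], ["MKT", "MKT"])
        with pytest.raises(ValueError, match="duplicate"):
            build_supermatrix({"g": aln}, ["a"])

    def test_mimics_patchy_multi_taxon_design(self, rng):
        """An 18-taxon, 31-gene design with planted missing genes builds and
        masks exactly those genes (the endogenous-virus situation)."""
        taxa = [f"t{i:02d}" for i in range(18)]
        planted_missing = {("t13", "g002"), ("t14", "g007"), ("t15", "g000"),
                           ("t16", "g020"), ("t17", "g030")}
        alignments = {}
        for gi in range(31):
            gene = f"g{gi:03d}"
            members = [t for t in taxa if (t, gene) not in planted_missing]
            alignments[gene] = self._aln(members, 40, seed=gi)
        sm = build_supermatrix(alignments, taxa)
        observed = {(t, g) for t, gs in sm.missing.items() for g in gs}
        assert observed == planted_missing


class TestDistances:
    def test_identical_rows_zero(self):
        sm = build_supermatrix(
            {"g": MultipleAlignment(["a", "b", "c"], ["MKTA" * 30] * 3)},
            ["a", "b", "c"],
        )
        D = distance_matrix(sm)
        assert np.allclose(D.values, 0.0)

    def test_monotone_in_p(self):
        f = lambda p: -np.log(1 - p - 0.2 * p * p)
        ps = np.linspace(0.0, 0.7, 30)
        ds = [f(p) for p in ps]
        assert ds[0] == 0.0
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_recovers_simulated_substitution_rate(self, rng):
        """Corrected distance within 10% of the true expected number of
        substitutions per site at 2000 columns."""
        L, d_true = 2000, 0.4
        aas = "ACDEFGHIKLMNPQRSTVWY"
        root = "".join(aas[int(rng.integers(20))] for _ in range(L))
        # Poisson(d) substitution events per site, each to a uniform other aa
        evolved = list(root)
        for i in range(L):
            for _ in range(rng.poisson(d_true)):
                evolved[i] = aas[int(rng.integers(20))]
        rows = [root, "".join(evolved), root]  # third taxon to satisfy >= 3
        sm = build_supermatrix(
            {"g": MultipleAlignment(["a", "b", "c"], rows)}, ["a", "b", "c"]
        )
        est = distance_matrix(sm).at["a", "b"]
        # events landing on the same amino acid are invisible: correct for
        # the 1/20 chance a substitution reproduces the original state
        d_effective = d_true * 19 / 20
        assert abs(est - d_effective) / d_effective < 0.10

    def test_incomparable_pair_raises(self):
        rows = {"a": "MK--", "b": "--TA", "c": "MKTA"}
        sm = build_supermatrix(
            {"g": MultipleAlignment(list("abc"), [rows[t] for t in "abc"])},
            list("abc"),
        )
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix(sm)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(D)
        # edge lengths: a = (5+9-10)/2 = 2, b = 3, c = 7
        lengths = {}
        for leaf_id, name in tree.leaf_names.items():
            [(_, L)] = tree.adjacency[leaf_id].items()
            lengths[name] = L
        assert lengths == {"a": 2.0, "b": 3.0, "c": 7.0}

    def test_additive_matrix_recovered_exactly(self, rng):
        """Distances generated on a known 6-taxon tree are additive; NJ must
        recover the exact topology and branch lengths."""
        # tree: ((a:2,b:3):1,(c:1,d:4):2,(e:2,f:5));
        paths = {
            "a": {"x": 2}, "b": {"x": 3}, "c": {"y": 1}, "d": {"y": 4},
            "e": {"z": 2}, "f": {"z": 5},
        }
        internal = {("x", "y"): 3, ("x", "z"): 4, ("y", "z"): 3}
        taxa = list("abcdef")

        def dist(u, v):
            (hu, du), (hv, dv) = list(paths[u].items())[0], list(paths[v].items())[0]
            if hu == hv:
                return du + dv
            return du + dv + internal[tuple(sorted((hu, hv)))]

        D = pd.DataFrame(
            [[0 if u == v else dist(u, v) for v in taxa] for u in taxa],
            index=taxa, columns=taxa, dtype=float,
        )
        tree = nj_tree(D)
        expected_splits = {
            frozenset({"a", "b"}), frozenset({"c", "d"}), frozenset({"e", "f"}),
        }
        got = {s if "a" not in s else frozenset(taxa) - s
               for s in tree.bipartitions()}
        normalized = set()
        for s in got:
            normalized.add(s if len(s) <= 3 else frozenset(taxa) - s)
        assert expected_splits <= {frozenset(x) for x in normalized} | got
        # leaf branch lengths recovered exactly
        leaf_len = {tree.leaf_names[i]: list(tree.adjacency[i].values())[0]
                    for i in tree.leaf_names}
        assert leaf_len == {"a": 2, "b": 3, "c": 1, "d": 4, "e": 2, "f": 5}

    def test_agrees_with_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as sk_nj

        taxa = [f"t{i}" for i in range(7)]
        base = rng.random((7, 7)) * 5
        M = (base + base.T) / 2
        np.fill_diagonal(M, 0.0)
        mine = nj_tree(pd.DataFrame(M, index=taxa, columns=taxa))
        theirs = sk_nj(DistanceMatrix(M, ids=taxa))
        their_splits = set()
        for node in theirs.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 1 < len(names) < len(taxa) - 1:
                ref = min(taxa)
                if ref in names:
                    names = frozenset(taxa) - names
                their_splits.add(names)
        assert mine.bipartitions() == their_splits

    def test_non_symmetric_rejected(self):
        D = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(D)


def _two_clade_supermatrix(rng, n_per=4, L=400, within=0.05, stem=0.25):
    """Two well-separated clades radiating from a common root, plus a long
    independent outgroup branch."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    root = "".join(aas[int(rng.integers(20))] for _ in range(L))
    anc_a = _mutate(rng, root, stem)
    anc_b = _mutate(rng, root, stem)
    rows, taxa = [], []
    for label, anc in (("A", anc_a), ("B", anc_b)):
        for i in range(n_per):
            taxa.append(f"{label}{i}")
            rows.append(_mutate(rng, anc, within))
    taxa.append("out")
    rows.append(_mutate(rng, root, 0.5))
    sm = build_supermatrix(
        {"g": MultipleAlignment(taxa, rows)}, taxa
    )
    groups = {
        "cladeA": {t for t in taxa if t.startswith("A")},
        "cladeB": {t for t in taxa if t.startswith("B")},
    }
    return sm, groups


class TestBootstrapAndClades:
    def test_deterministic_for_seed(self, rng):
        sm, _ = _two_clade_supermatrix(rng)
        a = bootstrap_support(sm, n_reps=20, seed=7)
        b = bootstrap_support(sm, n_reps=20, seed=7)
        assert a.supports == b.supports
        assert a.newick() == b.newick()

    def test_single_replicate_supports_binary(self, rng):
        sm, _ = _two_clade_supermatrix(rng)
        tree = bootstrap_support(sm, n_reps=1, seed=3)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_well_separated_clades_highly_supported(self, rng):
        sm, groups = _two_clade_supermatrix(rng)
        tree = bootstrap_support(sm, n_reps=100, seed=11)
        report = extract_clades(tree, "out", groups)
        for name, clade in report.items():
            assert clade.monophyletic, name
            assert clade.support is not None and clade.support >= 95

    def test_shuffled_labels_not_monophyletic(self, rng):
        sm, groups = _two_clade_supermatrix(rng)
        tree = bootstrap_support(sm, n_reps=10, seed=1)
        mixed = {"mix": {"A0", "B0", "A1"}}
        report = extract_clades(tree, "out", mixed)
        assert not report["mix"].monophyletic

    def test_single_taxon_group_trivially_monophyletic(self, rng):
        sm, _ = _two_clade_supermatrix(rng)
        tree = bootstrap_support(sm, n_reps=10, seed=2)
        report = extract_clades(tree, "out", {"solo": {"A0"}})
        assert report["solo"].monophyletic

    def test_missing_outgroup_rejected(self, rng):
        sm, groups = _two_clade_supermatrix(rng)
        tree = nj_tree(distance_matrix(sm))
        with pytest.raises(ValueError):
            extract_clades(tree, "nope", groups)

    def test_supports_invariant_to_taxon_order(self, rng):
        sm, _ = _two_clade_supermatrix(rng, n_per=3, L=200)
        perm = list(np.random.default_rng(0).permutation(sm.taxa))
        sm2 = type(sm)(perm, {t: sm.rows[t] for t in perm}, sm.partitions)
        a = bootstrap_support(sm, n_reps=30, seed=5)
        b = bootstrap_support(sm2, n_reps=30, seed=5)
        assert set(a.bipartitions()) == set(b.bipartitions())
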