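"""Site classification, minimum changes, Fitch parsimony and CI."""

import numpy as np
import pytest

from orthoprimer import (
    Alignment,
    QualityMask,
    classify_sites,
    exhaustive_parsimony,
    fitch_score,
    min_changes,
    parse_newick,
    same_topology,
    strain_polymorphism,
    to_newick,
    tree_splits,
)
from orthoprimer.alnstats import count_classes, enumerate_topologies
from orthoprimer.errors import AlignmentError, SizeError

from .oracles import fitch_enumerate, min_changes_recount


def _aln(*rows, names=None, kind="dna"):
    names = names or [f"t{i}" for i in range(len(rows))]
    return Alignment(names=names, rows=list(rows), kind=kind)


class TestClassifySites:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", "constant"),
            ("AAAT", "variable_uninformative"),
            ("AATT", "parsimony_informative"),
            ("A-T-", "variable_uninformative"),  # gaps are missing data
            ("AAT-", "variable_uninformative"),
            ("A---", "constant"),  # fewer than two observed cells
        ],
    )
    def test_single_column_classification(self, column, expected):
        aln = _aln(*[c for c in column])
        assert classify_sites(aln)[0].category == expected

    def test_counts_invariant_under_row_permutation_and_bounded(self, rng):
        rows = ["".join("ACGT-"[k] for k in rng.integers(5, size=60)) for _ in range(6)]
        aln = _aln(*rows)
        c1 = count_classes(classify_sites(aln))
        perm = rng.permutation(6)
        aln2 = Alignment(
            names=[aln.names[i] for i in perm],
            rows=[aln.rows[i] for i in perm],
            kind="dna",
        )
        assert count_classes(classify_sites(aln2)) == c1
        variable = c1["variable_uninformative"] + c1["parsimony_informative"]
        assert c1["parsimony_informative"] <= variable

    def test_masked_cells_are_missing(self):
        aln = _aln("AATT", "AATT", "TTAA", "TTAA")
        # mask the whole last row: informative columns become singletons? no —
        # each column still has two As and one T (or the reverse)
        trusted = [np.ones(4, bool)] * 3 + [np.zeros(4, bool)]
        mask = QualityMask(names=aln.names, trusted=trusted)
        classes = classify_sites(aln, mask)
        assert {c.category for c in classes} == {"variable_uninformative"}


class TestMinChanges:
    def test_three_states_need_two_changes(self):
        per_col, total = min_changes(_aln("A", "A", "T", "G"))
        assert per_col == [2] and total == 2

    def test_constant_alignment_needs_none(self):
        assert min_changes(_aln("AAAA", "AAAA"))[1] == 0

    def test_matches_independent_recount(self, rng):
        rows = ["".join("ACGT-"[k] for k in rng.integers(5, size=200)) for _ in range(6)]
        aln = _aln(*rows)
        columns = [
            [None if c in "-N" else c for c in aln.column(j)]
            for j in range(aln.length)
        ]
        assert min_changes(aln)[1] == min_changes_recount(columns)


class TestFitch:
    def test_single_transition_on_matching_tree(self):
        aln = _aln("A", "A", "T", "T", names=["a1", "a2", "t1", "t2"])
        res = fitch_score((("a1", "a2"), ("t1", "t2")), aln)
        assert res.total_changes == 1

    def test_conflicting_column_needs_two_changes(self):
        aln = _aln("A", "T", "A", "T", names=["a1", "t1", "a2", "t2"])
        res = fitch_score((("a1", "t1"), ("a2", "t2")), aln)
        assert res.total_changes == 2
        assert res.total_changes == fitch_enumerate(
            (("a1", "t1"), ("a2", "t2")),
            {"a1": "A", "t1": "T", "a2": "A", "t2": "T"},
        )

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        """Fitch equals brute-force enumeration of internal labelings on
        random <=6-taxon, <=30-site instances with missing data."""
        for rep in range(12):
            n = int(rng.integers(4, 7))
            L = int(rng.integers(5, 31))
            names = [f"t{i}" for i in range(n)]
            rows = [
                "".join("ACGT-"[k] for k in rng.integers(5, size=L)) for _ in range(n)
            ]
            aln = _aln(*rows, names=names)
            topologies = list(enumerate_topologies(names))
            tree = topologies[int(rng.integers(len(topologies)))]
            res = fitch_score(tree, aln)
            expected = sum(
                fitch_enumerate(
                    tree,
                    {nm: (None if c in "-N" else c)
                     for nm, c in zip(names, aln.column(j))},
                )
                for j in range(L)
            )
            assert res.total_changes == expected

    def test_score_never_below_min_changes_and_ci_one_iff_equal(self, rng):
        for _ in range(10):
            n = 6
            names = [f"t{i}" for i in range(n)]
            rows = ["".join("ACGT"[k] for k in rng.integers(4, size=40)) for _ in range(n)]
            aln = _aln(*rows, names=names)
            tree = parse_newick("(((t0,t1),(t2,t3)),(t4,t5));")
            res = fitch_score(tree, aln)
            assert res.total_changes >= res.min_possible
            assert (res.ci == 1.0) == (res.total_changes == res.min_possible)

    def test_homoplasy_free_alignment_has_ci_one(self):
        aln = _aln("AAG", "AAG", "ATC", "ATC", names=["a", "b", "c", "d"])
        res = fitch_score((("a", "b"), ("c", "d")), aln)
        assert res.ci == 1.0 and res.total_changes == res.min_possible == 2

    def test_leaf_mismatch_rejected(self):
        aln = _aln("A", "A", names=["x", "y"])
        with pytest.raises(AlignmentError):
            fitch_score(("x", "z"), aln)

    def test_rooting_invariance(self, rng):
        names = [f"t{i}" for i in range(5)]
        rows = ["".join("ACGT"[k] for k in rng.integers(4, size=30)) for _ in range(5)]
        aln = _aln(*rows, names=names)
        a = fitch_score(parse_newick("((t0,t1),(t2,(t3,t4)));"), aln)
        b = fitch_score(parse_newick("(t3,(t4,(t2,(t0,t1))));"), aln)
        assert a.total_changes == b.total_changes


class TestExhaustiveParsimony:
    def test_four_taxon_informative_data_recovers_pairing(self):
        aln = _aln("AAAA", "AAAA", "TTTT", "TTTT", names=list("abcd"))
        best, score = exhaustive_parsimony(aln)
        assert score == 4 and len(best) == 1
        assert same_topology(best[0], (("a", "b"), ("c", "d")))

    def test_identical_rows_tie_all_topologies_at_zero(self):
        aln = _aln("ACGT", "ACGT", "ACGT", "ACGT", names=list("abcd"))
        best, score = exhaustive_parsimony(aln)
        assert score == 0 and len(best) == 3  # all unrooted 4-taxon topologies

    def test_topology_count_is_double_factorial(self):
        assert sum(1 for _ in enumerate_topologies(list("abcde"))) == 15
        assert sum(1 for _ in enumerate_topologies(list("abcdef"))) == 105

    def test_taxon_cap_enforced(self, rng):
        rows = ["A" * 5] * 10
        aln = Alignment(names=[f"t{i}" for i in range(10)], rows=rows, kind="dna")
        with pytest.raises(SizeError):
            exhaustive_parsimony(aln)

    def test_exhaustive_score_equals_direct_fitch_on_winner(self, rng):
        names = [f"t{i}" for i in range(5)]
        rows = ["".join("ACGT"[k] for k in rng.integers(4, size=40)) for _ in range(5)]
        aln = _aln(*rows, names=names)
        best, score = exhaustive_parsimony(aln)
        assert score == fitch_score(best[0], aln).total_changes

    def test_recovers_generating_six_taxon_topology(self):
        from orthoprimer import evolve_on_tree

        truth = parse_newick("(((t1,t2),(t3,t4)),(t5,t6));")
        aln = evolve_on_tree(truth, length=300, subst_prob=0.08, seed=99)
        best, _ = exhaustive_parsimony(aln)
        assert len(best) == 1 and same_topology(best[0], truth)


class TestStrainPolymorphism:
    def test_planted_snps_counted_exactly(self, strain_case):
        panel = strain_case
        n_sites, n_var = strain_polymorphism(panel.aln, panel.mask)
        assert n_sites == 600
        assert n_var == len(panel.truth.visible_variable)
        assert n_var == len(panel.truth.snp_positions)  # all visible here

    def test_snp_visible_only_below_q40_not_counted(self):
        aln = _aln("AAAA", "AAAA", "AATA", names=["s1", "s2", "s3"])
        trusted = [np.ones(4, bool), np.ones(4, bool),
                   np.array([True, True, False, True])]
        mask = QualityMask(names=aln.names, trusted=trusted)
        assert strain_polymorphism(aln, mask) == (4, 0)
        assert strain_polymorphism(aln, None) == (4, 1)

    def test_identical_strains_have_no_variation(self):
        assert strain_polymorphism(_aln("ACGT", "ACGT", "ACGT"))[1] == 0


def test_newick_roundtrip_preserves_topology():
    t = parse_newick("(((t1,t2),(t3,t4)),(t5,t6));")
    assert same_topology(parse_newick(to_newick(t)), t)
    assert len(tree_splits(t)) == 3
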