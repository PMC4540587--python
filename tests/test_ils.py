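import numpy as np
import pandas as pd
import pytest

from retroils import (
    Tree,
    UndefinedDurationError,
    branch_summary,
    correlate,
    duration_class,
    ils_duration,
    map_character,
    marker_table,
    partition_summary,
    pct_ils_overall,
    radiation_summary,
    subtree_tree,
    search_mpre,
    z_vs_autosome,
    micro_vs_macro,
)


class TestDuration:
    def test_conflict_free_is_zero_class_le1(self, t5):
        mp = map_character(t5, {"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"})
        assert ils_duration(mp) == 0
        assert duration_class(0) == "<=1"

    def test_three_sorting_lineages_duration_two(self, t5):
        mp = map_character(t5, {"A": "1", "B": "0", "C": "1", "D": "0", "E": "0"})
        assert ils_duration(mp) == 2
        assert duration_class(2) == "2"

    def test_many_lineages_deep_duration(self):
        # pattern sorting independently in all 18 lineages of a ladder
        # (alternating states, insertion present in the earliest-diverging
        # lineage too) -> duration 17
        from retroils import ladder_tree

        names = [f"l{i + 1}" for i in range(18)]
        lad = ladder_tree(names)
        pattern = {n: ("1" if i % 2 == 0 else "0") for i, n in enumerate(names)}
        pattern["l18"] = "1"
        mp = map_character(lad, pattern)
        assert mp.n_fixations == 18
        assert ils_duration(mp) == 17
        assert duration_class(17) == ">=4"

    def test_all_absent_undefined(self, t5):
        mp = map_character(t5, {t: "0" for t in t5.taxa})
        with pytest.raises(UndefinedDurationError):
            ils_duration(mp)


class TestBranchSummary:
    def test_toy_pct_ils(self, t5, make_matrix):
        taxa = t5.taxa
        m = make_matrix(
            taxa,
            {
                "c1": dict(zip(taxa, [1, 1, 0, 0, 0])),
                "c2": dict(zip(taxa, [1, 1, 0, 0, 0])),
                "c3": dict(zip(taxa, [1, 1, 0, 0, 0])),
                # ILS-affected, origin above MRCA(A,B,C)=same branch as nothing else
                "x1": dict(zip(taxa, [1, 0, 1, 0, 0])),
            },
        )
        summaries = {s.branch_name: s for s in branch_summary(t5, m)}
        ab = summaries["{A|B}"]
        assert ab.conflict_free == 3 and ab.n_ils == 0 and ab.pct_ils == 0.0
        abc = summaries["{A|B|C}"]
        assert abc.n_ils == 1 and abc.ils_counts["2"] == 1 and abc.pct_ils == 100.0

    def test_marker_conservation(self, t5, make_matrix):
        rng = np.random.default_rng(4)
        taxa = t5.taxa
        markers = {f"m{i}": dict(zip(taxa, rng.choice(["0", "1", "?"], size=5))) for i in range(60)}
        m = make_matrix(taxa, markers)
        records, _ = marker_table(t5, m)
        n_informative = sum(1 for r in records if r.origin is not None)
        total = sum(s.total_markers for s in branch_summary(t5, m))
        assert total == n_informative

    def test_insertion_rate_with_dated_tree(self, t5, make_matrix):
        dated = Tree.from_newick("((((A:5,B:5):5,C:10):5,D:15):5,E:20);", units="my")
        taxa = t5.taxa
        m = make_matrix(
            taxa,
            {f"c{i}": dict(zip(taxa, [1, 1, 0, 0, 0])) for i in range(10)},
        )
        summaries = {s.branch_name: s for s in branch_summary(t5, m, dated_tree=dated)}
        ab = summaries["{A|B}"]
        assert ab.branch_length_my == 5.0
        assert ab.insertion_rate == pytest.approx(2.0)  # 10 insertions / 5 MY

    def test_rates_require_my_units(self, t5, make_matrix):
        notmy = Tree.from_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        m = make_matrix(t5.taxa, {"m": dict(zip(t5.taxa, [1, 1, 0, 0, 0]))})
        with pytest.raises(ValueError, match="MY"):
            branch_summary(t5, m, dated_tree=notmy)

    def test_empty_branch_pct_is_undefined(self, t5, make_matrix):
        m = make_matrix(t5.taxa, {"m": dict(zip(t5.taxa, [1, 1, 0, 0, 0]))})
        summaries = {s.branch_name: s for s in branch_summary(t5, m)}
        assert summaries["{A|B|C|D}"].pct_ils is None


class TestCorrelate:
    def test_perfect_negative(self):
        res = correlate([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.rho == pytest.approx(-1.0)
        assert res.n == 4

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate([1, 2, 3, 4], [5, 5, 5, 5])

    def test_permutation_agrees_with_t_for_strong_signal(self):
        rng = np.random.default_rng(0)
        x = np.arange(24, dtype=float)
        y = -x + rng.normal(0, 2.0, size=24)
        rt = correlate(x, y)
        rp = correlate(x, y, method="permutation", n_perm=999, seed=1)
        assert rt.rho == pytest.approx(rp.rho)
        assert rt.p < 0.01 and rp.p < 0.01


class TestPartitions:
    @staticmethod
    def _matrix_with_chrom(make_matrix, t5):
        taxa = t5.taxa
        markers = {
            "z1": dict(zip(taxa, [1, 0, 1, 0, 0])),   # ILS-affected
            "z2": dict(zip(taxa, [1, 1, 0, 0, 0])),
            "a1": dict(zip(taxa, [1, 1, 0, 0, 0])),
            "a2": dict(zip(taxa, [1, 1, 1, 0, 0])),
            "u1": dict(zip(taxa, [1, 1, 0, 0, 0])),
        }
        meta = pd.DataFrame(
            {"chromosome": ["chrZ", "chrZ", "chr1", "chr2", None]},
            index=list(markers),
        )
        return make_matrix(taxa, markers, meta)

    def test_z_vs_autosome(self, t5, make_matrix):
        m = self._matrix_with_chrom(make_matrix, t5)
        parts = {p.partition: p for p in partition_summary(m, t5, z_vs_autosome)}
        assert parts["Z"].pct_ils == pytest.approx(50.0)
        assert parts["autosome"].pct_ils == pytest.approx(0.0)
        assert parts["unknown"].n_markers == 1  # reported, not dropped

    def test_all_conflict_free_every_partition_zero(self, t5, make_matrix):
        taxa = t5.taxa
        meta = pd.DataFrame({"chromosome": ["chr1", "chrZ"]}, index=["m1", "m2"])
        m = make_matrix(
            taxa,
            {"m1": dict(zip(taxa, [1, 1, 0, 0, 0])), "m2": dict(zip(taxa, [1, 1, 1, 0, 0]))},
            meta,
        )
        assert all(p.pct_ils == 0.0 for p in partition_summary(m, t5))

    def test_micro_rule(self):
        sizes = {"chr1": 120e6, "chr20": 12e6}
        assert micro_vs_macro("chr20", sizes) == "micro"
        assert micro_vs_macro("chr1", sizes) == "macro"
        assert micro_vs_macro("chrNA", sizes) == "unknown"


class TestRadiations:
    def test_duration_spectrum_per_named_internode_set(self, t5, make_matrix):
        taxa = t5.taxa
        m = make_matrix(
            taxa,
            {
                "deep": dict(zip(taxa, [1, 0, 1, 0, 0])),   # origin {A,B,C}, duration 2
                "shal": dict(zip(taxa, [1, 1, 0, 0, 0])),   # origin {A,B}
            },
        )
        rads = radiation_summary(
            t5,
            m,
            {"deep_set": [{"A", "B", "C"}], "shallow_set": [{"A", "B"}]},
        )
        by = {r.radiation: r for r in rads}
        assert by["deep_set"].pct_ils == 100.0
        assert by["deep_set"].duration_spectrum == {2: 1}
        assert by["shallow_set"].pct_ils == 0.0

    def test_unknown_clade_rejected(self, t5, make_matrix):
        m = make_matrix(t5.taxa, {"m": dict(zip(t5.taxa, [1, 1, 0, 0, 0]))})
        with pytest.raises(ValueError, match="not a clade"):
            radiation_summary(t5, m, {"bad": [{"A", "C"}]})


class TestSubtreeTree:
    def test_full_subset_matches_direct_search(self):
        import numpy as np
        from retroils import PresenceAbsenceMatrix

        true = Tree.from_structure(((("A", "B"), "C"), ("D", "E")))
        taxa = true.taxa
        rows, ids = [], []
        k = 0
        for c in true.clades():
            if 1 < len(c) < 5:
                for _ in range(3):
                    ids.append(f"m{k}")
                    k += 1
                    rows.append([1 if t in c else 0 for t in taxa])
        m = PresenceAbsenceMatrix(taxa, ids, np.array(rows))
        t_direct, _ = search_mpre(m, n_jumbles=2, seed=5)
        t_subset, _ = subtree_tree(m, m.marker_ids, n_jumbles=2, seed=5)
        assert t_direct == t_subset == true

    def test_small_subset_warns_but_runs(self, caplog):
        import logging
        import numpy as np
        from retroils import PresenceAbsenceMatrix

        taxa = ["A", "B", "C", "D"]
        m = PresenceAbsenceMatrix(taxa, ["m1"], np.array([[1, 1, 0, 0]]))
        with caplog.at_level(logging.WARNING):
            tree, _ = subtree_tree(m, ["m1"], n_jumbles=1, seed=1)
        assert tree.n_leaves == 4
        assert any("informative" in rec.message for rec in caplog.records)


def test_pct_ils_overall(t5, make_matrix):
    taxa = t5.taxa
    m = make_matrix(
        taxa,
        {
            "a": dict(zip(taxa, [1, 1, 0, 0, 0])),
            "b": dict(zip(taxa, [1, 0, 1, 0, 0])),
            "c": dict(zip(taxa, [0, 0, 0, 0, 0])),  # uninformative
        },
    )
    assert pct_ils_overall(t5, m) == pytest.approx(50.0)
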