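import numpy as np
import pandas as pd
import pytest

from retroils import (
    SimulationConfig,
    SimulationError,
    genealogical_duration,
    ladder_tree,
    map_character,
    recover_parameters,
    simulate_gene_tree,
    simulate_matrix,
    to_coalescent_units,
)
from retroils.ils import ils_duration


class TestGeneTree:
    def test_two_species_forced_topology(self):
        tree = ladder_tree(["A", "B"], internode=1.0, units="coalescent")
        rng = np.random.default_rng(0)
        times = []
        for _ in range(2000):
            g = simulate_gene_tree(tree, rng)
            assert g.topology_matches(tree)
            times.append(g.times[g.root])
        # coalescence above the root: age 1 + Exp(1)
        assert np.mean(times) == pytest.approx(2.0, abs=0.1)

    def test_zero_internal_branch_gives_one_third_concordance(self):
        tree = ladder_tree(["A", "B", "C"], internode=0.0, units="coalescent")
        rng = np.random.default_rng(1)
        n = 6000
        match = sum(simulate_gene_tree(tree, rng).topology_matches(tree) for _ in range(n))
        se = (1 / 3 * 2 / 3 / n) ** 0.5
        assert match / n == pytest.approx(1 / 3, abs=3 * se)

    def test_requires_branch_lengths(self):
        from retroils import Tree, TreeError

        tree = Tree.from_structure((("A", "B"), "C"))
        with pytest.raises(TreeError):
            simulate_gene_tree(tree, np.random.default_rng(0))

    def test_deep_coalescence_counts_hidden_persistence(self):
        """A clade pattern fixed above the root carries genealogical duration
        the pattern cannot show."""
        tree = ladder_tree(["A", "B", "C"], internode=0.05, units="coalescent")
        rng = np.random.default_rng(3)
        found = 0
        for _ in range(400):
            g = simulate_gene_tree(tree, rng)
            parents = g.parent_map()
            for node, parent in enumerate(parents):
                if parent is None or g.tipmask[node] == (1 << 3) - 1:
                    continue
                # insertion near the top of this lineage's branch
                t_ins = g.times[node] + 0.99 * (g.times[parent] - g.times[node])
                carriers = g.tipmask[node]
                d_gene = genealogical_duration(g, tree, carriers, t_ins)
                pattern = {t: "1" if tree.leaf_bit(t) & carriers else "0" for t in tree.taxa}
                d_pat = ils_duration(map_character(tree, pattern))
                assert d_gene >= 0
                if d_gene >= 2 and d_pat <= 1:
                    found += 1
        assert found > 0  # hidden persistence occurs at tiny internodes


class TestSimulateMatrix:
    def test_seed_determinism(self, coalescent_ladder):
        cfg = dict(species_tree=coalescent_ladder(), n_loci=60, seed=42)
        m1, t1 = simulate_matrix(SimulationConfig(**cfg))
        m2, t2 = simulate_matrix(SimulationConfig(**cfg))
        assert m1 == m2
        pd.testing.assert_frame_equal(t1, t2)
        m3, _ = simulate_matrix(SimulationConfig(**dict(cfg, seed=43)))
        assert m1 != m3

    def test_no_missing_when_rate_zero(self, coalescent_ladder):
        cfg = SimulationConfig(species_tree=coalescent_ladder(), n_loci=80, missing_rate=0.0, seed=7)
        m, _ = simulate_matrix(cfg)
        assert not (m.states == -1).any()

    def test_ascertainment_respected_and_conserved(self, coalescent_ladder):
        cfg = SimulationConfig(
            species_tree=coalescent_ladder(5, 0.3),
            n_loci=150,
            missing_rate=0.15,
            min_scored_taxa=4,
            seed=9,
        )
        m, truth = simulate_matrix(cfg)
        assert m.n_markers == 150
        scored = (m.states != -1).sum(axis=1)
        present = (m.states == 1).sum(axis=1)
        assert (scored >= 4).all()
        assert (present >= 2).all()            # no all-absent, no autapomorphies
        assert (present < scored).all()        # no plesiomorphies
        assert truth.attrs["attempts_total"] == truth["attempts"].sum()

    def test_long_internodes_give_clean_clades(self):
        tree = ladder_tree([f"t{i}" for i in range(5)], internode=10.0, units="coalescent")
        cfg = SimulationConfig(species_tree=tree, n_loci=200, missing_rate=0.0, seed=5)
        m, truth = simulate_matrix(cfg)
        assert (truth["duration_pattern"] == 0).mean() >= 0.99

    def test_near_star_radiation_mostly_ils(self):
        tree = ladder_tree([f"t{i}" for i in range(5)], internode=0.01, units="coalescent")
        cfg = SimulationConfig(species_tree=tree, n_loci=300, missing_rate=0.0, seed=6)
        _, truth = simulate_matrix(cfg)
        assert (truth["duration_pattern"] >= 2).mean() > 0.5

    def test_impossible_ascertainment_raises(self):
        tree = ladder_tree(["A", "B"], internode=1.0, units="coalescent")
        # with two taxa every informative pattern is autapomorphic
        cfg = SimulationConfig(species_tree=tree, n_loci=5, seed=1, max_attempts_per_locus=30)
        with pytest.raises(SimulationError, match="ascertainment"):
            simulate_matrix(cfg)

    def test_metadata_fields_present(self, coalescent_ladder):
        from retroils.simulate import default_chromosome_scheme

        cfg = SimulationConfig(
            species_tree=coalescent_ladder(),
            n_loci=40,
            seed=2,
            chromosomes=default_chromosome_scheme(),
        )
        m, _ = simulate_matrix(cfg)
        assert set(m.meta.columns) >= {"chromosome", "start", "end", "genic", "tsd_motif"}
        assert m.meta["tsd_motif"].str.len().eq(5).all()
        assert (m.meta["start"] <= m.meta["end"]).all()


class TestRecovery:
    def test_clean_data_full_agreement(self):
        tree = ladder_tree([f"t{i}" for i in range(5)], internode=4.0, units="coalescent")
        cfg = SimulationConfig(species_tree=tree, n_loci=150, missing_rate=0.0, seed=8)
        m, truth = simulate_matrix(cfg)
        rep = recover_parameters(m, tree, truth)
        assert rep.agreement_pattern == 1.0

    def test_masked_data_recovers_most_durations(self):
        """With one unscored taxon allowed per locus, the estimator still
        recovers the pattern-implied ILS duration for the large majority."""
        tree = ladder_tree([f"t{i}" for i in range(5)], internode=0.5, units="coalescent")
        cfg = SimulationConfig(
            species_tree=tree, n_loci=800, missing_rate=0.2, min_scored_taxa=4, seed=11111
        )
        m, truth = simulate_matrix(cfg)
        rep = recover_parameters(m, tree, truth)
        assert rep.agreement_pattern >= 0.9
        # genealogical persistence includes unrecoverable deep coalescence
        assert rep.agreement_genealogy <= rep.agreement_pattern


def test_coalescent_unit_conversion():
    # 1 MY at Ne=500k, 1-year generations, diploid -> 1 coalescent unit
    assert to_coalescent_units(1.0, 500_000, 1.0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        to_coalescent_units(1.0, -1, 1.0)
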