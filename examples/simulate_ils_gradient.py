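"""Simulated ILS falls off with internode length, and parsimony recovers it.

For a 5-taxon ladder species tree with every internode set to tau
coalescent units, simulates 1,000 retrotransposon markers per tau under the
multispecies coalescent and reports (a) the fraction of markers the mapping
engine calls ILS-affected and (b) how often the estimated per-locus ILS
duration matches the simulated truth.
"""

from retroils import SimulationConfig, ladder_tree, pct_ils_overall, recover_parameters, simulate_matrix

print(f"{'tau':>5} {'%ILS':>7} {'agree(pattern)':>15} {'agree(genealogy)':>17}")
for tau in (0.1, 0.5, 1.0, 2.0, 4.0):
    tree = ladder_tree([f"t{i + 1}" for i in range(5)], internode=tau, units="coalescent")
    cfg = SimulationConfig(species_tree=tree, n_loci=1000, seed=11111)
    matrix, truth = simulate_matrix(cfg)
    rep = recover_parameters(matrix, tree, truth)
    print(
        f"{tau:>5} {pct_ils_overall(tree, matrix):>6.1f}% "
        f"{rep.agreement_pattern:>14.1%} {rep.agreement_genealogy:>16.1%}"
    )

print(
    "\nShort internodes (tau << 1) leave most markers ILS-affected, as in a\n"
    "near-simultaneous radiation; by tau = 4 conflicts essentially vanish.\n"
    "The estimator recovers the duration implied by each complete pattern\n"
    "exactly; agreement with the genealogical persistence is lower at small\n"
    "tau because deep coalescence can hide inside clade-like patterns —\n"
    "conflict a presence/absence marker cannot, in principle, reveal."
)
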