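"""Target-site motif composition of simulated markers.

Generates a marker matrix (whose 5-bp target-site-duplication motifs are
drawn uniformly, the no-preference null), tabulates the position-wise
nucleotide counts and information content, and runs the uniformity test.
A real target-site preference would show up as elevated information
content and a small global p-value.
"""

from retroils import SimulationConfig, ladder_tree, motif_matrix, preference_test, simulate_matrix

tree = ladder_tree([f"t{i + 1}" for i in range(6)], internode=0.8, units="coalescent")
cfg = SimulationConfig(species_tree=tree, n_loci=600, min_scored_taxa=5, seed=4)
matrix, _ = simulate_matrix(cfg)

motifs = matrix.meta["tsd_motif"].tolist()
mm = motif_matrix(motifs, ids=matrix.marker_ids)
test = preference_test(mm)

print(f"{len(motifs)} motifs; per-position counts (rows A/C/G/T):")
for nt, row in zip("ACGT", mm.counts):
    print(f"  {nt}  " + " ".join(f"{c:>5}" for c in row))
print("information content (bits):", " ".join(f"{b:.3f}" for b in mm.information_bits))
print("per-position uniformity p: ", " ".join(f"{p:.3f}" for p in test.p_per_position))
print(f"global p (Fisher combination): {test.p_global:.3f}")
print(
    "\nNear-zero information content and a non-significant global p mean no\n"
    "target-site preference — supporting the assumption that independent\n"
    "insertion into the same site (homoplasy) is negligible."
)
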