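"""Population distances (R_ST, pairwise differences), MDS and a dendrogram.

Simulates three populations that split from a common founder set at
different depths, computes the AMOVA-based pairwise R_ST matrix and the
average pairwise-difference matrices, embeds the populations with nonmetric
MDS, and cuts a UPGMA tree.
"""

from ystr_popkit import (
    SimulationConfig,
    nonmetric_mds,
    pairwise_differences,
    rst_matrix,
    simulate_table,
    upgma,
)
from ystr_popkit.synthetic_data import DEFAULT_FOUNDERS, LineageSpec

cfg = SimulationConfig(
    populations=(("Yemen", 40), ("Oman", 40), ("Iraq", 40)),
    lineages=(LineageSpec("J1a", 1.0, DEFAULT_FOUNDERS["J1a"]),),
    mu=0.01,
    depth=15,
    depth_distribution="fixed",
    microvariant_rules=(),
    divergence_depth=30,
    seed=7,
)
table, _ = simulate_table(cfg)

rst = rst_matrix(table)
print("pairwise R_ST (fraction of repeat-count variance between populations):")
print(rst.to_dataframe().round(4), "\n")

pw = pairwise_differences(table)
print("average squared pairwise differences within populations (PiX):")
print(pw.pix.round(2), "\n")
print("corrected between-population differences, PiXY - (PiX + PiY)/2:")
print(pw.corrected.round(2), "\n")

mds = nonmetric_mds(rst, k=2)
print(f"nonmetric MDS stress = {mds.stress:.3f} (x100 stress-1; <10 is a "
      "good 2-D fit)")
print(mds.coordinates.round(3), "\n")

dend = upgma(rst)
print("UPGMA tree:", dend.newick())
print("2-cluster cut:", dend.cut(2),
      "- populations that diverged least cluster together")
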