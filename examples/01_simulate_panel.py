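"""Simulate a foundation-parent breeding panel with planted truth.

Builds the desk-scale panel (4 FP groups x 15 inbred lines, 8,000 SNPs on
two 10 Mb chromosomes) and prints what was planted: conserved segments per
group, QTNs with their variance fractions, and differentially expressed
genes. The same generator scales to the full panel (304 lines, 43,252
SNPs) via `SimConfig()`.
"""

from fpscan import SimConfig, simulate_panel

cfg = SimConfig.ci_scale(seed=7)
g, truth = simulate_panel(cfg)

print(f"panel: {g.n_lines} lines x {g.n_markers} markers")
print(f"groups: {dict(g.lines['group'].value_counts())}")
per_class = truth.segments["groups"].str.count(",").add(1).value_counts()
print(f"planted segments by number of sharing groups: {dict(per_class)}")
print("planted QTNs:")
print(truth.qtns[["marker_id", "chrom", "pos_bp", "trait", "h2"]].to_string(index=False))
print(f"planted DE genes: {len(truth.de_genes)} "
      f"(log2 shifts {sorted(truth.de_genes['log2_shift'].unique())})")
# Each group's lines copy one founder haplotype inside its planted
# segments (gene diversity 0 there) and carry ~0.24 background diversity
# elsewhere, emulating descendants of a shared foundation parent.
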