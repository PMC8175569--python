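"""Profile RBP peak coverage over splice-site-anchored intron windows.

Builds the nine-window partition of a 1,000-bp intron (40-bp exonic and
intronic flanks at each splice site plus five near-equal interior tiles),
plants peaks for three RBPs preferentially in the intronic flanks, and
shows that the per-window coverage fractions recover the enrichment.
"""

import pirfish as pf
from pirfish.windows import build_intron_windows, coverage_matrix

ws = build_intron_windows((1000, 2000), strand="+", flank=40, n_tiles=5)
print("window partition of intron [1000, 2000):")
for w in ws.windows:
    print(f"  {w.role:>16}  [{w.start}, {w.end})  {w.length} bp")

model = pf.gen_gene_model(3, (150, 150), (700, 900), seed=5, gene_id="toy")
fx = pf.gen_peak_and_motif_fixtures(
    model, n_rbps=3, planted_roles=("intronic_5flank", "intronic_3flank"),
    background_cover=0.05, seed=2)
mat = coverage_matrix(fx.window_sets, fx.peaks_by_rbp)
print("\nper-RBP coverage fractions (rows RBPs, columns intron windows):")
print(mat.round(2).to_string())

flanks = [c for c in mat.columns if "intronic" in c[1]]
tiles = [c for c in mat.columns if c[1].startswith("tile")]
print(f"\nmean coverage in splice-site flanks: "
      f"{mat[flanks].to_numpy().mean():.2f}")
print(f"mean coverage in interior tiles:     "
      f"{mat[tiles].to_numpy().mean():.2f}")
print("Peaks were planted in the flanks, so the flank mean should dominate.")

Z, order = pf.cluster_introns(mat)
print(f"\nhierarchical clustering leaf order (RBPs): {order}")
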