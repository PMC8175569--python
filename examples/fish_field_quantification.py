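"""Quantify a synthetic dual-channel smFISH field.

Renders a field of four cells with 50 transcript signals (unspliced
exon+intron pairs, spliced exon-only spots, solo introns) at SNR 5,
detects spots in both channels, co-localises them, and reports per-cell
nuclear PIR — the percentage of nuclear transcripts that retain the
intron — against the generator's ground truth.
"""

import pirfish as pf
from pirfish.fish import quantify_field

field = pf.simulate_field(n_cells=4, n_signals=50, snr=5.0, seed=42)
truth = field.truth.per_cell_truth()

quant = quantify_field(field.exon, field.intron,
                       nucleus_mask=field.truth.nucleus_mask,
                       cell_mask=field.truth.cell_mask,
                       radius=3.0)

merged = quant.merge(truth, on="cell_id", suffixes=("", "_true"))
cols = ["cell_id", "exon_total", "unspliced_nuclear", "spliced_nuclear",
        "solo_intron", "nuclear_pir", "nuclear_pir_true"]
print(merged[cols].to_string(index=False, float_format="%.1f"))
print("\nnuclear_pir is measured from detected spots; nuclear_pir_true from")
print("the planted ground truth — at this SNR they should agree exactly")
print("for nearly every cell. nuclear_enrichment (not shown) is the share")
print("of each cell's transcripts located in the nucleus.")
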