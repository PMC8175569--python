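"""The statistics the pipeline reports: correlations, t-tests, fold
changes, nuclear enrichment, qPCR decay and compartment fractions."""

import numpy as np
import pandas as pd

import pirfish as pf

# Correlation between per-cell nuclear unspliced counts and nuclear totals,
# on a synthetic field's ground truth.
field = pf.simulate_field(n_cells=9, n_signals=120, seed=3)
truth = field.truth.per_cell_truth()
res = pf.pearson(truth["unspliced_nuclear"], truth["exon_nuclear"])
print(f"nuclear unspliced vs nuclear total: R^2 = {res.r_squared:.2f}, "
      f"p = {res.p:.2g} (n = {res.n} cells)")

# Fold change between control and treated mean molecule counts.
fc = pf.fold_change(29, 12)
print(f"cytoplasmic molecules 29 -> 12: {fc.fold_1dp}-fold {fc.direction}")

# Nuclear enrichment: share of a transcript's molecules in the nucleus.
print(f"nuclear enrichment of 86 nuclear / 14 cytoplasmic molecules: "
      f"{pf.nuclear_enrichment(86, 14):.0f}%")

# Unpaired two-tailed equal-variance t-test between two cell groups.
rng = np.random.default_rng(0)
interphase = rng.poisson(10, size=20)
mitosis = rng.poisson(1, size=20)
tt = pf.ttest_equal_var(interphase, mitosis)
print(f"unspliced per cell, interphase vs mitosis: t = {tt.t:.1f}, "
      f"p = {tt.p:.2g} ({tt.df} df)")

# Transcription-inhibition decay measured by RT-qPCR, 2^-ddCt vs time 0.
decay = pf.relative_expression_series(
    timepoints=[0, 0.67, 2.5, 4.5],
    ct_target=[[22.0, 22.1], [22.3, 22.4], [23.4, 23.5], [24.8, 24.9]],
    ct_reference=[[15.0, 15.0], [15.1, 15.1], [15.0, 15.1], [15.0, 15.0]])
print("\nrelative expression over a transcription-inhibition time course:")
print(decay[["timepoint", "relative_expression"]]
      .to_string(index=False, float_format="%.3f"))
print("(1.0 at the calibrator; one extra Ct cycle halves the value)")

# Compartment fractions from TPM of subcellular fractionation.
tpm = pd.DataFrame({"chromatin": [50.0, 2.0], "nucleoplasm": [30.0, 3.0],
                    "cytoplasm": [20.0, 95.0]}, index=["nuclear_gene",
                                                       "cytoplasmic_gene"])
print("\ncompartment fractions (rows sum to 1):")
print(pf.compartment_fraction(tpm).round(3).to_string())
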