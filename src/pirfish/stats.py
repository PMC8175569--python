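"""The study-style statistical layer.

Thin, explicit wrappers around the classical procedures used to compare
FISH counts, qPCR series and compartment expression: Pearson correlation
(reported as r, R-squared and the t-distribution p-value), the unpaired
two-tailed equal-variance Student t-test, one-decimal fold changes between
group means, nuclear enrichment percentages, qPCR relative expression by
2^-ddCt, and TPM compartment fractions. No multiple-testing correction is
applied anywhere in this module — every p-value is raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p: float
    n: int
    defined: bool = True


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation with the exact t-based p-value.

    p is two-sided from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom. Zero variance in either variable yields an undefined result
    (flagged, NaN statistics) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PearsonResult(np.nan, np.nan, np.nan, n, defined=False)
    r, p = sps.pearsonr(x, y)
    return PearsonResult(float(r), float(r) ** 2, float(p), n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int


def ttest_equal_var(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Unpaired two-tailed Student t-test with pooled (equal) variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), float(p), a.size + b.size - 2)


@dataclass(frozen=True)
class FoldChange:
    fold: float          # >= 1, unrounded
    fold_1dp: float      # rounded to one decimal, the reporting convention
    direction: str       # "increase" | "decrease" | "none"


def fold_change(mean_ref: float, mean_alt: float) -> FoldChange:
    """Fold change between two group means, reported as >= 1 with direction.

    ``direction`` describes the change from reference to alternative.
    """
    if mean_ref <= 0 or mean_alt <= 0:
        raise ValueError("fold change undefined for non-positive means")
    fold = max(mean_ref, mean_alt) / min(mean_ref, mean_alt)
    if mean_alt > mean_ref:
        direction = "increase"
    elif mean_alt < mean_ref:
        direction = "decrease"
    else:
        direction = "none"
    return FoldChange(float(fold), round(float(fold), 1), direction)


def nuclear_enrichment(nuclear: float, cytoplasmic: float) -> float:
    """Percentage of detected molecules located in the nucleus."""
    total = nuclear + cytoplasmic
    if total <= 0:
        raise ValueError("need at least one detected molecule")
    if nuclear < 0 or cytoplasmic < 0:
        raise ValueError("counts must be >= 0")
    return 100.0 * nuclear / total


# ---------------------------------------------------------------------------
# qPCR relative expression


def relative_expression_series(
    timepoints: Sequence[float],
    ct_target: Sequence[float] | Sequence[Sequence[float]],
    ct_reference: Sequence[float] | Sequence[Sequence[float]],
    calibrator: float | None = None,
) -> pd.DataFrame:
    """Per-timepoint relative expression by the comparative Ct method.

    dCt = Ct_target - Ct_reference per timepoint; ddCt is taken against the
    calibrator timepoint (default: the first), and relative expression is
    2^-ddCt, exactly 1 at the calibrator. Technical replicates may be given
    as per-timepoint lists; they are averaged to a mean Ct first.
    """
    tp = np.asarray(timepoints, dtype=float)

    def mean_ct(values):
        if len(values) and isinstance(values[0], (list, tuple, np.ndarray)):
            return np.array([float(np.mean(v)) for v in values])
        return np.asarray(values, dtype=float)

    tgt = mean_ct(ct_target)
    ref = mean_ct(ct_reference)
    if not (tp.size == tgt.size == ref.size):
        raise ValueError("timepoints, target and reference Ct must align")
    if calibrator is None:
        calibrator = tp[0]
    where = np.nonzero(tp == calibrator)[0]
    if where.size == 0:
        raise ValueError(f"calibrator timepoint {calibrator} not in series")
    dct = tgt - ref
    ddct = dct - dct[where[0]]
    return pd.DataFrame({
        "timepoint": tp, "ct_target": tgt, "ct_reference": ref,
        "delta_ct": dct, "delta_delta_ct": ddct,
        "relative_expression": 2.0 ** (-ddct),
    })


# ---------------------------------------------------------------------------
# compartment TPM fractions


def tpm_from_counts(counts: pd.DataFrame,
                    effective_lengths: Mapping[str, float] | pd.Series
                    ) -> pd.DataFrame:
    """Transcripts-per-million from a gene x sample count table."""
    lens = pd.Series(effective_lengths, dtype=float).reindex(counts.index)
    if lens.isna().any():
        missing = list(lens[lens.isna()].index)
        raise ValueError(f"missing effective lengths for {missing}")
    rate = counts.div(lens, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def compartment_fraction(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene relative abundance across compartments.

    ``tpm`` is a gene x compartment table (e.g. chromatin, nucleoplasm,
    cytoplasm); each gene's fractions are its TPM divided by the sum of its
    TPMs over all compartments, so rows sum to 1. Genes with zero total are
    returned as NaN rows.
    """
    tpm = tpm.astype(float)
    if (tpm < 0).any().any():
        raise ValueError("TPM values must be >= 0")
    totals = tpm.sum(axis=1)
    frac = tpm.div(totals.replace(0, np.nan), axis=0)
    return frac
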