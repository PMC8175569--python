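"""Percent intron retention (PIR) from exon-intron junction read evidence.

For one intron, three junction read categories carry the signal:

* ``EI`` — reads aligning contiguously across the upstream (transcript 5')
  exon-intron boundary, with at least ``min_anchor`` bp on each side;
* ``IE`` — likewise across the downstream intron-exon boundary;
* ``EE`` — spliced reads whose alignment gap spans the intron exactly.

PIR = 100 * mean(EI, IE) / (mean(EI, IE) + EE).  Two quality filters guard
the estimate: a minimum total read count over the three categories, and an
exact two-sided binomial test of EI vs IE balance (a strong imbalance
usually flags an overlapping alternative splice site, in which case the
estimate can be re-computed from the clean junction alone). ``mid_intron``
reads (fully inside the intron body) are tallied as supporting evidence but
do not enter the default PIR formula.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneModel
from .synth.reads import SimulatedReads

DEFAULT_MIN_ANCHOR = 8
DEFAULT_MIN_TOTAL = 15
DEFAULT_ALPHA = 0.05


class UnsupportedAlignmentError(ValueError):
    """Raised when an alignment uses CIGAR operators other than M/N."""


class Status(str, enum.Enum):
    OK = "ok"
    LOW_COVERAGE = "low_coverage"
    IMBALANCED = "imbalanced"
    SINGLE_JUNCTION_UPSTREAM = "single_junction_upstream"
    SINGLE_JUNCTION_DOWNSTREAM = "single_junction_downstream"


DEFINED_STATUSES = {Status.OK, Status.SINGLE_JUNCTION_UPSTREAM,
                    Status.SINGLE_JUNCTION_DOWNSTREAM}


@dataclass(frozen=True)
class JunctionCounts:
    intron_id: str
    EI: int
    IE: int
    EE: int
    mid_intron: int = 0
    min_anchor: int = DEFAULT_MIN_ANCHOR

    def __post_init__(self):
        for name in ("EI", "IE", "EE", "mid_intron"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")


@dataclass(frozen=True)
class PIREstimate:
    intron_id: str
    pir: float | None
    n_total: int
    balance_p: float
    status: Status

    @property
    def defined(self) -> bool:
        return self.status in DEFINED_STATUSES


# ---------------------------------------------------------------------------
# junction counting


def _blocks_to_arrays(reads: Iterable[Sequence[tuple[int, int]]]):
    """Pad per-read block lists into the (starts, ends) array form."""
    blocks = [list(b) for b in reads]
    width = max((len(b) for b in blocks), default=1)
    n = len(blocks)
    bs = np.full((n, max(width, 1)), -1, dtype=np.int64)
    be = np.full_like(bs, -1)
    for i, b in enumerate(blocks):
        for j, (s, e) in enumerate(b):
            bs[i, j] = s
            be[i, j] = e
    return bs, be


def _read_sam_blocks(path, chrom: str | None = None):
    """Parse a SAM/BAM file into per-read block lists; M/N CIGARs only."""
    import pysam

    blocks = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            if chrom is not None and read.reference_name != chrom:
                continue
            bad = [op for op, _ in (read.cigartuples or [])
                   if op not in (0, 3)]  # 0=M, 3=N
            if bad:
                raise UnsupportedAlignmentError(
                    f"read {read.query_name!r} uses CIGAR operators other "
                    f"than M/N"
                )
            pos = read.reference_start
            rb = []
            for op, length in read.cigartuples:
                if op == 0:
                    rb.append((pos, pos + length))
                    pos += length
                else:
                    pos += length
            blocks.append(rb)
    return blocks


def count_junction_reads(
    reads,
    model: GeneModel,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> dict[str, JunctionCounts]:
    """Tally EI/IE/EE/mid-intron reads for every intron of ``model``.

    ``reads`` may be a :class:`~pirfish.synth.reads.SimulatedReads`, a path
    to a SAM/BAM file, or an iterable of per-read block lists
    ``[(start, end), ...]`` (genomic, 0-based half-open, gaps implied
    between consecutive blocks).

    A read counts at most once per category per intron; one read may count
    for several introns. EE requires the gap to match both intron boundaries
    exactly with >= min_anchor matched bp flanking the gap.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if isinstance(reads, SimulatedReads):
        bs, be = reads.block_starts, reads.block_ends
    elif isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        bs, be = _blocks_to_arrays(_read_sam_blocks(reads, chrom=model.chrom))
    else:
        bs, be = _blocks_to_arrays(reads)

    valid = bs >= 0
    lens = np.where(valid, be - bs, 0)
    n, width = bs.shape
    last_idx = np.maximum(valid.sum(axis=1) - 1, 0)
    read_start = bs[:, 0] if n else np.empty(0, dtype=np.int64)
    read_end = be[np.arange(n), last_idx] if n else np.empty(0, dtype=np.int64)
    single_block = valid.sum(axis=1) == 1 if n else np.empty(0, dtype=bool)

    out: dict[str, JunctionCounts] = {}
    for iid, (istart, iend) in model.iter_introns():
        if n == 0:
            out[iid] = JunctionCounts(iid, 0, 0, 0, 0, min_anchor)
            continue
        # contiguous span across the genomic-left / genomic-right boundary
        left = np.any(valid & (bs <= istart - min_anchor)
                      & (be >= istart + min_anchor), axis=1)
        right = np.any(valid & (bs <= iend - min_anchor)
                       & (be >= iend + min_anchor), axis=1)
        # spliced gap exactly spanning the intron, anchored both sides
        if width > 1:
            gap = ((be[:, :-1] == istart) & (bs[:, 1:] == iend)
                   & (lens[:, :-1] >= min_anchor) & (lens[:, 1:] >= min_anchor))
            ee = np.any(gap, axis=1)
        else:
            ee = np.zeros(n, dtype=bool)
        mid = (single_block & (read_start >= istart + min_anchor)
               & (read_end <= iend - min_anchor))
        if model.strand == "+":
            ei_n, ie_n = int(left.sum()), int(right.sum())
        else:  # transcript 5' boundary is the genomic-right one
            ei_n, ie_n = int(right.sum()), int(left.sum())
        out[iid] = JunctionCounts(iid, ei_n, ie_n, int(ee.sum()),
                                  int(mid.sum()), min_anchor)
    return out


# ---------------------------------------------------------------------------
# estimation


def balance_test(ei: int, ie: int) -> float:
    """Exact two-sided binomial test of EI/IE balance (p = 1 when no reads)."""
    if ei < 0 or ie < 0:
        raise ValueError("junction counts must be >= 0")
    n = ei + ie
    if n == 0:
        return 1.0
    return float(stats.binomtest(ei, n, 0.5).pvalue)


def estimate_pir(
    counts: JunctionCounts,
    min_total: int = DEFAULT_MIN_TOTAL,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "two_junction",
) -> PIREstimate:
    """PIR with coverage and balance filters.

    two_junction: pir = 100 * mean(EI, IE) / (mean(EI, IE) + EE), undefined
    when the EI+IE+EE total falls below ``min_total`` or the balance test
    rejects at ``alpha``. The single-junction modes use one boundary's count
    only (the coverage filter then applies to the reduced EI+EE or IE+EE
    evidence) and skip the balance test.
    """
    ei, ie, ee = counts.EI, counts.IE, counts.EE
    p_bal = balance_test(ei, ie)
    if mode == "two_junction":
        n_total = ei + ie + ee
        if n_total < min_total:
            return PIREstimate(counts.intron_id, None, n_total, p_bal,
                               Status.LOW_COVERAGE)
        if p_bal < alpha:
            return PIREstimate(counts.intron_id, None, n_total, p_bal,
                               Status.IMBALANCED)
        ret = (ei + ie) / 2.0
        pir = 100.0 * ret / (ret + ee)
        return PIREstimate(counts.intron_id, pir, n_total, p_bal, Status.OK)
    if mode == "single_junction_upstream":
        used, status = ei, Status.SINGLE_JUNCTION_UPSTREAM
    elif mode == "single_junction_downstream":
        used, status = ie, Status.SINGLE_JUNCTION_DOWNSTREAM
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_used = used + ee
    if n_used < min_total:
        return PIREstimate(counts.intron_id, None, n_used, p_bal,
                           Status.LOW_COVERAGE)
    pir = 100.0 * used / n_used
    return PIREstimate(counts.intron_id, pir, n_used, p_bal, status)


def recalc_single_junction(
    counts: JunctionCounts,
    side: str,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> PIREstimate:
    """Re-estimate PIR from one boundary only (upstream EI or downstream IE).

    Used when the balance test flags an intron whose other boundary is
    confounded by an overlapping alternative donor/acceptor.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    return estimate_pir(counts, min_total=min_total,
                        mode=f"single_junction_{side}")


def estimate_pir_table(
    counts_by_intron: Mapping[str, JunctionCounts],
    gene_ids: Mapping[str, str] | None = None,
    min_total: int = DEFAULT_MIN_TOTAL,
    alpha: float = DEFAULT_ALPHA,
    single_junction: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Estimate PIR for a collection of introns, returning the PIR table.

    ``single_junction`` maps intron_id -> side for introns that should be
    re-computed from one junction (applied after, and regardless of, the
    two-junction attempt).
    """
    single_junction = single_junction or {}
    rows = []
    for iid, c in counts_by_intron.items():
        if iid in single_junction:
            est = recalc_single_junction(c, single_junction[iid],
                                         min_total=min_total)
        else:
            est = estimate_pir(c, min_total=min_total, alpha=alpha)
        rows.append({
            "intron_id": iid,
            "gene_id": (gene_ids or {}).get(iid, iid.split(":")[0]),
            "EI": c.EI, "IE": c.IE, "EE": c.EE, "mid_intron": c.mid_intron,
            "pir": est.pir if est.defined else np.nan,
            "balance_p": est.balance_p,
            "status": est.status.value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-gene summaries


def gene_pir_extremes(pir_table: pd.DataFrame,
                      biotypes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-gene max/min PIR over introns with a defined estimate.

    Genes with no defined PIR are omitted. ``biotypes`` maps gene_id to
    biotype (default "coding").
    """
    df = pir_table.dropna(subset=["pir"])
    rows = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        rows.append({
            "gene_id": gene_id,
            "biotype": (biotypes or {}).get(gene_id, "coding"),
            "max_pir": float(grp["pir"].max()),
            "min_pir": float(grp["pir"].min()),
            "n_evaluable_introns": int(len(grp)),
        })
    return pd.DataFrame(rows)


def max_pir_ecdf(summary: pd.DataFrame) -> pd.DataFrame:
    """ECDF of max_pir within each biotype class, with the paired min_pir.

    Returns rows sorted by (biotype, max_pir) with column ``ecdf`` in (0, 1].
    """
    out = []
    for biotype, grp in summary.groupby("biotype", sort=True):
        g = grp.sort_values(["max_pir", "gene_id"]).reset_index(drop=True)
        n = len(g)
        vals = g["max_pir"].to_numpy()
        # ECDF with ties: fraction of genes with max_pir <= value
        g["ecdf"] = np.searchsorted(np.sort(vals), vals, side="right") / n
        out.append(g)
    return pd.concat(out, ignore_index=True)


def percentile_rank(value: float, population: Sequence[float]) -> float:
    """Percentile of ``value`` within ``population``: 100 * #(<= value) / N."""
    pop = np.asarray(population, dtype=float)
    if pop.size == 0:
        raise ValueError("population must be non-empty")
    return 100.0 * float(np.count_nonzero(pop <= value)) / pop.size


# ---------------------------------------------------------------------------
# TSV exchange


def read_junction_counts_tsv(path) -> dict[str, JunctionCounts]:
    """Read pre-tabulated junction counts (intron_id, EI, IE, EE, mid_intron)."""
    df = pd.read_csv(path, sep="\t")
    required = {"intron_id", "EI", "IE", "EE"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"junction count table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["intron_id"])] = JunctionCounts(
            str(row["intron_id"]), int(row["EI"]), int(row["IE"]),
            int(row["EE"]), int(row.get("mid_intron", 0) or 0),
        )
    return out


def write_pir_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
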