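"""Simulate aligned RNA-seq reads from a retention/splicing isoform mixture.

Each source molecule of a gene either retains each intron (independently,
with the intron's true retention fraction rho) or has it spliced out. Reads
are sampled uniformly over all valid read start positions in the molecule
pool, which makes the expected read count over every junction exactly
proportional to the fraction of molecules carrying that junction — the
property the downstream junction-ratio estimator relies on.

Reads are emitted pre-aligned: contiguous genomic blocks (CIGAR M) separated
by splice gaps (CIGAR N). No sequencing-error model, no alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from ..genes import GeneModel

_MAX_INTRONS_ENUM = 16  # isoform configurations are enumerated (2**n)


@dataclass(frozen=True)
class RetentionSpec:
    """Ground truth for a simulated retention experiment.

    rho may be a scalar (shared by all introns) or one value per intron in
    transcript orientation. depth is the expected total read count (Poisson);
    read_length in bp.
    """

    rho: float | Sequence[float]
    depth: float
    read_length: int
    seed: int = 0

    def rho_vector(self, n_introns: int) -> np.ndarray:
        rho = np.broadcast_to(np.asarray(self.rho, dtype=float), n_introns).copy()
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("retention fractions must lie in [0, 1]")
        return rho

    def validate(self, min_anchor: int) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length < 2 * min_anchor:
            raise ValueError(
                f"read_length ({self.read_length}) must be >= 2*min_anchor "
                f"({2 * min_anchor}) so a read can anchor both sides of a junction"
            )


class SimulatedReads:
    """A set of simulated spliced alignments in block form.

    Blocks are stored as padded integer arrays: ``block_starts[i, j]`` /
    ``block_ends[i, j]`` give the j-th aligned genomic block of read i
    (0-based half-open); -1 pads unused slots. This compact form feeds the
    vectorised junction counter directly and serialises to SAM on demand.
    """

    def __init__(self, chrom: str, block_starts: np.ndarray,
                 block_ends: np.ndarray, reference_length: int):
        assert block_starts.shape == block_ends.shape
        self.chrom = chrom
        self.block_starts = block_starts
        self.block_ends = block_ends
        self.reference_length = int(reference_length)

    def __len__(self) -> int:
        return self.block_starts.shape[0]

    def iter_blocks(self):
        """Yield each read's blocks as a list of (start, end) tuples."""
        for i in range(len(self)):
            bs = self.block_starts[i]
            be = self.block_ends[i]
            yield [(int(s), int(e)) for s, e in zip(bs, be) if s >= 0]

    def cigar_string(self, i: int) -> str:
        parts = []
        prev_end = None
        for s, e in zip(self.block_starts[i], self.block_ends[i]):
            if s < 0:
                break
            if prev_end is not None:
                parts.append(f"{s - prev_end}N")
            parts.append(f"{e - s}M")
            prev_end = e
        return "".join(parts)

    def to_sam(self, path) -> None:
        """Write a minimal SAM file (header + M/N alignments, fixed SEQ=*)."""
        import pysam

        header = pysam.AlignmentHeader.from_dict({
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.chrom, "LN": self.reference_length}],
        })
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for i in range(len(self)):
                a = pysam.AlignedSegment(header)
                a.query_name = f"r{i:07d}"
                a.reference_id = 0
                a.reference_start = int(self.block_starts[i, 0])
                a.mapping_quality = 60
                a.cigarstring = self.cigar_string(i)
                a.flag = 0
                fh.write(a)


def _isoform_segments(model: GeneModel, retained: tuple[bool, ...]):
    """Genomic segments (coalesced) of the isoform retaining the given introns."""
    segs: list[list[int]] = []
    introns = model.introns
    for k, exon in enumerate(model.exons):
        if segs and segs[-1][1] == exon[0]:
            segs[-1][1] = exon[1]
        else:
            segs.append([exon[0], exon[1]])
        if k < len(introns) and retained[k]:
            segs[-1][1] = introns[k][1]  # extend through the retained intron
    return np.array([s for s, _ in segs]), np.array([e for _, e in segs])


def _map_starts_to_blocks(tx_starts: np.ndarray, read_len: int,
                          seg_starts: np.ndarray, seg_ends: np.ndarray):
    """Map transcript-coordinate read starts onto genomic blocks.

    Returns (block_starts, block_ends) padded with -1; vectorised over reads,
    looping only over the (small) number of segments a read can span.
    """
    seg_lens = seg_ends - seg_starts
    cum = np.concatenate([[0], np.cumsum(seg_lens)])
    n = tx_starts.shape[0]
    seg_idx = np.searchsorted(cum, tx_starts, side="right") - 1
    pos = tx_starts.copy()
    remaining = np.full(n, read_len, dtype=np.int64)
    out_s, out_e = [], []
    while np.any(remaining > 0):
        in_seg_off = pos - cum[seg_idx]
        avail = seg_lens[seg_idx] - in_seg_off
        take = np.minimum(avail, remaining)
        bs = np.where(remaining > 0, seg_starts[seg_idx] + in_seg_off, -1)
        be = np.where(remaining > 0, bs + take, -1)
        out_s.append(bs)
        out_e.append(be)
        pos = pos + take
        remaining = remaining - take
        advance = remaining > 0
        seg_idx = np.where(advance, seg_idx + 1, seg_idx)
    return np.stack(out_s, axis=1), np.stack(out_e, axis=1)


def simulate_junction_reads(model: GeneModel, spec: RetentionSpec,
                            min_anchor: int = 8) -> SimulatedReads:
    """Draw a seeded read set from the retention mixture of ``model``.

    The molecule pool is the set of 2**n_introns isoform configurations with
    mixture weight prod(rho or 1-rho); a read's source configuration is drawn
    with probability proportional to weight x (isoform length - read_length
    + 1), i.e. uniformly over valid start positions in the pool. Total read
    count is Poisson(depth).
    """
    spec.validate(min_anchor)
    n_int = model.n_introns
    if n_int > _MAX_INTRONS_ENUM:
        raise ValueError(
            f"simulate_junction_reads enumerates isoforms; {n_int} introns "
            f"exceeds the supported {_MAX_INTRONS_ENUM}"
        )
    rho_tx = spec.rho_vector(n_int)
    # rho is given in transcript orientation; convert to genomic intron order
    rho = rho_tx if model.strand == "+" else rho_tx[::-1]
    L = int(spec.read_length)
    rng = np.random.default_rng(spec.seed)

    configs, weights = [], []
    for retained in product([False, True], repeat=n_int):
        w = float(np.prod(np.where(retained, rho, 1.0 - rho)))
        if w == 0.0:
            continue
        seg_s, seg_e = _isoform_segments(model, retained)
        tx_len = int((seg_e - seg_s).sum())
        n_starts = tx_len - L + 1
        if n_starts <= 0:
            raise ValueError(
                f"read_length {L} exceeds isoform length {tx_len} for "
                f"configuration {retained}"
            )
        configs.append((seg_s, seg_e, n_starts))
        weights.append(w * n_starts)

    weights = np.asarray(weights)
    p = weights / weights.sum()
    n_reads = int(rng.poisson(spec.depth))
    if n_reads == 0:
        empty = np.empty((0, 1), dtype=np.int64)
        return SimulatedReads(model.chrom, empty, empty.copy(),
                              reference_length=model.span[1] + 1000)
    cfg_of_read = rng.choice(len(configs), size=n_reads, p=p)

    all_s, all_e = [], []
    for ci, (seg_s, seg_e, n_starts) in enumerate(configs):
        m = int(np.sum(cfg_of_read == ci))
        if m == 0:
            continue
        tx_starts = rng.integers(0, n_starts, size=m)
        bs, be = _map_starts_to_blocks(tx_starts, L, seg_s, seg_e)
        all_s.append(bs)
        all_e.append(be)
    width = max(a.shape[1] for a in all_s)

    def pad(a):
        if a.shape[1] == width:
            return a
        padded = np.full((a.shape[0], width), -1, dtype=np.int64)
        padded[:, :a.shape[1]] = a
        return padded

    block_starts = np.concatenate([pad(a) for a in all_s])
    block_ends = np.concatenate([pad(a) for a in all_e])
    return SimulatedReads(model.chrom, block_starts, block_ends,
                          reference_length=model.span[1] + 1000)
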