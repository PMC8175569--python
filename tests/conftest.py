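import numpy as np
import pytest
from hypothesis import settings

import pirfish as pf

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_exon_model() -> pf.GeneModel:
    """One 500-bp intron between two 300-bp exons."""
    return pf.gen_gene_model(2, (300, 300), (500, 500), seed=0, gene_id="g")


@pytest.fixture(scope="session")
def multi_intron_model() -> pf.GeneModel:
    return pf.gen_gene_model(4, (150, 250), (400, 900), seed=3, gene_id="m")


@pytest.fixture(scope="session")
def snr5_field() -> pf.FishField:
    """A rendered dual-channel field at the low end of usable SNR."""
    return pf.simulate_field(n_signals=50, snr=5.0, seed=11)


def brute_force_junction_counts(blocks_list, model, min_anchor):
    """Independent per-read interval check of the junction counting rules.

    Deliberately a plain double loop over reads and introns with no shared
    code or arrays, used as the oracle for the vectorised counter.
    """
    counts = {iid: {"EI": 0, "IE": 0, "EE": 0, "mid_intron": 0}
              for iid in model.intron_ids()}
    for blocks in blocks_list:
        for iid, (istart, iend) in model.iter_introns():
            left = any(s <= istart - min_anchor and e >= istart + min_anchor
                       for s, e in blocks)
            right = any(s <= iend - min_anchor and e >= iend + min_anchor
                        for s, e in blocks)
            ee = any(
                blocks[k][1] == istart and blocks[k + 1][0] == iend
                and blocks[k][1] - blocks[k][0] >= min_anchor
                and blocks[k + 1][1] - blocks[k + 1][0] >= min_anchor
                for k in range(len(blocks) - 1))
            mid = (len(blocks) == 1
                   and blocks[0][0] >= istart + min_anchor
                   and blocks[0][1] <= iend - min_anchor)
            c = counts[iid]
            if model.strand == "+":
                c["EI"] += left
                c["IE"] += right
            else:
                c["EI"] += right
                c["IE"] += left
            c["EE"] += ee
            c["mid_intron"] += mid
    return counts


def random_block_reads(rng, model, n_reads, read_len=60):
    """Random single- or two-block reads scattered over a gene's span."""
    lo, hi = model.span
    lo -= 200
    hi += 200
    reads = []
    introns = list(model.introns)
    for _ in range(n_reads):
        kind = rng.random()
        if kind < 0.5:  # contiguous read anywhere
            s = int(rng.integers(lo, hi - read_len))
            reads.append([(s, s + read_len)])
        elif kind < 0.8 and introns:  # spliced read over a real intron
            istart, iend = introns[int(rng.integers(0, len(introns)))]
            a = int(rng.integers(1, read_len - 1))
            reads.append([(istart - a, istart), (iend, iend + read_len - a)])
        else:  # spliced read with an arbitrary (wrong) gap
            s = int(rng.integers(lo, hi - 2 * read_len))
            gap = int(rng.integers(1, 400))
            a = int(rng.integers(1, read_len - 1))
            reads.append([(s, s + a), (s + a + gap, s + gap + read_len)])
    return reads
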