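"""Transcript models: exon/intron structure of a single gene.

Coordinates are genomic, 0-based half-open throughout the package. A
:class:`GeneModel` stores the exon chain of one transcript; introns are
derived as the gaps between consecutive exons. Strand matters only for
transcript-orientation labelling (which intron boundary is the 5' splice
site); coordinates themselves are always on the forward genomic axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence, Tuple

import numpy as np
import pandas as pd

Interval = Tuple[int, int]

BIOTYPES = ("coding", "lncRNA", "other")


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron structure of one transcript, strand-aware.

    Parameters
    ----------
    gene_id : str
        Identifier used to derive intron ids (``"<gene_id>:I<k>"``, with k
        numbered 1..n in transcript orientation).
    chrom : str
        Reference sequence name.
    strand : {"+", "-"}
    exons : sequence of (start, end)
        Genomic intervals, 0-based half-open, ascending, non-overlapping.
    biotype : {"coding", "lncRNA", "other"}
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"biotype must be one of {BIOTYPES}, got {self.biotype!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if len(exons) < 1:
            raise ValueError("GeneModel needs at least one exon")
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval [{s}, {e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(
                    f"exons must be sorted and separated by >=1 bp introns: "
                    f"[{s0},{e0}) then [{s1},{e1})"
                )
        object.__setattr__(self, "exons", exons)

    # -- derived structure -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Interval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def n_introns(self) -> int:
        return self.n_exons - 1

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def intron_ids(self) -> Tuple[str, ...]:
        """Intron identifiers numbered 1..n in transcript orientation.

        On the minus strand intron 1 is the genomically *last* gap.
        """
        n = self.n_introns
        order = range(1, n + 1) if self.strand == "+" else range(n, 0, -1)
        return tuple(f"{self.gene_id}:I{k}" for k in order)

    def intron_by_id(self, intron_id: str) -> Interval:
        ids = self.intron_ids()
        try:
            return self.introns[ids.index(intron_id)]
        except ValueError:
            raise KeyError(f"unknown intron id {intron_id!r} for {self.gene_id}") from None

    def iter_introns(self) -> Iterator[tuple[str, Interval]]:
        yield from zip(self.intron_ids(), self.introns)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the intron structure (one row per intron)."""
        rows = [
            {"intron_id": iid, "gene_id": self.gene_id, "chrom": self.chrom,
             "strand": self.strand, "start": s, "end": e, "biotype": self.biotype}
            for iid, (s, e) in self.iter_introns()
        ]
        return pd.DataFrame(rows)


def gen_gene_model(
    n_exons: int,
    exon_len_range: Tuple[int, int] = (100, 300),
    intron_len_range: Tuple[int, int] = (300, 2000),
    biotype: str = "coding",
    strand: str = "+",
    seed: int = 0,
    gene_id: str | None = None,
    chrom: str = "chrSim",
    start: int = 1000,
) -> GeneModel:
    """Draw a random but valid :class:`GeneModel`.

    Exon and intron lengths are sampled uniformly (inclusive) from the given
    ranges; deterministic for a fixed seed.
    """
    if n_exons < 2:
        raise ValueError("n_exons must be >= 2 (a gene with no intron has no retention)")
    for name, (lo, hi) in (("exon_len_range", exon_len_range),
                           ("intron_len_range", intron_len_range)):
        if lo < 1 or hi < lo:
            raise ValueError(f"{name} must be a positive range, got {(lo, hi)}")
    rng = np.random.default_rng(seed)
    exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
    intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1,
                               size=n_exons - 1)
    exons = []
    pos = int(start)
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    if gene_id is None:
        gene_id = f"gene{seed}"
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     exons=tuple(exons), biotype=biotype)


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from the package's TSV exchange format.

    Columns: gene_id, chrom, strand, biotype, exon_starts, exon_ends where
    the last two are comma-separated ascending coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["exon_starts"]).rstrip(",").split(",")]
        ends = [int(x) for x in str(row["exon_ends"]).rstrip(",").split(",")]
        models.append(GeneModel(
            gene_id=row["gene_id"], chrom=row["chrom"], strand=row["strand"],
            exons=tuple(zip(starts, ends)),
            biotype=row.get("biotype", "coding") or "coding",
        ))
    return models


def write_gene_models(models: Sequence[GeneModel], path) -> None:
    rows = []
    for m in models:
        rows.append({
            "gene_id": m.gene_id, "chrom": m.chrom, "strand": m.strand,
            "biotype": m.biotype,
            "exon_starts": ",".join(str(s) for s, _ in m.exons),
            "exon_ends": ",".join(str(e) for _, e in m.exons),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
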