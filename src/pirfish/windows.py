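"""Splice-site-anchored intron windows and RBP peak coverage profiles.

An intron is summarised by nine windows in transcript orientation: an exonic
and an intronic flank (default 40 bp each) at the 5' splice site, five
near-equal tiles over the remaining intron interior, and an intronic plus an
exonic flank at the 3' splice site. Per RBP, peak intervals pooled over
experiments are merged and the fraction of covered base pairs is computed
per window; introns can then be clustered by their binding profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

Interval = Tuple[int, int]

ROLES_5_TO_3 = ("exonic_5flank", "intronic_5flank",
                "tile1", "tile2", "tile3", "tile4", "tile5",
                "intronic_3flank", "exonic_3flank")


@dataclass(frozen=True)
class Window:
    role: str
    start: int   # genomic, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowSet:
    """Ordered windows of one intron, 5'->3' in transcript orientation."""

    intron_id: str
    strand: str
    windows: Tuple[Window, ...]

    def roles(self) -> tuple[str, ...]:
        return tuple(w.role for w in self.windows)

    def by_role(self, role: str) -> Window:
        for w in self.windows:
            if w.role == role:
                return w
        raise KeyError(role)

    def window_of_position(self, pos: int) -> str | None:
        """Role of the window containing genomic position ``pos`` (or None)."""
        for w in self.windows:
            if w.start <= pos < w.end:
                return w.role
        return None


def _near_equal_tiles(total: int, n: int) -> list[int]:
    """Split ``total`` bp into n tiles differing by <= 1 bp, remainder first."""
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def build_intron_windows(
    intron: Interval,
    strand: str = "+",
    flank: int = 40,
    n_tiles: int = 5,
    intron_id: str = "intron",
) -> WindowSet:
    """Partition an intron (plus exonic flanks) into role-labelled windows.

    The intron interior (intron minus its two intronic flanks) is split into
    ``n_tiles`` near-equal tiles; any remainder goes to the 5'-most tiles in
    transcript orientation. On the minus strand, tile1 abuts the transcript
    5' splice site, i.e. the higher genomic coordinate.
    """
    start, end = intron
    length = end - start
    if length <= 2 * flank + n_tiles:
        raise ValueError(
            f"intron {intron_id} is too short ({length} bp) for flank="
            f"{flank} and {n_tiles} tiles (needs > {2 * flank + n_tiles} bp)")
    interior = length - 2 * flank
    tile_lens = _near_equal_tiles(interior, n_tiles)

    if strand == "+":
        tiles = []
        pos = start + flank
        for t in tile_lens:
            tiles.append((pos, pos + t))
            pos += t
        ordered = [
            Window("exonic_5flank", start - flank, start),
            Window("intronic_5flank", start, start + flank),
            *[Window(f"tile{i + 1}", s, e) for i, (s, e) in enumerate(tiles)],
            Window("intronic_3flank", end - flank, end),
            Window("exonic_3flank", end, end + flank),
        ]
    elif strand == "-":
        tiles = []
        pos = end - flank
        for t in tile_lens:  # tile1 gets the remainder, at the genomic top
            tiles.append((pos - t, pos))
            pos -= t
        ordered = [
            Window("exonic_5flank", end, end + flank),
            Window("intronic_5flank", end - flank, end),
            *[Window(f"tile{i + 1}", s, e) for i, (s, e) in enumerate(tiles)],
            Window("intronic_3flank", start, start + flank),
            Window("exonic_3flank", start - flank, start),
        ]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return WindowSet(intron_id=intron_id, strand=strand, windows=tuple(ordered))


# ---------------------------------------------------------------------------
# peaks and coverage


def merge_peaks(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or book-ended intervals coalesce."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"bad interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_peaks_by_rbp(
    peaks: Mapping[str, Iterable[Interval]]
) -> dict[str, list[Interval]]:
    """Merge pooled peak intervals per RBP (e.g. replicate/cell-line union)."""
    return {rbp: merge_peaks(ivs) for rbp, ivs in peaks.items()}


def window_coverage(windows: WindowSet,
                    merged: Sequence[Interval]) -> dict[str, float]:
    """Fraction of base pairs of each window covered by the merged peaks."""
    out = {}
    for w in windows.windows:
        covered = 0
        for s, e in merged:
            covered += max(0, min(e, w.end) - max(s, w.start))
        out[w.role] = covered / w.length
    return out


def coverage_matrix(
    window_sets: Sequence[WindowSet],
    peaks_by_rbp: Mapping[str, Iterable[Interval]],
) -> pd.DataFrame:
    """RBP x window coverage-fraction matrix.

    With several introns, columns are a (intron_id, role) MultiIndex in the
    fixed 5'->3' role order; with one intron, plain role columns.
    """
    merged = merge_peaks_by_rbp(peaks_by_rbp)
    cols, data = [], {}
    for ws in window_sets:
        cov_by_rbp = {rbp: window_coverage(ws, m) for rbp, m in merged.items()}
        for role in ws.roles():
            key = (ws.intron_id, role) if len(window_sets) > 1 else role
            cols.append(key)
            data[key] = [cov_by_rbp[rbp][role] for rbp in merged]
    df = pd.DataFrame(data, index=list(merged))
    df.index.name = "rbp"
    return df[cols]


# ---------------------------------------------------------------------------
# clustering


def cluster_introns(matrix: pd.DataFrame, method: str = "average",
                    metric: str = "euclidean"):
    """Agglomerative clustering of rows (introns or RBPs) of a profile matrix.

    Returns (linkage, leaf_order) where ``linkage`` is the SciPy linkage
    table and ``leaf_order`` the row labels in dendrogram order. SciPy's
    linkage breaks distance ties on the smaller cluster index, which makes
    the leaf order deterministic.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage
    from scipy.spatial.distance import pdist

    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    dist = pdist(matrix.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    order = [matrix.index[i] for i in leaves_list(Z)]
    return Z, order


# ---------------------------------------------------------------------------
# BED IO


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) rows from a BED3+ file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed_intervals(rows: Iterable[tuple], path, name: str = ".",
                        score: int = 0, strand: str = ".") -> None:
    """Write (chrom, start, end[, name, score, strand]) rows as BED6."""
    with open(path, "w") as fh:
        for row in rows:
            chrom, start, end = row[:3]
            rest = list(row[3:]) + [name, score, strand][len(row) - 3:]
            fh.write(f"{chrom}\t{start}\t{end}\t{rest[0]}\t{rest[1]}\t{rest[2]}\n")
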