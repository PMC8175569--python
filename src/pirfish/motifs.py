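"""PWM motif scanning with exact null p-values.

A position weight matrix is scored as log-odds (log2) against a background
base composition at every position of a sequence. The p-value of a score s
is P(score >= s) for a random background word, computed *exactly* by
dynamic programming over the discretised score distribution — the same
construction FIMO uses. With the default 0.01-bit discretisation the DP is
exact for the integerised scores, and enumeration over all 4^w words
reproduces it bit-for-bit for short motifs.

Hits below a raw p-value threshold (default 1e-4) are retained; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
# sentinel for log2(0) integer scores; large enough to dominate any finite
# sum of per-position scores yet safe from int64 overflow over long motifs
_NEG_INF = -(10 ** 12)

DEFAULT_STEP = 0.01          # bits per discretisation step
DEFAULT_P_THRESHOLD = 1e-4


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities of one motif.

    ``probs`` has shape (w, 4) over A,C,G,T (U is read as T); rows must sum
    to 1. ``background`` is the null base composition (uniform by default).
    """

    motif_id: str
    rbp: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (w, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-4) or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / background) with -inf where the motif probability is 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    @classmethod
    def from_consensus(cls, consensus: str, motif_id: str, rbp: str,
                       background: Sequence[float] | None = None) -> "PWM":
        """Degenerate PWM putting probability 1 on each consensus base."""
        seq = consensus.upper().replace("U", "T")
        probs = np.zeros((len(seq), 4))
        for i, b in enumerate(seq):
            probs[i, _IDX[b]] = 1.0
        return cls(motif_id, rbp, probs,
                   np.asarray(background) if background is not None
                   else np.full(4, 0.25))


# ---------------------------------------------------------------------------
# exact null distribution


def _integer_scores(pwm: PWM, step: float) -> np.ndarray:
    lo = pwm.log_odds()
    ints = np.full(lo.shape, _NEG_INF, dtype=np.int64)
    finite = np.isfinite(lo)
    ints[finite] = np.round(lo[finite] / step).astype(np.int64)
    return ints


def score_distribution(pwm: PWM, step: float = DEFAULT_STEP):
    """Exact null distribution of the discretised score.

    Returns (offset, probs, dead_mass): ``probs[k]`` is the probability that
    a background word scores ``offset + k`` (in integer steps); ``dead_mass``
    is the probability of words hitting a zero-probability motif position
    (score -inf, below every finite score).
    """
    ints = _integer_scores(pwm, step)
    finite = ints > _NEG_INF // 2
    bg = pwm.background
    offset = 0
    dist = np.array([1.0])
    dead = 0.0
    for pos in range(pwm.width):
        vals = ints[pos]
        fin = finite[pos]
        if not fin.any():
            return 0, np.array([]), 1.0
        vmin, vmax = vals[fin].min(), vals[fin].max()
        new = np.zeros(len(dist) + (vmax - vmin), dtype=float)
        alive = dist.sum()
        for b in range(4):
            if fin[b]:
                new[vals[b] - vmin: vals[b] - vmin + len(dist)] += bg[b] * dist
            else:
                dead += bg[b] * alive
        dist = new
        offset += int(vmin)
    return offset, dist, dead


def score_pvalue(pwm: PWM, score_int: int, step: float = DEFAULT_STEP,
                 _cache={}) -> float:
    """P(null integer score >= score_int), exact.

    Words hitting a zero-probability motif position score minus infinity and
    therefore never reach any finite query score; for a query at or below
    the smallest finite score the p-value is the total finite mass.
    """
    key = (pwm.motif_id, pwm.probs.tobytes(), pwm.background.tobytes(), step)
    if key not in _cache:
        offset, dist, _ = score_distribution(pwm, step)
        tail = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])
        _cache[key] = (offset, tail)
    offset, tail = _cache[key]
    k = score_int - offset
    if k <= 0:
        return float(tail[0])
    if k >= len(tail):
        return 0.0
    return float(tail[k])


# ---------------------------------------------------------------------------
# scanning


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    codes = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _IDX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(b)] = i
    return codes


_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    step: float = DEFAULT_STEP,
    both_strands: bool = False,
    sequence_id: str = "",
) -> pd.DataFrame:
    """Scan a sequence for motif hits with exact p-value < ``p_threshold``.

    Positions overlapping N (or any non-ACGT character) are excluded. By
    default only the given strand is scanned (RNA motifs on a transcript
    sequence); ``both_strands=True`` also scans the reverse complement,
    reporting hit positions on the forward sequence.

    Returns columns: sequence_id, motif_id, rbp, position (0-based start on
    the forward sequence), strand, score (bits), p.
    """
    codes = _encode(sequence)
    w = pwm.width
    rows = []
    if len(codes) >= w:
        strands = [("+", codes)]
        if both_strands:
            rc = _COMPLEMENT[codes[::-1].clip(min=0)]
            rc[codes[::-1] < 0] = -1
            strands.append(("-", rc))
        ints = _integer_scores(pwm, step)
        n_pos = len(codes) - w + 1
        for strand, cs in strands:
            total = np.zeros(n_pos, dtype=np.int64)
            valid = np.ones(n_pos, dtype=bool)
            for k in range(w):
                window = cs[k:k + n_pos]
                valid &= window >= 0
                # clip keeps one sentinel from stacking into int64 overflow
                total = np.maximum(
                    total + np.where(window >= 0,
                                     ints[k, window.clip(min=0)], 0),
                    _NEG_INF)
            for pos in np.nonzero(valid)[0]:
                s = int(total[pos])
                if s <= _NEG_INF // 2:
                    continue
                p = score_pvalue(pwm, s, step)
                if p < p_threshold:
                    fwd_pos = pos if strand == "+" else len(codes) - w - pos
                    rows.append({
                        "sequence_id": sequence_id,
                        "motif_id": pwm.motif_id, "rbp": pwm.rbp,
                        "position": int(fwd_pos), "strand": strand,
                        "score": s * step, "p": p,
                    })
    return pd.DataFrame(
        rows, columns=["sequence_id", "motif_id", "rbp", "position",
                       "strand", "score", "p"])


def scan_pwms(sequences: Mapping[str, str], pwms: Sequence[PWM],
              p_threshold: float = DEFAULT_P_THRESHOLD,
              both_strands: bool = False) -> pd.DataFrame:
    """Scan several sequences with several PWMs; concatenated hit table."""
    frames = [scan_pwm(seq, pwm, p_threshold=p_threshold,
                       both_strands=both_strands, sequence_id=sid)
              for sid, seq in sequences.items() for pwm in pwms]
    if not frames:
        return scan_pwm("", PWM.from_consensus("A", "empty", "empty"))
    return pd.concat(frames, ignore_index=True)


def collate_max_score(hits: pd.DataFrame, windows, offset: int = 0
                      ) -> pd.DataFrame:
    """Per-RBP, per-window maximum hit score matrix.

    ``windows`` is a :class:`~pirfish.windows.WindowSet`; hit positions are
    sequence offsets converted to genomic coordinates by adding ``offset``
    (the genomic start of the scanned sequence). A hit belongs to the window
    containing its start position. RBPs with no hit in a window get NaN;
    RBPs present in ``hits`` keep their row even if entirely empty.
    """
    roles = list(windows.roles())
    rbps = sorted(hits["rbp"].unique())
    mat = pd.DataFrame(np.nan, index=rbps, columns=roles)
    mat.index.name = "rbp"
    for _, h in hits.iterrows():
        role = windows.window_of_position(int(h["position"]) + offset)
        if role is None:
            continue
        prev = mat.at[h["rbp"], role]
        if np.isnan(prev) or h["score"] > prev:
            mat.at[h["rbp"], role] = h["score"]
    return mat


# ---------------------------------------------------------------------------
# MEME minimal format IO


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write motifs in MEME minimal text format."""
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "",
             "Background letter frequencies",
             " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)), ""]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.motif_id} {pwm.rbp}")
        # a large nsites keeps readers that reconstruct counts from rounding
        # the probabilities (Biopython does) at full written precision
        lines.append(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 1000000 E= 0")
        for row in pwm.probs:
            lines.append(" " + " ".join(f"{p:.6f}" for p in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme(path) -> list[PWM]:
    """Read motifs from MEME minimal text format.

    Matrix parsing is delegated to Biopython; the alternate name on each
    MOTIF line (used here to carry the RBP) is recovered from the raw text
    since Biopython's minimal reader drops it.
    """
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        text = fh.read()
    alt_names = {}
    for line in text.splitlines():
        if line.startswith("MOTIF"):
            parts = line.split()
            alt_names[parts[1]] = parts[2] if len(parts) > 2 else parts[1]
    parsed = bio_motifs.parse(io.StringIO(text), "minimal")
    out = []
    for m in parsed:
        probs = np.column_stack([np.asarray(m.pwm[b]) for b in ALPHABET])
        bg = np.array([m.background[b] for b in ALPHABET])
        out.append(PWM(m.name, alt_names.get(m.name, m.name), probs, bg))
    return out
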