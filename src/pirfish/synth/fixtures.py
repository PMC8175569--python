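"""Peak and motif fixtures over toy introns, with planted truth.

Generates, per RBP, BED-style peak interval sets planted preferentially in
requested window roles (e.g. the splice-site flanks) so that window
enrichment is recoverable; random intron sequences with a known consensus
motif planted at recorded positions; and a truth table of planted base
pairs / positions for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genes import GeneModel
from ..motifs import ALPHABET, PWM
from ..windows import WindowSet, build_intron_windows


@dataclass
class PeakMotifFixture:
    """Planted peak/motif data for a set of introns."""

    window_sets: list[WindowSet]
    peaks_by_rbp: dict[str, list[tuple[int, int]]]
    sequences: dict[str, str]                  # intron_id -> sequence
    sequence_offsets: dict[str, int]           # genomic start of each sequence
    pwms: list[PWM]
    truth: pd.DataFrame                        # planted bp per rbp/intron/role
    motif_truth: pd.DataFrame                  # planted motif positions


def gen_peak_and_motif_fixtures(
    model: GeneModel,
    n_rbps: int = 4,
    planted_roles: tuple[str, ...] = ("intronic_5flank", "intronic_3flank"),
    flank: int = 40,
    n_tiles: int = 5,
    planted_cover: float = 0.5,
    background_cover: float = 0.05,
    consensus: str = "ACGTACGT",
    seed: int = 0,
) -> PeakMotifFixture:
    """Plant peaks in the requested window roles and motifs in sequences.

    Each RBP receives one peak per intron per planted role covering
    ``planted_cover`` of that window, plus sparse background peaks covering
    ``background_cover`` of the remaining windows. Every intron sequence is
    random with the consensus motif planted once at a recorded position.
    """
    if n_rbps < 1:
        raise ValueError("n_rbps must be >= 1")
    rng = np.random.default_rng(seed)
    window_sets = [build_intron_windows(iv, model.strand, flank=flank,
                                        n_tiles=n_tiles, intron_id=iid)
                   for iid, iv in model.iter_introns()]
    rbps = [f"RBP{k + 1}" for k in range(n_rbps)]

    peaks: dict[str, list[tuple[int, int]]] = {r: [] for r in rbps}
    truth_rows = []
    for rbp in rbps:
        for ws in window_sets:
            for w in ws.windows:
                if w.role in planted_roles:
                    span = max(1, int(round(planted_cover * w.length)))
                    start = int(rng.integers(w.start, w.end - span + 1))
                    peaks[rbp].append((start, start + span))
                    planted = span
                elif background_cover > 0 and rng.random() < background_cover:
                    span = max(1, int(round(0.1 * w.length)))
                    start = int(rng.integers(w.start, w.end - span + 1))
                    peaks[rbp].append((start, start + span))
                    planted = span
                else:
                    planted = 0
                truth_rows.append({"rbp": rbp, "intron_id": ws.intron_id,
                                   "role": w.role, "planted_bp": planted,
                                   "window_length": w.length})
    truth = pd.DataFrame(truth_rows)

    # intron sequences with one planted consensus occurrence each
    motif = consensus.upper().replace("U", "T")
    sequences, offsets, motif_rows = {}, {}, []
    for iid, (s, e) in model.iter_introns():
        length = e - s
        seq = rng.choice(list(ALPHABET), size=length)
        pos = int(rng.integers(0, length - len(motif) + 1))
        seq[pos:pos + len(motif)] = list(motif)
        # break accidental extra occurrences without touching the planted one
        text = "".join(seq)
        for _ in range(20):
            extra = [o for o in _occurrences(text, motif) if o != pos]
            if not extra:
                break
            for o in extra:
                # mutate a base of the stray occurrence outside [pos, pos+w)
                j = o + len(motif) - 1 if o > pos else o
                text = text[:j] + _mutate(text[j], rng) + text[j + 1:]
        sequences[iid] = text
        offsets[iid] = s
        motif_rows.append({"intron_id": iid, "position": pos,
                           "genomic_position": s + pos, "consensus": motif})
    pwms = [PWM.from_consensus(motif, motif_id="planted", rbp=rbps[0])]
    return PeakMotifFixture(window_sets, peaks, sequences, offsets, pwms,
                            truth, pd.DataFrame(motif_rows))


def _occurrences(text: str, motif: str) -> list[int]:
    out, start = [], 0
    while True:
        i = text.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _mutate(base: str, rng) -> str:
    choices = [b for b in ALPHABET if b != base]
    return choices[int(rng.integers(0, 3))]


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
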