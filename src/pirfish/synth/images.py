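"""Synthetic dual-channel smFISH fields with ground truth.

A field is a 3D stack (z, y, x) per channel: an exon-probe channel, an
intron-probe channel and a DNA-stain channel. Cells are laid out on a grid;
each interphase cell has a disk-shaped nucleus. Single transcripts are
rendered as anisotropic Gaussian spots; three signal classes mirror what
dual-colour probing distinguishes:

* ``unspliced_pair`` — an exon spot and an intron spot co-localised within a
  small pairing offset (an intron-retaining transcript);
* ``spliced_exon_only`` — an exon spot alone (the intron was excised);
* ``solo_intron`` — an intron spot alone (a stable excised intron).

SNR is defined as Gaussian peak amplitude over background noise standard
deviation. Noise is Gaussian by default (Poisson behind a flag). The
generator returns the rendered stacks together with the exact truth used to
place every spot, so downstream detection/quantification can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CLASSES = ("unspliced_pair", "spliced_exon_only", "solo_intron")


class PlacementError(RuntimeError):
    """Raised when the requested spots cannot be placed in the stack."""


@dataclass(frozen=True)
class SignalTruth:
    """One ground-truth transcript signal."""

    signal_class: str            # one of CLASSES
    compartment: str             # "nuclear" | "cytoplasmic"
    cell_id: int
    exon_zyx: tuple[float, float, float] | None
    intron_zyx: tuple[float, float, float] | None

    def __post_init__(self):
        if self.signal_class not in CLASSES:
            raise ValueError(f"unknown signal class {self.signal_class!r}")
        has_e, has_i = self.exon_zyx is not None, self.intron_zyx is not None
        expected = {"unspliced_pair": (True, True),
                    "spliced_exon_only": (True, False),
                    "solo_intron": (False, True)}[self.signal_class]
        if (has_e, has_i) != expected:
            raise ValueError(
                f"{self.signal_class} signal must have exon/intron spots "
                f"{expected}, got {(has_e, has_i)}"
            )


@dataclass
class FieldTruth:
    """Ground truth for one rendered field."""

    shape: tuple[int, int, int]
    signals: list[SignalTruth]
    nucleus_mask: np.ndarray     # 2D labels, 0 = background
    cell_mask: np.ndarray        # 2D labels, 0 = background
    mitotic: dict[int, bool]
    pairing_radius: float

    def validate(self) -> None:
        """Assert the class/compartment invariants for every signal."""
        for s in self.signals:
            anchor = s.exon_zyx if s.exon_zyx is not None else s.intron_zyx
            y, x = int(round(anchor[1])), int(round(anchor[2]))
            cell = int(self.cell_mask[y, x])
            if cell != s.cell_id:
                raise AssertionError(
                    f"signal at ({y},{x}) labelled cell {s.cell_id} but mask "
                    f"says {cell}")
            in_nuc = self.nucleus_mask[y, x] == s.cell_id
            if (s.compartment == "nuclear") != bool(in_nuc):
                raise AssertionError(
                    f"signal at ({y},{x}) compartment {s.compartment} "
                    f"disagrees with nucleus mask")
            if s.signal_class == "unspliced_pair":
                d = np.hypot(s.exon_zyx[1] - s.intron_zyx[1],
                             s.exon_zyx[2] - s.intron_zyx[2])
                if d > self.pairing_radius + 1e-9:
                    raise AssertionError("pair separation exceeds pairing radius")

    def per_cell_truth(self) -> pd.DataFrame:
        """True per-cell compartmentalised counts and nuclear PIR."""
        cells = sorted(set(s.cell_id for s in self.signals)
                       | set(self.mitotic))
        rows = []
        for cid in cells:
            sig = [s for s in self.signals if s.cell_id == cid]

            def count(cls, comp=None):
                return sum(1 for s in sig if s.signal_class == cls
                           and (comp is None or s.compartment == comp))

            un_n = count("unspliced_pair", "nuclear")
            un_c = count("unspliced_pair", "cytoplasmic")
            sp_n = count("spliced_exon_only", "nuclear")
            sp_c = count("spliced_exon_only", "cytoplasmic")
            exon_nuc = un_n + sp_n
            rows.append({
                "cell_id": cid,
                "mitotic": bool(self.mitotic.get(cid, False)),
                "unspliced_nuclear": un_n, "unspliced_cytoplasmic": un_c,
                "spliced_nuclear": sp_n, "spliced_cytoplasmic": sp_c,
                "solo_intron": count("solo_intron"),
                "exon_nuclear": exon_nuc,
                "exon_total": exon_nuc + un_c + sp_c,
                "nuclear_pir": (100.0 * un_n / exon_nuc) if exon_nuc else np.nan,
            })
        return pd.DataFrame(rows)


@dataclass
class FishField:
    """Rendered field: three channels plus the generating truth/parameters."""

    exon: np.ndarray
    intron: np.ndarray
    dna: np.ndarray
    truth: FieldTruth
    params: dict

    def write(self, outdir) -> None:
        """Write per-channel TIFFs, label masks and a sidecar parameter JSON."""
        import tifffile
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in (("exon", self.exon), ("intron", self.intron),
                          ("dna", self.dna)):
            tifffile.imwrite(outdir / f"{name}.tif", arr)
        tifffile.imwrite(outdir / "nucleus_mask.tif",
                         self.truth.nucleus_mask.astype(np.uint16))
        tifffile.imwrite(outdir / "cell_mask.tif",
                         self.truth.cell_mask.astype(np.uint16))
        (outdir / "params.json").write_text(
            json.dumps(self.params, sort_keys=True, indent=2))
        self.truth.per_cell_truth().to_csv(outdir / "truth_cells.tsv",
                                           sep="\t", index=False)
        rows = []
        for s in self.truth.signals:
            rows.append({
                "signal_class": s.signal_class, "compartment": s.compartment,
                "cell_id": s.cell_id,
                "exon_z": s.exon_zyx[0] if s.exon_zyx else "",
                "exon_y": s.exon_zyx[1] if s.exon_zyx else "",
                "exon_x": s.exon_zyx[2] if s.exon_zyx else "",
                "intron_z": s.intron_zyx[0] if s.intron_zyx else "",
                "intron_y": s.intron_zyx[1] if s.intron_zyx else "",
                "intron_x": s.intron_zyx[2] if s.intron_zyx else "",
            })
        pd.DataFrame(rows).to_csv(outdir / "truth_signals.tsv", sep="\t",
                                  index=False)


# ---------------------------------------------------------------------------
# geometry and rendering helpers


def _cell_layout(shape, n_cells):
    """Rectangular cell grid with centred disk nuclei; returns label masks."""
    _, ny, nx = shape
    g = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / g))
    cell_mask = np.zeros((ny, nx), dtype=np.int32)
    nucleus_mask = np.zeros((ny, nx), dtype=np.int32)
    rects, nuclei = {}, {}
    h, w = ny // rows, nx // g
    cid = 0
    for r in range(rows):
        for c in range(g):
            if cid >= n_cells:
                break
            cid += 1
            y0, x0 = r * h, c * w
            y1 = ny if r == rows - 1 else (r + 1) * h
            x1 = nx if c == g - 1 else (c + 1) * w
            cell_mask[y0:y1, x0:x1] = cid
            cy, cx = (y0 + y1) / 2.0, (x0 + x1) / 2.0
            rad = 0.30 * min(y1 - y0, x1 - x0)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2
            nucleus_mask[y0:y1, x0:x1][disk] = cid
            rects[cid] = (y0, y1, x0, x1)
            nuclei[cid] = (cy, cx, rad)
    return cell_mask, nucleus_mask, rects, nuclei


def _render_spots(shape, spots, amplitude, psf_sigma):
    """Additively render anisotropic Gaussian spots into a float stack."""
    nz, ny, nx = shape
    img = np.zeros(shape, dtype=np.float64)
    sz, sy, sx = psf_sigma
    rz, ry, rx = (int(np.ceil(4 * s)) for s in psf_sigma)
    for (z, y, x) in spots:
        z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 1)
        y0, y1 = max(0, int(y) - ry), min(ny, int(y) + ry + 1)
        x0, x1 = max(0, int(x) - rx), min(nx, int(x) + rx + 1)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        img[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(
            -((zz - z) ** 2 / (2 * sz ** 2)
              + (yy - y) ** 2 / (2 * sy ** 2)
              + (xx - x) ** 2 / (2 * sx ** 2)))
    return img


def _finalize(img, background, noise_sd, rng, noise_model):
    if noise_model == "gaussian":
        img = img + background + rng.normal(0.0, noise_sd, size=img.shape)
    elif noise_model == "poisson":
        # scale so that the background's shot noise sd matches noise_sd
        gain = background / max(noise_sd, 1e-9) ** 2
        img = rng.poisson(np.maximum(img + background, 0) * gain) / gain
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# the generator


def simulate_field(
    shape: tuple[int, int, int] = (12, 256, 256),
    n_cells: int = 4,
    n_signals: int = 50,
    class_probs: Sequence[float] = (0.55, 0.35, 0.10),
    p_nuclear: dict | None = None,
    mitotic_cells: Sequence[int] = (),
    pairing_radius: float = 1.5,
    min_separation: float = 8.0,
    psf_sigma: tuple[float, float, float] = (1.0, 1.3, 1.3),
    amplitude: float = 500.0,
    background: float = 200.0,
    snr: float = 10.0,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> FishField:
    """Render one dual-channel smFISH field with known truth.

    ``class_probs`` orders (unspliced_pair, spliced_exon_only, solo_intron);
    ``p_nuclear`` gives the probability that a signal of each class sits in
    the nucleus (defaults: unspliced 0.9, spliced 0.3, solo intron 0.9).
    Signal anchors keep ``min_separation`` pixels apart in (y, x) so that
    individual transcripts stay resolvable, emulating sub-saturation spot
    densities; exceeding the achievable density raises PlacementError.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if abs(sum(class_probs) - 1.0) > 1e-9 or len(class_probs) != 3:
        raise ValueError("class_probs must be 3 values summing to 1")
    p_nuclear = {"unspliced_pair": 0.9, "spliced_exon_only": 0.3,
                 "solo_intron": 0.9, **(p_nuclear or {})}
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    cell_mask, nucleus_mask, rects, nuclei = _cell_layout(shape, n_cells)
    mitotic = {cid: (cid in set(mitotic_cells)) for cid in rects}

    margin = 6.0
    signals: list[SignalTruth] = []
    anchors: list[tuple[float, float]] = []

    def sample_position(cid, compartment):
        y0, y1, x0, x1 = rects[cid]
        cy, cx, rad = nuclei[cid]
        for _ in range(300):
            y = rng.uniform(y0 + margin, y1 - margin)
            x = rng.uniform(x0 + margin, x1 - margin)
            r = np.hypot(y - cy, x - cx)
            if compartment == "nuclear" and r > rad - 3.0:
                continue
            if compartment == "cytoplasmic" and r < rad + 3.0:
                continue
            if any(np.hypot(y - ay, x - ax) < min_separation
                   for ay, ax in anchors):
                continue
            return y, x
        raise PlacementError(
            f"could not place a {compartment} spot in cell {cid}; "
            f"requested density too high for min_separation={min_separation}")

    cell_ids = list(rects)
    for i in range(n_signals):
        cid = cell_ids[i % len(cell_ids)]
        cls = CLASSES[rng.choice(3, p=np.asarray(class_probs))]
        comp = "nuclear" if rng.random() < p_nuclear[cls] else "cytoplasmic"
        y, x = sample_position(cid, comp)
        anchors.append((y, x))
        z = rng.uniform(2.0, nz - 3.0)
        exon = intron = None
        if cls in ("unspliced_pair", "spliced_exon_only"):
            exon = (z, y, x)
        if cls == "unspliced_pair":
            theta = rng.uniform(0, 2 * np.pi)
            rr = rng.uniform(0, pairing_radius)
            dz = rng.uniform(-0.5, 0.5)
            intron = (float(np.clip(z + dz, 2.0, nz - 3.0)),
                      y + rr * np.sin(theta), x + rr * np.cos(theta))
        elif cls == "solo_intron":
            intron = (z, y, x)
        signals.append(SignalTruth(cls, comp, cid, exon, intron))

    truth = FieldTruth(shape=shape, signals=signals,
                       nucleus_mask=nucleus_mask, cell_mask=cell_mask,
                       mitotic=mitotic, pairing_radius=pairing_radius)
    truth.validate()

    noise_sd = amplitude / snr
    exon_img = _render_spots(shape, [s.exon_zyx for s in signals
                                     if s.exon_zyx is not None],
                             amplitude, psf_sigma)
    intron_img = _render_spots(shape, [s.intron_zyx for s in signals
                                       if s.intron_zyx is not None],
                               amplitude, psf_sigma)
    # DNA channel: bright smooth nuclei (interphase) / condensed blobs (mitosis)
    dna2d = np.zeros((ny, nx), dtype=np.float64)
    for cid, (cy, cx, rad) in nuclei.items():
        yy, xx = np.mgrid[0:ny, 0:nx]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        scale = 0.55 if mitotic[cid] else 1.0
        dna2d += 1200.0 * (r2 <= (rad * scale) ** 2)
    from scipy.ndimage import gaussian_filter
    dna2d = gaussian_filter(dna2d, 1.0)
    dna_img = np.broadcast_to(dna2d, shape).copy()

    exon_st = _finalize(exon_img, background, noise_sd, rng, noise_model)
    intron_st = _finalize(intron_img, background, noise_sd, rng, noise_model)
    dna_st = _finalize(dna_img, background, noise_sd, rng, noise_model)

    params = dict(shape=list(shape), n_cells=n_cells, n_signals=n_signals,
                  class_probs=list(class_probs), p_nuclear=p_nuclear,
                  mitotic_cells=sorted(set(mitotic_cells)),
                  pairing_radius=pairing_radius, min_separation=min_separation,
                  psf_sigma=list(psf_sigma), amplitude=amplitude,
                  background=background, snr=snr, noise_model=noise_model,
                  seed=seed)
    return FishField(exon_st, intron_st, dna_st, truth, params)
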