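# Methods

This note documents the models implemented in `pirfish`, the parameter
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that matter for reproducing its
output. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Percent intron retention from junction reads

For one intron with boundaries (s, e) in 0-based half-open genomic
coordinates, three read categories are counted from spliced alignments
(CIGAR M/N only):

- **EI** — reads whose contiguous aligned block spans the upstream
  (transcript 5′) exon–intron boundary with at least `min_anchor` bp on each
  side;
- **IE** — likewise for the downstream intron–exon boundary;
- **EE** — reads with an alignment gap matching the intron exactly
  (gap start = s, gap end = e) and ≥ `min_anchor` aligned bp flanking the
  gap;
- **mid-intron** — single-block reads fully inside
  [s + min_anchor, e − min_anchor); tallied as corroborating evidence but
  not part of the PIR formula, which is stated purely in junction terms.

PIR = 100 · r̄ / (r̄ + EE) with r̄ = (EI + IE)/2, the mean retention-read
count. Strand affects only which boundary is labelled upstream: on the minus
strand EI refers to the genomically right boundary.

Quality filters:

- **Coverage**: the estimate is undefined (`low_coverage`) when
  EI + IE + EE < `min_total` (default 15). In single-junction modes the
  filter applies to the reduced evidence actually used (EI + EE or
  IE + EE) — re-computation from one junction should not be allowed to pass
  on the strength of reads it discards.
- **Balance**: an exact two-sided binomial test of EI successes in EI + IE
  trials at p = 0.5; p < α (default 0.05) marks the intron `imbalanced` and
  leaves PIR undefined. Strong imbalance typically betrays an overlapping
  alternative donor/acceptor that inflates one boundary; the caller can then
  re-estimate from the clean junction alone (`recalc_single_junction`,
  side = upstream or downstream), which skips the balance test.

Undefined PIR propagates as an explicit missing value (None/NaN), never as
0 or 100. Per-gene summaries take max and min PIR over introns with a
defined estimate; ECDFs are computed within biotype classes (coding, lncRNA,
other); `percentile_rank(v, pop)` = 100 · #{p ≤ v}/N with ties counted as ≤.

`min_anchor` defaults to 8 bp — long enough that an anchor is unlikely to be
a spurious partial match at typical read lengths, short enough to keep
junction-read yield high; it is recorded alongside the counts and is
configurable everywhere.

## The read simulator

`simulate_junction_reads` draws reads from a molecule pool in which each
intron of a gene is independently retained with probability ρ (its true
retention fraction) or spliced out. The 2^k isoform configurations are
enumerated with mixture weights ∏ ρᵢ / (1 − ρᵢ); a read's source
configuration is drawn with probability proportional to

  weight × (isoform length − read length + 1),

i.e. uniformly over **valid read start positions in the pool**, and the
start is then uniform within the configuration. Total read count is
Poisson(depth). This is the simplest model under which the junction-ratio
estimator is unbiased: every junction's expected read count is exactly
proportional to the fraction of molecules carrying it, and EI and IE are
exchangeable (binomial with p = 1/2 given their sum). Weighting by raw
isoform length instead would leave a bias of order read_length/isoform_length
between isoforms of different lengths — a few percentage points of PIR at
the simulation sizes used here, which is why valid-start weighting was
chosen.

Reads are emitted pre-aligned as genomic blocks (M runs separated by N
gaps); there is no sequencing-error or alignment model, and no attempt at
positional coverage bias. SAM serialisation (via pysam) carries a minimal
header and M/N CIGARs only.

Simulation sizes used by the tests and the acceptance script: a two-exon
gene (300-bp exons, 500-bp intron), read length 100, depth 50,000 for
recovery (100 replicates per ρ ∈ {0.1, 0.3, 0.5, 0.9}) and depth 20,000 for
the 1,000-replicate balance calibration — large enough that binomial
sampling error alone bounds the estimator within the stated tolerances,
small enough to run in seconds.

## smFISH simulation and quantification

### Generator

A field is a (z, y, x) stack per channel at 16-bit depth, default
12 × 256 × 256. Cells are rectangular grid territories with a disk nucleus
(radius 0.3 × the cell's short side); label masks for cells and nuclei are
emitted alongside. Each transcript signal is one of three classes —
`unspliced_pair` (exon + intron spot within a pairing offset, default
≤ 1.5 px in (y, x) and ≤ 0.5 in z), `spliced_exon_only`, `solo_intron` — and
is placed in the nucleus or cytoplasm according to per-class probabilities
(defaults: unspliced 0.9, spliced 0.3, solo intron 0.9, giving realistically
high nuclear PIR). Signal anchors keep a minimum separation (default 8 px)
and a 3-px margin from the nucleus boundary, emulating sub-saturation spot
densities where single molecules are resolvable; infeasible requests raise
`PlacementError` rather than silently crowding.

Spots are rendered as anisotropic Gaussians with σ = (1.0, 1.3, 1.3) voxels
(z, y, x), emulating the axial elongation of a widefield PSF at a 200–250 nm
z-step. SNR is defined as peak amplitude over background noise standard
deviation; noise is additive Gaussian by default (analytically convenient
and a fair approximation of a deconvolved, background-subtracted image),
with a Poisson option (`noise_model="poisson"`, gain set so the background
shot-noise SD matches the requested SNR). The DNA channel renders smoothed
nucleus disks (smaller condensed blobs for cells flagged mitotic). Every
generator call is driven by one explicit seed; identical parameters give
byte-identical TIFF and truth-table outputs, and the class/compartment
invariants of the truth are asserted on emission.

What the generator does **not** emulate: deconvolution artefacts, chromatic
aberration or channel misregistration, autofluorescent texture, transcription
site foci (multi-RNA intensity outliers), or cell-to-cell background
variation. Passing the recovery tests therefore demonstrates the
correctness of the quantification logic and its robustness to Gaussian
noise at a stated SNR and spot density — not performance on raw microscope
data, which typically requires per-dataset threshold tuning.

### Quantification

Detection: scale-normalised Laplacian-of-Gaussian band-pass at the spot
scale, local maxima (minimum separation 3 px), a robust threshold of k
MAD-based standard deviations of the filtered response, and sub-pixel
refinement by local centroid. Defaults k = 6 in 2D and k = 7 in 3D sit above
the observed noise-maximum ceiling of a 256² / 12 × 256² field, so blank
images yield zero detections. By default the end-to-end path
(`quantify_field`) detects in 3D — the matched anisotropic filter separates
dim spots (which lose up to ~25% of peak intensity when they fall between
z-planes) from projection-noise maxima far better than detection on the max
projection — and then quantifies on the (y, x) coordinates, i.e. the
max-projection geometry; `detect_3d=False` selects projection-based
detection.

Co-localisation: candidate exon–intron pairs within a radius (default 3 px
on the projection — "overlapping" is operationalised as centre distance
within the radius, since diffraction-limited spots of ~1.3 px σ overlap
visually at that distance) are accepted greedily in order of increasing
distance, ties broken by smaller exon then intron index. Because enlarging
the radius only appends longer candidate edges after the ones already
accepted, the pair set grows monotonically with the radius. On fields where
distinct signals are separated by more than the radius (the regime the
generator enforces and the one in which counting single molecules is
meaningful at all), the greedy matching attains maximum cardinality; this is
verified against SciPy's maximum bipartite matching in the tests.

Compartment assignment: a spot is nuclear iff its rounded centre pixel
carries the cell's label in the nucleus mask — no partial-overlap logic.
Spots outside any cell label are dropped and counted. Solo introns never
enter transcript totals. Mitotic cells are identified by provided flags (no
automated mitosis detection); mitosis tables report whole-cell means and
SDs per stage, with no compartment split since mitotic cells have no
nuclear envelope.

Segmentation: provided label masks are the faithful path (the quantification
this package mirrors was done with manual outlining). The automated fallback
(Otsu threshold on the DNA stain, hole filling, connected components,
minimum-area filter, optional unbounded label expansion for surrogate cell
territories) is a convenience, not a reproduction.

## Intron windows, peak coverage and motifs

`build_intron_windows` partitions [5′ss − flank, 3′ss + flank] into nine
windows in transcript orientation: exonic and intronic 40-bp flanks at each
splice site plus five near-equal interior tiles (the intron minus its two
intronic flanks). The Methods-style sentence this implements is ambiguous
between 7 and 9 windows; both exonic and intronic flanks are emitted with
explicit roles so a 7-window reading is obtained by dropping the exonic
flanks. Tile remainders go to the 5′-most tiles (lengths differ by ≤ 1 bp);
on the minus strand tile 1 abuts the higher genomic coordinate. Preconditions
are enforced (intron length > 2·flank + n_tiles) with errors naming the
intron.

Peak coverage: intervals pooled per RBP across experiments are merged
(union; book-ended intervals coalesce), and each window's fraction of
covered base pairs is computed by interval intersection. Merging is
idempotent and order-invariant; adding a peak can never decrease coverage.
Hierarchical clustering of binding profiles uses Euclidean distance and
average linkage (neither is dictated by the source description; these are
the common defaults for coverage heatmaps), through SciPy, whose
smaller-index tie-breaking makes leaf order deterministic.

Motif scanning scores log₂ odds of PWM versus background at every position
(single given strand by default, as appropriate for RNA motifs on a
transcript sequence; reverse-complement scanning behind a flag). P-values
are exact: scores are discretised at 0.01 bits and the null distribution of
the integerised score under the background composition is built by dynamic
programming, position by position — the FIMO construction. Words hitting a
zero-probability PWM cell score −∞ and are kept as a separate mass that can
never reach a finite threshold, so a length-8 consensus-only motif has
p(perfect match) = 4⁻⁸ exactly under a uniform background. Exhaustive
enumeration over all 4^w words reproduces the DP tail to float precision
for w ≤ 8 (verified in tests). Hits with p < 1e-4 are retained; positions
overlapping N are excluded; no multiple-testing correction is applied
(deliberately — raw-p filtering is the convention this mirrors). Per-RBP
per-window collation takes the maximum hit score, assigning a hit to the
window containing its start position; multiple motifs of one RBP collate by
max with first-motif tie-breaking.

MEME minimal-format IO delegates matrix parsing to Biopython; the alternate
name on each MOTIF line (used to carry the RBP) is recovered from the raw
text because Biopython's minimal reader discards it, and motifs are written
with a large `nsites` so count-reconstructing readers keep full precision.

## Statistics

- **Pearson**: r, R² and the two-sided p from t = r·√((n−2)/(1−r²)) on n−2
  df (via `scipy.stats.pearsonr`, which evaluates the same closed form).
  Zero variance yields a flagged undefined result. r is reported alongside
  R² to avoid sign loss.
- **t-test**: unpaired, two-tailed, pooled variance (Student), n ≥ 2 per
  group.
- **Fold change**: max/min of two positive means, reported unrounded and at
  one decimal (the "~x.x-fold" convention), with the direction from
  reference to alternative. Note one consequence of one-decimal rounding:
  means of 22 vs 8 give 2.75 → 2.8, whereas prose summaries sometimes
  truncate such values downwards.
- **2^−ΔΔCt**: technical replicate Cts are averaged per timepoint before
  ΔCt = Ct_target − Ct_reference; ΔΔCt is taken against a calibrator
  timepoint (default the first), making the calibrator value exactly 1. The
  series is invariant under any global Ct shift.
- **Compartment fractions**: per-gene TPM divided by the gene's TPM sum over
  compartments (rows sum to 1); TPM is computed from counts and effective
  lengths by the standard per-million normalisation when counts are given.

No multiple-testing correction is applied anywhere in the package.

## Configuration, benchmark and reproducibility

`RunConfig` (pydantic, `extra="forbid"`) validates YAML configs: unknown
keys and out-of-range values raise errors naming the key, defaults are
filled, and validation is idempotent. Every random stage derives its seed
deterministically from the single config seed (kept below 2³¹), so
re-running a benchmark from its embedded manifest reproduces every TSV and
JSON byte-for-byte. The benchmark writes PIR recovery tables over a ρ grid,
FISH detection/recovery accuracy, a correlation summary, and a manifest with
the config hash.

## Known limitations

- The PIR estimator re-implements the junction-ratio core and its two
  published filters only; the additional internal quality scores of the
  original pipeline tooling are out of scope.
- Reads supporting alternative donors/acceptors are not counted as EE for
  the annotated intron (exact boundary match required); the single-junction
  modes exist precisely to route around such introns.
- The image generator's fidelity gap to deconvolved widefield data is
  untested; detection thresholds validated here should be re-tuned on real
  stacks.
- `simulate_junction_reads` enumerates isoform configurations and is
  limited to 16 introns per gene; genes are simulated independently.
- Mitosis identification, image registration and probe design are out of
  scope.
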