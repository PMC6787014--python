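# Methods

This note documents the models, conventions and numerical choices behind
`gliomactx`, and what the synthetic-data generators do and do not emulate.

## Perivascular annulus quantification

**Model.** Tissue is a 2-D calibrated raster; vessels are a binary mask,
T cells are point centroids. The distance of a pixel (or cell) to the
vasculature is the exact Euclidean distance to the nearest vessel pixel
(`scipy.ndimage.distance_transform_edt`), in µm; vessel pixels have
distance 0 and belong to no annulus. Annuli are half-open bins
[k·w, (k+1)·w) with w = 30 µm out to 180 µm (six bins), so a cell exactly
at 180 µm is excluded — deterministic tie handling. Where the annuli of
nearby vessels overlap, the single nearest-vessel distance map resolves
the assignment, which conserves both cells and area (no double counting).
Cells inside vessel lumina are excluded from every bin but reported, so
per-bin counts + inside-vessel + beyond-maximum always add up to the
input cell count.

**Parameters.** Pixel size defaults to 0.5 µm/px and must be overridden
with the true microscope calibration — a "20×" magnification alone does
not determine it. Bin width and maximum distance are free parameters;
defaults are the 30/180 µm convention. Samples counted around fewer than
5 vessels are flagged (`qc_flags`) rather than dropped; the 5-vessel rule
is an inclusion criterion, not a computation.

**Aggregation.** Profiles are pooled per sample (summed counts and areas
over all vessels via the shared distance map). Per-vessel profiles with a
mean-of-densities aggregation can be obtained by calling the profile
functions on single-vessel masks; pooling is the default because it
weights annuli by the tissue actually present.

**Normalization and comparison.** The normalized profile sets the first
annulus to 100% (skipped with a flag when the first annulus is empty; the
operation is idempotent). Group comparison is one two-sided Mann-Whitney
test per annulus on per-sample densities; per-annulus p-values are *not*
FDR-corrected by default (a `fdr=True` flag enables BH), matching the
convention of reporting each perimeter separately.

**Decay length.** λ̂ = −1/slope of the least-squares fit of ln(density)
against annulus midpoints, requiring ≥3 annuli with positive density.
Slopes ≥ −1e−12 report λ̂ = +∞ (no decay). For an exponential intensity
the within-bin averaging multiplies every bin's density by the same
factor (2λ/w)·sinh(w/2λ), so the log-slope — and hence λ̂ — is unbiased
by binning.

**Segmentation.** Otsu threshold (or a user-supplied numeric threshold),
binary hole filling, and removal of components below a minimum area
(default 100 µm²). This is deliberately simple: elongated-vessel tracing,
PSF modelling and nuclear segmentation are out of scope; supply your own
mask if you have a better segmentation.

## Neo-epitope candidate pipeline

Single-nucleotide variants in CDS coordinates (1-based) are edited into
the transcript sequence; both alleles are translated with the standard
genetic code, stopping at the first stop codon. Consequence is judged at
the affected codon: synonymous, missense, stop-gain or stop-loss.
Missense variants yield a 17-residue window with the mutated residue at
the middle (index 8), truncated at protein termini with the index shifted
accordingly — truncation preserves near-terminal candidates rather than
discarding them. All distinct 9-mers whose span covers the mutated
residue are scored per HLA class-I allele on three channels in [0, 1]
(MHC binding, cleavage, TAP); a candidate passes iff FPKM > 0 and all
three scores > 0.5, all strict inequalities. Window tiling is provably
lossless for missense SNVs: every mutation-covering 9-mer of the full
mutant protein lies inside the 17-mer window, and the test suite checks
the pipeline against an exhaustive whole-protein enumeration.

Design choices on points the workflow leaves open:

* stop-gain/stop-loss variants produce no windows (there is no single
  "mutated amino acid" 9-mer semantics); they are logged and excluded,
  but still count as nonsynonymous for expressed-mutation counting;
* multiple variants in one transcript are applied independently (no
  phasing);
* the counting unit defaults to distinct (peptide, allele) pairs, with
  distinct peptides available via `counting_unit="peptide"`, since the
  reported "neo-epitopes per tumor" unit is not defined;
* the 0.5 threshold is applied to each of the three scores separately
  (the conservative reading of "a score >0.5 for binding, cleavage and
  TAP");
* CGA counting uses FPKM > 0 by symmetry with the expressed-mutation
  rule; the threshold is a parameter.

The production scorer (NetCTLpan) is external; any object with
`score(peptide, allele) -> (binding, cleavage, tap)` plugs in. The
bundled `MockEpitopeScorer` maps SHA-256 of `peptide|allele|channel` to
[0, 1): deterministic across platforms, uniform-looking, and with an
expected pass rate of 0.5³ = 12.5% per expressed pair — far less
selective than a real predictor, so synthetic candidate counts are not
comparable to counts from real tumors.

## TCR-Vβ repertoire statistics

Clonotypes are unique CDR3 nucleotide sequences (immunoSEQ convention).
Productive frequency is the percentage of unique clonotypes without a
premature stop; a read-weighted variant is exposed. Dominance ranks
productive clones by read count (ties broken lexicographically by CDR3
nt for determinism) and reports the smallest k whose cumulative read
fraction reaches the threshold (default 30%, crossing counted, ≥).
Top-n abundance (default n = 10) is the cumulative read percentage of
the n largest productive clones. The denominator is productive reads by
default; `denominator="all"` includes nonproductive reads, since the
phrase "total TCR-Vβ reads" admits both readings. For a uniform
repertoire of N clones, k = ⌈0.30·N⌉ and top-10 = 100·min(10, N)/N %.

## Group statistics

* **2^−ΔCt**: ΔCt = Ct_gene − Ct_housekeeping within a sample (GAPDH
  default). Missing target Ct stays missing — never imputed to cycle 40;
  an explicit imputation flag would be required to change that. The
  statistic is invariant to adding a constant to all Ct values.
* **Mann-Whitney U**: two-sided throughout. Exact enumeration of the
  null distribution when min(n) ≤ 8 and the pooled sample has no ties;
  otherwise the normal approximation with tie and continuity correction
  (both via `scipy.stats.mannwhitneyu`, cross-checked in the tests
  against an independent full-permutation enumerator). Fully tied pooled
  samples return p = 1.
* **BH-FDR**: standard step-up with monotone enforcement (statsmodels),
  one FDR family per analysis block (e.g. the qPCR gene panel); spatial
  per-annulus tests are uncorrected by default.
* **Fold change**: ratio of group means rounded half-away-from-zero, the
  rounding used in printed tables (0.25 → 0.3, not banker's 0.2). The
  published table divides *log2-scale* means; the replication uses those
  printed means as inputs, and a linear-scale ratio is simply the same
  function applied to linear means.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)`; identical
parameters and seed give byte-identical outputs, and every stochastic
quantity ships with a ground-truth record computed independently of the
analysis modules.

* **Tissue**: vessels are non-overlapping disks (radius uniform in
  15–30 µm by default) whose centers keep the outermost annulus inside
  the image — disks keep annulus geometry analytically checkable. Cells
  are a homogeneous Poisson process of rate ρ0 thinned with acceptance
  probability exp(−d/λ) (d = distance to nearest vessel border), which
  realizes the inhomogeneous intensity ρ0·exp(−d/λ) exactly and without
  grid bias; points inside lumina are rejected. Defaults: ρ0 =
  500 cells/mm² (a dense infiltrate near vessels), λ = 40 µm, 3 vessels
  in a 600×600 µm field. Parameter-recovery tests raise ρ0 into the
  10⁴–10⁵/mm² range purely to reach the ≥5000-cell regime where the
  estimator's sampling error is small; the intensity model is unchanged.
  Not emulated: real vessel morphology, microscope noise, cell-size
  exclusion effects.
* **Transcriptome**: random in-frame CDSs (ATG + sense codons + stop).
  Variants are planted at distinct internal codons with the intended
  consequence forced (synonymous with the configured probability,
  otherwise missense; codons that cannot mutate synonymously, like ATG
  and TGG, are skipped for synonymous draws). A configured fraction of
  genes gets log-normal FPKM, the rest exactly 0. The truth list of
  passing neo-epitopes is computed by a brute-force oracle with its own
  codon table that enumerates all 9-mers of each whole mutant protein —
  independent of the windowed pipeline it validates. No mutational
  signatures, indels or phasing.
* **Repertoire**: clone frequencies uniform, geometric (parameter p) or
  power-law (exponent α); reads are one guaranteed read per clone plus a
  multinomial; a configured fraction of clones carries a premature stop.
  Truth statistics are direct prefix sums on the emitted counts.
* **qPCR**: housekeeping Ct is noise-free at its configured mean; target
  genes sit a fixed ΔCt above it (default 5 cycles, typical for
  low-abundance immune transcripts in FFPE material) plus Gaussian noise
  (default sd 0.5 cycles), and group B receives a per-gene cycle shift
  (+3 cycles = 8-fold lower 2^−ΔCt). Keeping the housekeeper noise-free
  makes planted shifts translate exactly into expression ratios;
  efficiency-corrected qPCR models are out of scope.

Passing tests on these generators demonstrates algorithmic correctness
(binning, enumeration, filtering, ranking, test statistics), not that the
generators reproduce the variability of patient material — real tissues
have heterogeneous vessel shapes, clustered cells, correlated expression
and sequencing artefacts that are deliberately absent here.

## Problem sizes and tolerances

The test and acceptance runs use: 200×200 px fixtures (20 of them) for
brute-force distance checks; 1600×1600 px tissues, 6 vessels, 20 seeds
per λ ∈ {20, 40, 80} µm for decay recovery (tolerance 15% on the mean,
reflecting Monte-Carlo error at ~5–10k cells); 50 random variant sets for
pipeline-vs-oracle equality (exact set equality required); 100 random
repertoires for prefix-sum equality (exact); 1000 null replicates at
n = 8/8 for the type-I error bound; rasterization tolerance 5% for
single-disk annulus areas (observed ≈0.5% at 0.5 µm/px). The end-to-end
pipeline demo uses 2–4 samples per group and finishes in seconds.

## Known limitations

2-D analysis only; simple threshold segmentation; no genome-coordinate
annotation (CDS-coordinate variants, or supply a transcript map
externally); no class-II epitopes, V/D/J assignment, clonotype error
correction or diversity indices beyond the two reported statistics; the
mock scorer's absolute candidate counts are not biologically meaningful.
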