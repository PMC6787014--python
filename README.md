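# gliomactx

Quantitative re-implementation of the computational workflow used to compare
the T-cell contexture of low-grade (LGG, WHO II) and high-grade (HGG, WHO IV)
diffuse glioma: where T cells sit relative to the vasculature, whether the
tumors carry presentable antigens, how clonal the infiltrating T-cell
receptor repertoire is, and whether T-cell-trafficking genes differ in
expression. It is aimed at tumor-immunology groups who have vessel/T-cell
stainings, somatic variant calls with expression data, immunoSEQ-style TCRβ
clone tables, or qPCR Ct tables, and want the corresponding statistics as
reusable, tested library calls instead of one-off scripts. Since no patient
data are public for this study design, a seeded synthetic-data generator
stands in for every input type and carries ground truth for testing.

## What it computes

* **Perivascular TIL profiles** (`spatial_til`). Vessels are segmented from
  an autofluorescence channel (Otsu threshold, hole filling, minimum-area
  filter); a Euclidean distance transform assigns every cell centroid to a
  half-open 30 µm annulus [30k, 30(k+1)) µm out to 180 µm from the nearest
  vessel border. Output per sample: per-annulus counts, areas (mm²),
  densities ρ_k (cells/mm²), the normalized profile 100·ρ_k/ρ_0 (first
  perimeter = 100%), and an exponential decay length λ̂ = −1/slope of
  ln ρ against distance, summarising how deep T cells invade.
* **Neo-epitope candidates** (`antigenicity`). Each coding SNV is edited
  into its transcript CDS and translated; for missense changes a 17-mer
  window with the mutated residue at the middle position is tiled into
  9-mers. A candidate (peptide, HLA allele) pair passes when it contains
  the mutated amino acid, its gene is expressed (FPKM > 0), and all three
  scores — MHC-I binding, proteasomal C-terminal cleavage, TAP transport —
  exceed 0.5 (strict). The scorer is pluggable (a deterministic mock ships
  for testing; wrap NetCTLpan for production). Also: per-sample counts of
  expressed nonsynonymous mutations and of expressed cancer germline
  antigens against a gene catalogue.
* **TCR-Vβ repertoire statistics** (`tcr_repertoire`): productive frequency
  (% of unique clonotypes without a premature stop), dominant-clone count
  (smallest k whose top-k clones reach 30% of productive reads), and
  top-10 abundance (% of reads in the ten largest clones).
* **Group statistics** (`group_stats`): 2^−ΔCt relative expression against
  a housekeeping gene (GAPDH by default), two-sided Mann-Whitney U (exact
  enumeration for small tie-free samples), Benjamini-Hochberg FDR, fold
  changes of group means with printed-table rounding, and per-gram T-cell
  normalization.

## Worked example

```python
from gliomactx import spatial_til as st, synthetic_data as sd

params = sd.SpatialSimParams(baseline_density_per_mm2=20000,
                             decay_length_um=40.0, seed=1)
sample, truth = sd.generate_tissue(params)          # mask + cell centroids
geom = st.build_annuli(sample.vessel_mask, params.pixel_size_um)
prof = st.normalize_profile(st.count_cells_per_annulus(sample.cells, geom))
print(prof.densities_per_mm2.round(1))
print(prof.normalized_pct.round(1))
print(round(st.estimate_decay_length(prof), 1))
```

prints

```
[13399.8  6174.4  3337.   1389.2   685.7   355.8]
[100.   46.1  24.9  10.4   5.1   2.7]
41.0
```

i.e. the simulated T-cell density falls from ~13,400 cells/mm² in the first
30 µm perimeter to ~360 cells/mm² at 150–180 µm; normalized to the first
perimeter the profile drops to 2.7%, and the fitted decay length 41.0 µm
recovers the planted 40 µm. The same pattern — LGG profiles collapsing
much faster than HGG — is what distinguishes a vessel-confined from an
invading infiltrate.

The full synthetic pipeline (all four data types, group comparisons,
stage reports and a summary table) runs with:

```bash
gliomactx run --seed 7 --out out/
```

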