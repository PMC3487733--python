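# barcodiv

Assessment of hyperdiverse arthropod faunas from DNA barcodes. The package
implements the computational core of a barcode-based biodiversity survey of
soil mites (Acari): quality filtering of COI barcode sequences, delineation
of molecular operational taxonomic units (MOTUs) at an absolute
nucleotide-change threshold, specimen-based accumulation curves and Chao1
richness projection, and beta-diversity analysis of site and substrate
communities. It is aimed at community ecologists and barcoding labs who
need a transparent, reproducible species-proxy pipeline for taxa where
morphological identification is impractical, and it ships a
synthetic-community generator with full ground truth so every stage can be
validated end to end.

## Methods at a glance

* **Sequence QC.** Two grades on each recovered COI barcode: length > 500 bp
  with < 1% ambiguous sites (the grade required for a standalone species
  proxy), and length ≥ 300 bp with < 1% ambiguous sites (the grade required
  for clustering). Sequencing success is summarized per order and its
  homogeneity tested with a Pearson χ² on the order × {recovered, failed}
  table.
* **MOTU delineation.** Pairwise distances are absolute nucleotide
  differences from a global alignment with free terminal overhangs
  (ambiguity-masked columns excluded; internal gap columns count one
  difference each). MOTUs are the connected components of the graph joining
  pairs with ≤ *t* differences (single linkage at the cutoff, default
  *t* = 15, ≈ 2.3% of a 648 bp barcode).
* **Richness.** Accumulation curves by Monte-Carlo resampling (1000 random
  specimen orderings), with the closed-form hypergeometric rarefaction
  E[S(n)] = S_obs − Σᵢ C(N−Nᵢ, n)/C(N, n) as the exact reference. Survey
  completeness from the terminal slope of the mean curve over its last 10
  specimens (> 0.1 very undersampled, > 0.01 modestly undersampled). Total
  richness by Chao1 from singletons f₁ and doubletons f₂ (bias-corrected
  S_obs + f₁(f₁−1)/(2(f₂+1)) by default), with standard errors.
* **Community structure.** Unit × MOTU abundance matrices per site or
  substrate; Hellinger transformation √(yᵢⱼ/yᵢ·); Bray-Curtis
  dissimilarity Σ|u−v|/Σ(u+v); complete-linkage dendrograms (exported as
  Newick); rank-based ANOSIM, R = (r̄_between − r̄_within)/(M/2), with a
  seeded permutation p-value (999 permutations).
* **Synthetic communities.** Log-series abundances, three orders /
  77 families, ten sites split forested vs non-forested, eight substrates,
  per-order sequencing success near 68–80%, configurable intraspecific
  (≤ 5 changes) and interspecific (≥ 30 changes) divergence, truncation and
  ambiguity artifacts — with per-specimen ground truth.

## Worked example

Simulate a small survey and run every stage:

```
$ barcodiv simulate --seed 3 --n-species 30 --out sim
simulated 220 specimens (157 recovered) from 30 species -> sim

$ barcodiv qc --fasta sim/sequences.fasta --metadata sim/metadata.tsv
attempted       220
recovered       157
success_pct     71.4
motu_grade      154
bin_grade       151
chi_square      1.2     df      2       p       0.537

$ barcodiv run-all --fasta sim/sequences.fasta --metadata sim/metadata.tsv \
      --out run --iterations 100 --permutations 99
28 MOTUs; reports in run
```

Of 220 specimens attempted, 157 yielded a sequence (71.4%; the χ² test
finds no significant variation in success among the three orders here,
p = 0.537). 154 sequences met the clustering grade and collapsed into 28
MOTUs at the 15-change threshold — close to the 30 species actually
simulated; the two missing species were lost to sequencing dropout.
`run/richness_report.tsv` then reads:

```
group           motus  n    chao  chao_se  terminal_slope  category               n_families
Mesostigmata    4      8    4     0                                               4
Sarcoptiformes  11     61   11    1        0.035           modestly_undersampled  6
Trombidiformes  13     85   15    3        0.033           modestly_undersampled  7
Total           28     154  31    3        0.047           modestly_undersampled  17
```

i.e. the accumulation curves are still rising (terminal slopes > 0.01), and
Chao1 projects 31 ± 3 MOTUs in total. The run directory also contains the
per-order site and substrate dendrograms (Newick), the ANOSIM table (here
Sarcoptiformes R = 0.776, Trombidiformes R = 0.956 for forested vs
non-forested sites, p = 0.03 at 99 permutations), mean Bray-Curtis
dissimilarities, the family-level report with pooled "Others" groups, and a
checksum manifest; a rerun with the same seed is byte-identical.

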