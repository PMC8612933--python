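# cicerscan

Analysis pipeline for structured diploid SNP panels: windowed
diversity/selection scans, private/enriched allele classification,
structural-variant merging, deleterious-mutation burden accounting, genomic
prediction, haplotype-based breeding values and optimal-contribution mate
allocation — with a first-class simulator providing ground truth for every
stage.

## Modules

| module | contents |
| --- | --- |
| `cicerscan.core_io` | `GenotypeMatrix` data model, VCF/phenotype/BED I/O, MAF/missingness/het/LD-prune filters, window tiling |
| `cicerscan.simulate` | Balding–Nichols structured genotypes, founder-collapse sweep injection, multi-environment phenotypes with controlled h² and G×E, SIFT/GERP/outgroup annotations with planted burden enrichment |
| `cicerscan.diversity` | per-window π, Watterson's θ, Tajima's D; Weir–Cockerham F\_ST (weighted, component-sum); ROD; LD decay; the combined ROD ∧ F\_ST ∧ D selection-window caller; 10-kb SNP interval clustering |
| `cicerscan.varclass` | private / population-enriched allele classes; dual-caller SV merging (breakpoint distance < 100 bp, transitive) and ≥5 % population-frequency filtering |
| `cicerscan.burden` | outgroup polarization, SIFT/GERP/constrained-mask deleterious classification (+ DAF-fixed subset), per-sample derived-allele burden, permutation group comparison |
| `cicerscan.prediction` | VanRaden GRM, RR-BLUP via exact spectral REML (≡ GBLUP), E+L / E+L+G / E+L+G+GE kernel models by EM-REML, CV0/CV1/CV2 accuracy |
| `cicerscan.haplotypes` | greedy-r² LD blocks, local GEBVs from homozygous haplotypes, in-silico stacking, haplo–pheno scans with Duncan's multiple range test, donor identification |
| `cicerscan.ocs` | economic index ($/ha with seed-size and earliness bonuses), co-ancestry, gain-vs-diversity frontier optimizer with a target-degrees selector |

## CLI

All stages are exposed through one entry point (`cicerscan --help`):

```bash
# synthetic panel with injected sweeps + phenotypes
cicerscan simulate --config sim.yaml --out-dir sim/

# variant filtering
cicerscan filter --vcf in.vcf.gz --maf 0.05 --max-missing 0.3 --out out.vcf

# diversity / selection scan (windowed pi, theta, D, F_ST, ROD, caller)
cicerscan scan --vcf sim/genotypes.vcf --samples sim/samples.csv \
    --ref-pop wild --target-pop landrace --window 100000 --step 10000 \
    --out-prefix scan

# allele classes, SV merging, burden comparison
cicerscan classify-alleles --vcf ... --samples ... --out classes.tsv
cicerscan merge-sv --calls-a a.tsv --calls-b b.tsv --out merged.tsv
cicerscan burden --vcf ... --samples ... --annotations ann.csv \
    --group-a wild --group-b landrace --out-prefix burden

# genomic prediction and OCS mating
cicerscan predict --vcf ... --phenotypes pheno.csv --trait 100SW \
    --model E+L+G --scheme CV0 --out accuracy.tsv
cicerscan ocs --gebvs gebvs.csv --vcf ... --degrees 60 --matings 325 \
    --out-prefix plan
```

## Conventions

- Coordinates are 0-based half-open internally, 1-based inclusive in VCF and
  reports.
- Dosages are alt-allele counts {0, 1, 2} with −1 for missing; frequencies
  always use non-missing alleles.
- Genome-wide F\_ST is the ratio of summed Weir–Cockerham components, never
  a mean of window ratios.
- Quantiles for the selection caller are empirical type-7 (linear
  interpolation).
- Haplotypes are read from fully homozygous accessions only (unphased data).
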