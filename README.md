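# sweepscan

Intraspecific selection-scan toolkit for phased SNP data: site-frequency-spectrum
statistics (π, Watterson's θ, Tajima's D, Fay–Wu H and its variance-normalized
form "DH"), per-SNP Weir–Cockerham F_ST with MAF-binned empirical outlier
ranking, the DIND intra-allelic diversity test with DAF-binned calibration,
linkage disequilibrium (r²) and haplotype-matrix reports, a combined-evidence
positive-selection caller, and a coalescent generator of phased synthetic
cohorts that stands in for real resequencing data so the whole pipeline is
testable offline.

## Layout

| module | contents |
| --- | --- |
| `sweepscan.genomic_io` | VCF/panel/BED I/O, ancestral-allele polarization (table / `AA` tag / outgroup parsimony) |
| `sweepscan.sfs_stats` | π, θ_W, Tajima's D, θ_L, Fay–Wu H, normalized DH, 5-kb/500-bp sliding windows |
| `sweepscan.fst_differentiation` | haploid Weir–Cockerham F_ST, MAF binning (50 classes), ranked scans |
| `sweepscan.dind_test` | DIND (iπ_A/iπ_D over 40 flanking variants), sentinel rule, DAF binning (100 classes) |
| `sweepscan.empirical_calibration` | control-set empirical nulls, percentile ranks, DH window thresholds, combined caller |
| `sweepscan.ld_haplotypes` | haplotype-count D/r², phase relations, haplotype-matrix text/PNG reports |
| `sweepscan.synthetic_data` | hand-written coalescent simulator (neutral / two-deme island / hard-sweep approximation), cohort writer |
| `sweepscan.pipeline_cli` | `run_scan` orchestration and the `sweepscan` CLI |
| `sweepscan.validation` | simulation studies backing the acceptance criteria |

## CLI

Every stage is a subcommand; `sweepscan --help` lists them.

```sh
# simulate a cohort (VCF + panel + BED + truth table)
sweepscan simulate --scenario neutral --n-haplotypes 20 --theta 5 \
    --n-loci 100 --seed 1 --out-dir cohort/

# window statistics for one population
sweepscan stats --vcf cohort/cohort.vcf --panel cohort/panel.tsv \
    --bed cohort/loci.bed --population pop1 --out windows.tsv

# per-SNP F_ST, DIND, LD, haplotype report
sweepscan fst  --vcf ... --panel ... --bed ... --pop-a pop1 --pop-b pop2 --out fst.tsv
sweepscan dind --vcf ... --panel ... --bed ... --population pop1 --out dind.tsv
sweepscan ld   --vcf ... --panel ... --bed ... --population pop1 \
    --variant rsA --variant rsB --out ld.tsv
sweepscan hapmatrix --vcf ... --panel ... --bed ... --population pop1 \
    --focal rsA --out hap.txt --png hap.png

# full combined-evidence scan from a YAML config
sweepscan scan --config scan.yaml
```

A scan config names the inputs and parameters (defaults shown):

```yaml
vcf: cohort/cohort.vcf
panel: cohort/panel.tsv
test_regions: cohort/test_regions.bed
control_regions: cohort/control_regions.bed
out_dir: scan_out
populations: [pop1, pop2]
comparisons: [[pop1, pop2]]
params:
  window: 5000        # bp, DH sliding windows
  step: 500
  flank_variants: 20  # per side, DIND
  rank_threshold: 0.95
  dh_quantile: 0.05
  region_flank: 30000 # bp added to each side of every test region
```

The scan emits per-region F_ST/DIND/window TSVs, serialized null caches, a
`calls.tsv` verdict table, and a `manifest.json` recording version, config
digest, and seed. A region is called in a population when one variant reaches
rank ≥ 0.95 in at least two statistics from different feature families
(differentiation vs intra-allelic diversity); DH windows below the control
fifth percentile are attached as confirmatory evidence only.

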