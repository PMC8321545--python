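# sgvscan

Genome scans for species-specific adaptation in a recent radiation, and
classification of divergent alleles as standing genetic variation (SGV) vs
new mutation.

The package re-implements, as a tested reusable pipeline:

* **variants** — VCF ingestion, the site-filter chain (biallelic / indel /
  missing / Hardy-Weinberg exact test), plink-style LD pruning
  (50 SNP window, step 5, r² 0.1) and per-individual inbreeding F.
* **winstats** — sliding-window (10 kb / 2 kb) nucleotide diversity π,
  Weir-Cockerham weighted F_ST (ratio of summed variance components) and
  absolute divergence d_XY, plus dosage PCA.
* **scan** — highly differentiated regions (HDRs) as merged top-0.5%
  F_ST windows per species pair, joint F_ST/d_XY sweep flags,
  species-specificity labels, candidate genes within 10-kb flanks, and
  differentiated-SNP annotation (exon/intron/UTR/flank, ≥0.5 frequency,
  ≥0.6 between-species difference).
* **haploscan** — EHH / iHH / iHS on phased haplotypes with
  frequency-bin standardization and two-sided 1% extreme calling.
* **sgv** — per-gene consensus alignments, neighbor-joining trees on
  Jukes-Cantor distances with 100 column-bootstrap replicates, monophyly
  testing of the radiation species (support ≥ 60), SGV / new-mutation /
  unresolved origin calls with depth labels (before_LT / before_HB /
  before_LM), and the two-tailed Mann-Whitney comparison of per-gene
  maximum d_XY between origin classes.
* **simgen** — a forward Wright-Fisher simulator of a radiating species
  complex (diploid, Poisson crossovers, infinite-sites mutations on
  continuous coordinates, coalescent-initialized founders) with neutral,
  hard-sweep-from-new-mutation and sweep-from-ancient-balanced-polymorphism
  scenarios, emitting VCF + BED gene models + species map + newick species
  tree + truth labels.
* **pipeline / cli** — end-to-end orchestration with plain-text
  intermediates and a JSON run report.

## CLI

```sh
sgvscan simulate --config sim.yaml --seed 1 --out runs/sim
sgvscan filter   --vcf in.vcf --species-map map.tsv --no-hwe --out runs/f
sgvscan winstats --vcf runs/f.vcf --species-map map.tsv --win 10000 --step 2000 --out win.tsv
sgvscan scan     --stats win.tsv --genes genes.bed \
                 --pair HChi,HSau --pair HChi,LRuf --pair HSau,LRuf --out runs/scan
sgvscan ihs      --vcf runs/f.vcf --species-map map.tsv --species HChi --crit 0.01 --out ihs.tsv
sgvscan origin   --vcf runs/f.vcf --species-map map.tsv --genes genes.bed \
                 --lineage-map tiers.tsv --outgroup ONil --support 60 --boot 100 --out origin.tsv
sgvscan all      --config demo.yaml --seed 1 --out runs/demo
```

`sgvscan all` runs simulate → filter → winstats → scan → ihs → origin and
writes every stage table plus `report.json` (realized thresholds, per-stage
counts, origin tallies and the Mann-Whitney summary). Config YAML keys
mirror `sgvscan.pipeline.PipelineConfig`; every tunable defaults to the
canonical scan constants (10 kb/2 kb windows, top 0.5%, HWE 0.001,
MAF 0.05, LD 50/5/0.1, iHS crit 1%, 100 bootstraps, support 60, 10-kb
flanks). Exit codes: 0 ok, 1 user/config error, 2 internal error.

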