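# popgenkit

Statistics for diploid SNP panels: between-population differentiation
(Weir–Cockerham F_ST, PBS, f3/f4 with block-jackknife errors), LD-decay
effective-population-size and F_ST-based divergence-time estimation,
haplotype selection scans (EHH, iHS, XP-EHH), runs of homozygosity,
hierarchical AMOVA with permutation significance, a derived-allele-frequency
candidate screen, and a Monte-Carlo Wright–Fisher drift null that assigns
significance to candidate allele-frequency shifts. A synthetic-data module
(forward Wright–Fisher frequency and haplotype simulators, plus an msprime
convenience wrapper) generates every input the analyses need, so the whole
pipeline runs without external data.

## Library layout

| module | contents |
| --- | --- |
| `popgenkit.genotype_io` | VCF / PLINK PED-MAP readers, `GenotypePanel` / `HaplotypePanel` / `PopulationMap` / `GeneticMap`, polarization to derived alleles, PI_HAT relatedness, QC filtering, LD pruning |
| `popgenkit.diff_stats` | Weir–Cockerham F_ST (per-locus a/b/c components, ratio-of-sums θ), pairwise F_ST matrix, PBS, f3/f4 with weighted block jackknife |
| `popgenkit.demography` | 1/n-adjusted LD-decay Ne trajectory (Ne = 1/(4c)·(1/r² − 2), t = 1/(2c)), T_F = 2·Ne_harm·F_ST divergence times, generation–year conversion |
| `popgenkit.selection_scan` | EHH curves, iHS (DAF-bin standardized), XP-EHH, PLINK-style ROH calling with Wilcoxon comparison, DAF candidate screen, sequencing-vs-target-panel AF consistency |
| `popgenkit.drift_test` | binomial Wright–Fisher drift simulator and Monte-Carlo drift-null p-values (single locus and batch) |
| `popgenkit.amova` | hierarchical AMOVA (among groups / among populations within groups / within populations) with per-level permutation tests and group-rotation scan |
| `popgenkit.synthetic_data` | split-with-migration frequency simulator, recombining forward haplotype simulator with optional sweeps, multi-population demography preset, msprime equilibrium panels |
| `popgenkit.cli` | `popgenkit` command-line entry point |

## CLI

```bash
popgenkit --help
popgenkit drift-test --p0 0 --obs 0.0987 --ne 11000 --gens 280 --reps 1000 --seed 1
popgenkit drift-test --candidates path/to/candidates.tsv --out drift.tsv
popgenkit simulate --out-prefix run/panel --n-loci 5000 --seed 1
popgenkit fst --vcf run/panel.vcf --popmap run/panel.popmap.tsv --out fst.tsv
popgenkit amova --vcf run/panel.vcf --popmap run/panel.popmap.tsv --out amova.tsv
popgenkit pipeline --config config.yaml   # simulate -> qc -> fst -> drift-test
```

Every output TSV starts with a `# {...}` provenance header naming the tool,
version, seed and resolved parameters; identical config + seed reproduces
outputs byte for byte.

A candidate-variant table (positions, alleles, ancestral states, per-panel
derived-allele frequencies and annotation scores for 13 putatively adaptive
variants) ships with the package
(`src/popgenkit/data/candidate_variants.tsv`) and is the default input for
`popgenkit screen` and batch `popgenkit drift-test`.

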