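# bulkmap

A bulked-segregant (QTL-seq) trait-mapping toolkit for biparental plant
populations. It covers the full desk-scale workflow for mapping a
single dominant locus:

- **simpop** — synthetic F2 / selfed F2:3 populations from inbred
  parents under a no-interference (Poisson) crossover model, with
  phenotype-selected sequencing bulks and depth-sampled pooled allele
  counts.
- **segregation** — chi-square goodness-of-fit of phenotype counts
  against Mendelian ratios (3:1, 15:1, ...).
- **bsaindex** — per-pool SNP-index and delta SNP-index, depth/
  informativeness filters, sliding-window profiling (default 1,000 kb
  windows, 100 kb steps), simulated null confidence envelopes (genotype
  resampling + binomial read sampling at observed depths), and
  candidate-region calling by merging significant windows.
- **linkage** — two-point F2 recombination-fraction ML estimation (A/H/B
  codominant and A/C dominant codings), LOD scores, single-linkage
  grouping, and Haldane map distances ordered by physical position.
- **finemap** — recombinant screening between flanking markers and
  substitution mapping: each recombinant's genotypes and phenotype bound
  the locus by its innermost excluding markers; the refined interval is
  the intersection across recombinants.
- **candgene** — exon splicing, standard-code translation, per-variant
  effect annotation (synonymous / non-synonymous), haplotype grouping
  with phenotype concordance, and a delta-delta-Ct expression helper.
- **io / cli** — TSV (canonical), minimal VCF with per-pool allele
  depths, BED, genotype-matrix TSV, YAML run configuration, and the
  `bulkmap` command-line interface. Every output carries a provenance
  header (version, config hash, seed); identical seeds give
  byte-identical outputs.

Coordinates are 1-based inclusive everywhere internally; BED exports are
0-based half-open.

## Command line

```sh
# full simulate -> bsa -> linkage -> finemap -> haplotype demo pipeline
bulkmap run --seed 1 --out-dir demo_out

# individual stages
bulkmap segregate --counts 88,32 --ratio 3,1
bulkmap simulate --seed 2 --out-dir sim_out
bulkmap bsa --in sim_out/pooled_variants.tsv --out-dir bsa_out \
    --window 1000000 --step 100000 --min-depth 7 --reps 10000 --seed 2
bulkmap linkage --matrix demo_out/genotype_matrix.tsv --out trait_map.tsv
bulkmap haplotype --calls calls.tsv
```

`bulkmap run` accepts a YAML config (`--config run.yaml`) overriding any
field of `bulkmap.io.RunConfig` (genome geometry, pool sizes, window /
step / filter parameters, bootstrap replicates, seeds, ...).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit and property tests per module plus
`tests/test_acceptance.py`, which checks the printed-value
reproductions and the statistical acceptance surface (power/containment
of region calling over 100 seeded simulations, null CI calibration,
recombination-fraction recovery, fine-mapping soundness, and the
variant-effect oracle). The full run takes a few minutes on one CPU.

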