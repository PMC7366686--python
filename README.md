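# alsdiag

Heterozygote-aware SNP diagnostics and ALS target-site
herbicide-resistance genotyping for aligned Sanger amplicons.

Given a multi-species nucleotide alignment in which diploid
heterozygotes are encoded as IUPAC ambiguity codes, `alsdiag` provides:

* **Site statistics** — per-species per-position IUPAC code counts,
  variable sites, and parsimony-informative sites, with an explicit rule
  for heterozygotes (an ambiguity code contributes each of its resolved
  bases; a lone heterozygote makes a site variable but not
  parsimony-informative).
* **Diagnostic SNPs** — positions where one species' resolved allele set
  is disjoint from all other species'. The strict verdict treats a
  single shared heterozygote as disqualifying; a relaxed "majority"
  report (singleton codes dropped) is emitted separately.
* **Resistance calling** — extraction of catalog codons (ALS positions
  122, 197, 574, 653 enabled by default; 205/654 shipped but disabled,
  376/377 uncallable on these amplicons), resolution of IUPAC codon
  genotypes into diploid allele pairs, wild-type-preferring phasing,
  amino-acid substitution calls with zygosity, and `novel` flags for
  substitutions absent from the shipped previously-reported list.
  Synonymous variants are suppressed; stop codons are reported as `*`
  and flagged, never dropped.
* **Haplotype grouping** — multi-locus groups (default loci 1770, 1776,
  1782, 1794) with homozygous samples labelled by their haplotype string
  and heterozygous samples pooled with all phase-consistent haplotypes
  listed.
* **Patristic summaries** — mean within- and between-species path-length
  distances on a user-supplied newick tree (trees are inputs, never
  inferred here).
* **Synthetic data** — a seeded, fully deterministic simulator that
  plants diagnostic sites, intraspecific polymorphism, resistance
  diplotypes and haplotype groups, and emits a ground-truth JSON for
  exact recovery scoring.

Two worked-example panels (a six-species SNP comparison and a 25-sample
resistance panel) ship with the package and back the test suite.

## Command line

All subcommands log to stderr and write TSV/JSON artifacts to `--out`.
Outputs embed input hashes, not timestamps, so reruns are byte-identical.

```sh
# export the bundled worked-example panels
alsdiag demo --panel resistance --out demo/
alsdiag demo --panel snp --out demo/

# resistance calls + summary (positions are 1-based reference coords)
alsdiag call-resistance --fasta demo/resistance_panel.fasta \
    --metadata demo/resistance_panel.tsv --first-position 349 --out out/

# per-site summaries, variable/PIS counts
alsdiag snp-stats --fasta demo/snp_panel.fasta --first-position 349 --out out/

# species-diagnostic positions (strict + majority reports)
alsdiag diagnostics --fasta demo/snp_panel.fasta --first-position 349 \
    --target-species "A. tuberculatus" --out out/

# multi-locus haplotype groups
alsdiag haplogroups --fasta demo/snp_panel.fasta --first-position 349 \
    --species-scope "A. tuberculatus" --out out/

# patristic distance summary from a newick tree + metadata TSV
alsdiag distances --tree tree.nwk --metadata metadata.tsv --out out/

# deterministic synthetic dataset with truth records
alsdiag simulate --config sim.yaml --seed 7 --out sim/
```

FASTA headers may carry `sample_id|species|origin`; a metadata TSV
(columns `sample_id`, `species`, `origin`) overrides header metadata
when supplied. The resistance catalog is editable data
(`alsdiag.resistance.dump_catalog` writes the built-in one to YAML for
customisation via `--catalog`).

## Notes on conventions

* All coordinates are 1-based; reference positions come from a
  config-supplied frame (a designated reference sample plus
  `--first-position`), never from amino-acid numbers.
* Gaps inside an extracted codon yield an explicit no-call with a
  reason, not an error; 3- and 4-fold ambiguity codes are likewise
  uncallable (diploids carry at most two alleles).
* Gaps and `N` are excluded from allele sets and counts.
* The mapping of haplotype-string letters to the four default loci
  follows the loci's ascending position order; this ordering is an
  assumption, and the loci are fully configurable.
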