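# ampligen

Genotyping of multilocus MHC class IIB exon-2 alleles from MID-tagged
amplicon deep-sequencing reads, with frequency-based artifact filtering,
molecular-evolution tests, and population-genetic summaries. A synthetic-data
module generates allele pools, genotypes, artifact-laden reads (PCR point
errors and chimeras, including a frameshifted pseudogene-like allele), and
microsatellite genotypes with known truth, so the whole pipeline is testable
offline.

## What it does

1. **Simulation** (`ampligen.simulate`) — seeded generation of a diverse
   allele pool, per-individual allele sets (1 to 2·n_loci alleles across
   several populations), log-normal per-amplicon read depths, point-error and
   within-individual chimera artifacts, and diploid microsatellites.
2. **Genotyping** (`ampligen.genotyping`) — perfect-match MID + primer
   demultiplexing (both orientations, IUPAC-aware), exact-sequence variant
   tallying, a local-alignment reference-identity filter, the maximum
   per-amplicon frequency (MPAF) artifact filter (default threshold 0.10,
   inclusive), a within-amplicon 10%-of-most-frequent rule for genotype
   calls, depth QC, pseudogene flagging (frameshift or internal stop), a
   depth-vs-allele-count bias check, and minimum-locus inference.
3. **Selection statistics** (`ampligen.selection`) — amino-acid p-distances,
   Tamura–Nei (TN93) distances, modified Nei–Gojobori dN/dS with
   Jukes–Cantor correction on total / antigen-binding-site / non-ABS codon
   partitions, codon-bootstrap standard errors, and a one-tailed Z-test.
4. **Population statistics** (`ampligen.popgen`) — nucleotide diversity,
   Tajima's D (beta and normal p-values), allelic and private-allele
   richness, Hurlbert analytic and resampling rarefaction, observed/expected
   heterozygosity, multilocus heterozygosity, randomization tests, Spearman
   correlations, and table-shaped population summaries.
5. **Orchestration** (`ampligen.pipeline`, `ampligen.cli`) — staged runs
   with a manifest (seed, config hash, checksums) for bit-identical
   reproducibility.

## CLI

```sh
# seeded end-to-end run (simulate -> genotype -> selection -> summarize)
ampligen all --seed 42 --out run/ --abs-sites 5,9,11,13,26,28,30,32,37,38,40,47,51,54

# individual stages
ampligen simulate --seed 42 --populations 79,17,6 --pool-size 24 --out sim/
ampligen genotype --reads sim/reads.fastq --mids sim/mids.tsv \
    --fwd-primer ACWGGTCAYGCTTACGACGG --rev-primer GTCATSGCAGTRCCTTCAC \
    --refs sim/refs.fasta --mpaf 0.10 --within 0.10 --min-reads 100 --out geno/
ampligen selection --alleles geno/catalog.fasta --abs-sites abs.txt \
    --ts-tv 2.0 --boot 1000 --seed 42 --out sel/
ampligen summarize --mhc-genotypes geno/genotypes.tsv --alleles geno/catalog.fasta \
    --populations pops.tsv --microsats ms.tsv --perms 10000 --seed 42 --out sum/
```

All outputs are plain text (FASTQ/FASTA/TSV/JSON); TSVs carry `# seed=` and
`# config=` header comments, and `manifest.json` records input checksums.

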