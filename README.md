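# driptools

Restriction-fragment DRIP-seq analysis: R-loop peak calling, estrogen-response
z-scores, and covariate-matched mutation-enrichment testing.

## The problem

R-loops are three-stranded structures — an RNA-DNA hybrid plus a displaced
single strand — that form co-transcriptionally and predispose loci to DNA
damage. DRIP-seq (DNA-RNA immunoprecipitation with the S9.6 antibody) maps
them genome-wide, but with a twist: the genomic DNA is first digested with a
restriction-enzyme cocktail (BsrGI, EcoRI, HindIII, SspI, XbaI), so the
natural unit of quantification is the *restriction fragment*, not a sliding
window or a de-novo peak shape. `driptools` implements the downstream
computational pipeline for such experiments, motivated by the biology of
estrogen (E2) signalling in breast cells: E2 triggers a transcriptional
burst, R-loops accumulate at E2-responsive genes, and those same genes can
be asked — via public tumour-genome mutation catalogues — whether they are
also hotspots of cancer mutation.

The package is a library first (`import driptools`), with an `examples/`
directory of short narrative scripts and a thin `driptools` command-line
interface over the same functions.

## What it computes

1. **In-silico digestion** (`genome_digest`): every exact forward-strand
   match of the cocktail's palindromic recognition sequences; fragments tile
   each contig between cut sites. Windowed GC skew, (G−C)/(G+C), is computed
   directly from sequence.
2. **Counting and testing** (`count_model`): reads are assigned to the
   fragment containing their 5′ end; fragments with fewer than 10 counts in
   any sample are removed; counts are normalized to total mapped reads; and
   enrichment/differential testing uses a negative-binomial model
   (variance μ + αμ²) with a Wald test on
   log2((μ_t + ½)/(μ_r + ½)) and Benjamini–Hochberg correction.
3. **Peak analysis** (`peak_analysis`): DRIP peaks are fragments with
   positive log2 fold change (IP over input) at padj < 0.1; differential
   (E2-induced) calling runs on positives plus length-matched negative
   intervals and can require every biological replicate to agree in sign;
   peaks are assigned to genes within 1 kb; meta-gene coverage profiles
   scale gene bodies to fixed bins.
4. **E2 response** (`e2_response`): per-gene induction z-score
   z = (μ_E2 − μ_mock)/√(σ²_E2 + σ²_mock), induced iff z > 2 (strict), and
   the DRIP × GRO-seq sign-quadrant categorization of differential regions.
5. **Mutation enrichment** (`mutation_enrichment`): mutated genes are
   compared against a control set matched on replication timing and mean
   expression (studentized covariates, greedy nearest-neighbour without
   replacement); significance of the difference in medians comes from a
   two-tailed resampling test of pooled values (structural variants and
   translocations compare z-scores; simple somatic mutations compare log10
   per-kilobase rates of induced vs matched non-induced genes).
6. **Synthetic data** (`synthetic`): seeded generators for every input —
   genomes with planted restriction sites, NB counts with planted
   enrichment/induction, gene tables with correlated covariates and planted
   induced genes, and mutation sets with configurable preference for
   induced genes — each with its ground truth, so every stage is testable
   without downloads.

## Worked example

```bash
python examples/04_mutation_enrichment.py
```

prints (seed 42, 5,000 genes, 3-fold planted mutation preference for
E2-induced genes, 10,000 resamples):

```
structural_variant: statistic=z                 median test=+0.686 matched=+0.182 delta=+0.503 p=0.0001 (n=630 vs 630)
     translocation: statistic=z                 median test=+0.743 matched=+0.176 delta=+0.567 p=0.0001 (n=615 vs 615)
    simple_somatic: statistic=log10_rate_per_kb median test=+0.476 matched=-0.004 delta=+0.480 p=0.0001 (n=858 vs 852)
```

Read: genes carrying structural variants have a median E2 z-score 0.50
higher than covariate-matched unmutated genes; induced genes carry
10^0.48 ≈ 3.0× the per-kb simple-somatic rate of matched non-induced genes
(exactly the planted effect); all three differences sit at the resampling
floor p = 1/10,000. The other examples cover digestion/GC skew, peak and
differential calling, and z-score/quadrant categorization.

The same stages are available as subcommands — `driptools simulate`,
`digest`, `gcskew`, `count`, `test`, `callpeaks`, `diff`, `metagene`,
`assign`, `zscore`, `correlate`, `match-enrich` — each writing TSV/BED
outputs that begin with a provenance comment block.

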