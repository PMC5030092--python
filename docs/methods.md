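# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, the numerical conventions, and the design choices
made where more than one reasonable option existed. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Fragment model and in-silico digestion

DRIP-seq quantifies immunoprecipitated restriction fragments, so intervals
are defined by digestion, not by read pileup. The enzyme table is fixed to
the five-enzyme cocktail with canonical cut conventions:

| enzyme  | recognition | cut offset |
|---------|-------------|------------|
| BsrGI   | T^GTACA     | 1 |
| EcoRI   | G^AATTC     | 1 |
| HindIII | A^AGCTT     | 1 |
| SspI    | AAT^ATT     | 3 |
| XbaI    | T^CTAGA     | 1 |

All five recognition sequences are palindromic, so a forward-strand search
finds every site on either strand. Matching requires exact base identity
(`N` breaks a match; IUPAC ambiguity codes other than `N` are rejected as
input errors), overlapping matches are all reported, and fragment
boundaries default to the *cut* positions (recognition start + offset),
which matches physical digestion; a `boundary="site_start"` convention is
available since interval files in the wild use either. Coordinates are
0-based half-open (BED dialect) throughout. Fragments per contig are
guaranteed to tile `[0, contig_length)` exactly: duplicate cut positions
collapse, and cuts at a contig edge produce no zero-length fragment.

GC skew is (G−C)/(G+C) per window (default window 100 bp when run from the
CLI), with the convention that a window containing no G or C scores 0, and
`N` bases counting toward neither. Reverse-complementing a sequence negates
the skew of the mirrored window — a property test.

## Counting, filtering, normalization

Each read contributes to exactly one fragment: the one containing its 5′
position (interval start for plus-strand or unstranded reads, `end − 1` for
minus-strand). Reads on unknown contigs are dropped and counted in the log.

The coverage filter removes a fragment when *any* sample has fewer than
`min_count = 10` reads — the strictest reading of "fewer than 10 counts per
interval in any sample" — with an `"all"` mode (removed only when every
sample is below threshold) as an alternative. The filter is idempotent.

Two size-factor conventions are provided. `size_factors_total_mapped`
anchors totals to their geometric mean (factors average to 1 on the log
scale, convenient for display). The NB test, however, defaults to
`size_factors_per_million` — counts per million mapped reads — because the
test should depend on the data only through normalized counts: under
per-million anchoring, rescaling one library's counts and its total by the
same constant leaves every result exactly unchanged, whereas geometric-mean
anchoring shifts all samples' normalized scale and the pseudo-mean would
feel it.

## The negative-binomial Wald test

Counts are modelled as NB with variance μ + αμ². Per fragment and group,
the mean is the average of normalized counts; the reported effect is

    log2fc = log2((μ_alt + c) / (μ_ref + c)),   c = 0.5,

with the pseudo-mean guarding against zero group means. The standard error
comes from the delta method: Var(μ̂) = (μ + αμ²)/n per group on the
normalized scale, Var(log2(μ̂ + c)) = Var(μ̂)/((μ + c) ln 2)², and the
two-sided p-value is the Wald statistic against the standard normal. A
numeric likelihood-ratio oracle (profile NB likelihood, χ²₁) agrees with
the Wald p within 0.05 on small-sample cases — a test. The two-group Wald
form was chosen over an IRLS GLM because every contrast in this pipeline is
a plain two-group design.

**Dispersion.** `estimate_dispersion` implements the per-fragment
method-of-moments estimator α = max over groups of (var − mean)/mean²,
floored at 10⁻⁸ (the Poisson floor). At the 2–3 replicates of a typical
DRIP design, per-fragment variances carry only 1–2 degrees of freedom, and
plugging them into the Wald statistic visibly distorts the null p-value
distribution. The test therefore defaults to a *pooled* moment estimate,
Σ(var − mean)/Σmean² across fragments within groups — a single, stable α
shared by all fragments, in the spirit of common-dispersion estimation in
count-based differential analysis. The per-fragment estimator remains
available (`method="per_fragment"`) and is the right choice when replicate
numbers are large; its recovery at 50 replicates is property-tested.

**Multiple testing.** Benjamini–Hochberg step-up with enforced
monotonicity, capped at 1; NaN inputs propagate without entering the
ranking. Cross-checked against `statsmodels.multipletests` by property
test.

RPKM is count / (interval kb × total/10⁶), provided for strength-vs-rate
displays.

## Peak and differential calling

A DRIP peak is a fragment with log2fc > 0 (IP over input) and padj < α;
α defaults to 0.1, mirroring the differential threshold, since no separate
peak-calling threshold is established for this assay. Calling is monotone
in α (tested).

Differential calling runs the joint NB test over the supplied region set —
intended to be positives plus a matched negative background so the
comparison is not conditioned on enrichment — and calls a fragment induced
iff log2fc > 0 and padj < 0.1, and (by default) every per-replicate
pairwise log2 fold change is also positive. The consistency rule is *sign*
consistency, not per-replicate significance: a single replicate pair
supports no dispersion estimate of its own, so a per-replicate significance
requirement would be arbitrary. Replicates are paired by replicate number.
Decreased calls are symmetric. With the rule on, calls are a subset of
calls with it off (tested).

Negative intervals ("similarly-sized intervals with no significant
enrichment") are drawn by length-stratified sampling: the positive lengths
define decile bins, candidates are binned by the same edges, and
per-stratum targets are proportional to positive bin occupancy
(largest-remainder rounding). A stratum short of candidates borrows from
the nearest stratum with a warning. Value-binned (not rank-binned) strata
were chosen because rank targets degenerate when many positive lengths are
tied. Selection is deterministic given its seed.

Gene assignment measures distance to the *gene body* (0 inside the gene),
assigns peaks within 1 kb, and breaks ties by smaller distance then
lexicographic gene id. Meta-gene profiles sample a fixed 5′ flank
(default 2 kb, 20 bins), the length-scaled body (100 bins) and the 3′
flank, reverse minus-strand genes, and average per bin across genes;
positions beyond a contig's end contribute zero coverage.

## E2-response z-scores and quadrants

z = (μ_E2 − μ_mock)/√(σ²_E2 + σ²_mock) with no small-sample correction and
no transformation of the expression units (they are treated as opaque).
When both σ are zero the score is 0 for equal means and signed infinity —
a sentinel, flagged rather than used — otherwise. A gene is induced iff
z > 2 *strictly*; z = 2 is non-induced.

Quadrant categorization labels a region only when the DRIP result has
padj < 0.1 and the GRO-seq result has padj < α_gro, then uses the sign pair
of the two fold changes. The published GRO-seq threshold is stated
inconsistently at its source (0.5 in one place, 0.9 in another), so
`alpha_gro` has **no default**: both values ship as named presets
(`GRO_ALPHA_PROSE = 0.5`, `GRO_ALPHA_CRITERIA = 0.9`) and the caller must
choose. Regions with an exactly-zero fold change carry no sign and stay
unclassified.

## Covariate-matched mutation enrichment

Mutation burden tracks expression and replication timing, so the test
compares mutated genes against a matched control set rather than against
all genes. Covariates (default: mean expression, replication timing) are
studentized jointly over test ∪ candidates — (x − mean)/sd with the
sample (n−1) sd; a zero-variance covariate studentizes to zeros with a
warning. Matching is greedy nearest-neighbour without replacement in the
studentized Euclidean space: test genes are visited in input order (the
order is part of the procedure's definition; pre-shuffle with a seed for a
randomized variant), each takes the unused candidate at minimum distance,
ties break by lexicographic gene id. Greedy matching is deterministic and
never beats the optimal assignment (verified against a brute-force
assignment oracle on small instances); what matters for the test is that
it reduces covariate imbalance relative to random control sets, which the
acceptance checks measure directly.

Two statistic flavours share the machinery:

* **structural variants / translocations** — per-gene presence ("at least
  one event in any patient"); the compared statistic is the E2 z-score of
  mutated vs matched genes;
* **simple somatic mutations** — per-gene event counts; the test set is
  the induced genes (z > 2), candidates are the non-induced, and the
  statistic is log10 of the per-kb rate, count/(length/1000). Zero-count
  genes have no finite log rate; they are excluded from the compared
  values (a NaN sentinel), not silently imputed. Multi-event genes are not
  weighted in the presence-based flavours.

**Significance** is a two-tailed resampling test of the median difference
Δ = median(test) − median(matched): both sets are pooled, sorted (so the
result is independent of input order, and label exchange is numerically
symmetric for equal sizes), and repartitioned `n_resamples` times into
pseudo-sets of the original sizes; p is the fraction of resamples with
|Δ*| strictly greater than |Δ|, floored at 1/n_resamples, and Δ = 0
returns p = 1 by definition. Strict exceedance is the correct tail rule
here: with continuous data it coincides with ≥, while with heavily tied
data it keeps perfect separation maximally significant instead of counting
ties against the observed effect. The default scheme repartitions
*without* replacement (a permutation null): measured at null, it rejects
at 4–5% for a nominal 5% level, whereas the with-replacement pooled
bootstrap is conservative for medians at small set sizes (2–3.5%); the
bootstrap variant remains available as `resampling="pooled_bootstrap"`.
The reference analysis scale is 10⁶ resamples; the package default is
10⁴ for interactive use, with the full count one flag away.

## Synthetic data: what it emulates, and what it does not

All generators draw from one `numpy` generator seeded by the mandatory
config seed; one seed fixes every downstream artifact byte for byte.

* **Genome**: uniform random sequence with recognition sites planted at
  density 2×10⁻⁴ per bp per enzyme (≈1 cut/kb combined — the scale of a
  five-enzyme digest, which in a real genome cuts every few hundred bp to
  few kb), plus whatever background occurrences arise by chance; the truth
  table lists planted sites only, so discovered ⊇ planted.
* **Counts**: NB with mean/dispersion parameterization (α = 0.05, typical
  of biological replicates), per-fragment log-normal baselines (log-sd
  0.8), per-sample size factors uniform in [0.7, 1.3] echoed into the
  recorded library totals, 20% of fragments IP-enriched at log2 effect 2,
  and induced fragments (10%, drawn within the enriched set, as R-loop
  induction happens at R-loop-positive loci) gaining log2 effect 1.5 in E2
  conditions, IP assay only.
* **Genes**: log-normal mock means; per-condition sds via a
  gamma-distributed coefficient of variation around 0.2; planted induced
  genes (15%, within the range reported for E2-regulated fractions of the
  transcriptome) get μ_E2 solved so the realized z equals threshold +
  margin + half-normal excess (margin default 2); σ_E2 scales with the
  mock mean so the solve is exact. Replication timing is drawn correlated
  with log mean expression at ρ = 0.5 (early replication tracks high
  expression). Gene lengths are log-normal with median 10 kb.
* **Mutations**: presence flags with base probability 0.1 and odds
  multiplied by the enrichment parameter (default 3) for induced genes;
  simple-somatic counts Poisson with mean length_kb × rate (1/kb) × the
  same multiplier.

Because the generator's effects act directly on the quantities the
pipeline measures, passing benchmarks establishes *internal correctness* —
calibration, recovery of planted effects, determinism — not performance on
real data, where fragment-length biases, mappability, copy-number
variation, antibody efficiency and inter-patient heterogeneity all exist
and are not simulated. Read-level simulation (FASTQ, alignment, sequencing
error) is deliberately out of scope; reads enter as intervals.

## Benchmark problem sizes

The shipped checks use: 1,000 random 10-kb sequences against the
digest oracle; 5,000-fragment 3v3 null and 2,000-fragment planted
simulations for NB calibration (sensitivity ≥ 0.9, empirical FDR ≤ 0.2 at
padj < 0.1); 10,000 random tuples for z-score exactness at 10⁻¹²; 500 null
repetitions at 2,000 resamples for the resampling test's size (rejection
rate in [0.03, 0.07] at nominal 0.05); 100 simulated datasets for matching
quality; and 100 + 100 end-to-end runs (planted 3-fold enrichment vs null)
for power and p-value uniformity. These sizes make the whole suite run in
a few minutes on one CPU while leaving the statistical margins wide.

## Known limitations

* The Wald test with pooled dispersion assumes dispersion is shared across
  fragments; strongly fragment-specific overdispersion (e.g. repeat
  content) would call for the per-fragment estimator plus many replicates,
  or a shrinkage curve, which is not implemented.
* Greedy matching is order-dependent by construction and can be beaten by
  optimal assignment; it is kept because it mirrors the established
  procedure and its imbalance reduction is verified empirically.
* Meta-gene profiles assume per-base coverage fits in memory per contig.
* BAM/CRAM input is out of scope; reads are accepted as BED intervals.
* Peak merging across adjacent fragments and summit calling are
  deliberately absent: the restriction fragment is the unit of analysis.
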