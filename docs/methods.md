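# Methods

## Data model and genotype coding

Input is PLINK text PED/MAP (whitespace-delimited, six leading PED
columns, two allele tokens per variant; phenotype 1 = control, 2 = case,
0/−9 = missing, in which case the individual is dropped). Alleles are
recoded per variant to ordinal codes 1/2/3 (major homozygote,
heterozygote, minor homozygote) and 0 for a pair containing the missing
token "0". The source data never say which allele anchors the coding, so
the **major allele is defined dataset-intrinsically**: the allele with the
higher sample frequency among individuals with a retained phenotype, ties
broken lexicographically. This makes write-then-read a genotype-preserving
round trip (allele labels may swap only at a variant whose sample
frequency is exactly ½). Monomorphic variants store "0" as the unobserved
second allele. More than two observed alleles is a fatal error.

Missingness filtering follows PLINK semantics: variants whose missing
fraction exceeds the variant threshold are removed first, individual
missingness is then recomputed on the surviving variants. The operation
is idempotent and order-preserving.

## Missing genotypes and pattern counts

A single convention is used throughout and matters for reproducing the
worked example, whose tabulated cases number 141 although the study
genotyped 143:

- for **support**, an individual missing a genotype at a pattern variant
  is a non-carrier (it demonstrably does not carry the pattern);
- for the pattern's **2×2 table** and for the **2×9 two-locus table**,
  such individuals are excluded entirely, because their position among
  the observed genotype categories is unknowable.

Consequently `support = cases_with + controls_with` always holds, while
table totals can be smaller than the sample.

## Mining

Transactions are per-individual item lists, item = 3·(variant index) +
genotype code − 1; the phenotype is the transaction label, never a
minable item, since confidence is defined against it. The production
engine is a classic FP-tree with header-table node links and recursive
conditional-tree growth; supports are exact transaction counts, and
itemsets mixing two genotypes of one variant are rejected defensively
(they cannot occur in genotype transactions). An exhaustive enumerator
(`method="bruteforce"`) implements the identical filter/score/order
contract and serves as the correctness oracle; the suite asserts
list-identical output on dozens of randomized instances.

Confidence is one-sided by design (fraction of the target class among
carriers, cases by default); `target_class=0` mines control-enriched
patterns, symmetric by relabeling. `min_confidence=0` disables the
filter. Results are ranked by G descending, ties by support descending,
then canonical pattern order, so reports are byte-deterministic.
Default `max_length=2`: the length-3 candidate space is ~9 V/2 times
larger per added locus, and at fixed sample size the enlarged null
maximum destroys multiplicity-corrected significance; L = 3 is supported
for exactly that comparison.

## G-test and the two-locus partition

All association scores are likelihood-ratio chi-squares,
G = 2 Σ O ln(O/E) with 0·ln 0 = 0, chosen because G is exactly additive
under nested partitioning — the Pearson statistic is not. The 2×9 table's
total (held at 8 df even when genotype-pair columns are structurally
empty, so that the worked example's empty (1,1) column does not change
the reference distribution) decomposes as

    G_total = G_main1 + G_main2 + G_interaction,

with the mains the G of phenotype × single-variant margins (2 df each)
and the interaction obtained by subtraction (4 df), not by fitting a
log-linear model. The subtraction term equals 2N·(I(R;C|P) − I(R;C)) in
mutual-information terms and is therefore **signed**: it is positive when
the genotype pair carries information about the phenotype beyond its
margins (synergy, the digenic signature) and can be legitimately negative
when marginal inter-locus dependence exceeds the conditional one (two
redundant proxies of the same effect). Only floating-point negatives
(magnitude < 1e-9) are clamped to zero; the p-value uses the upper tail
at max(G, 0). The additivity identity is asserted to 1e-9 on random
tables.

On the worked example the partition gives 2.329 + 7.388 + 12.592 =
22.309. The study's published table prints p = 0.0002 for the total, but
the chi-square upper tail of 22.309 at 8 df is ≈ 0.0044 (0.0002
corresponds to 4 df); this package reports the 8-df tail.

Degenerate tables (fewer than two positive rows or columns) score
G = 0 with df 0 and are flagged rather than raised.

## Permutation correction

Family-wise corrected p-values use the Westfall–Young max-statistic
construction: permute phenotype labels, re-run the scan, record each
replicate's maximum G over passing patterns (0 if none), and set
p = (1 + #{null max ≥ G_obs})/(R + 1). The +1 smoothing keeps p in
(0, 1] with floor 1/(R+1); p is non-increasing in G_obs by construction.

Because support is phenotype-free, the support-passing pattern set is
permutation-invariant; the replicate sweep therefore re-tabulates only
carrier-by-phenotype counts (one matrix product per replicate over
pattern blocks of 4096) and recomputes G vectorized. A test asserts this
equals literally re-mining the permuted dataset.

Within replicates the confidence filter defaults to `'match'` — the same
one-sided rule as the observed scan — because the corrected p is exact
under exchangeability only when replicates recompute the identical
selection rule. A `'symmetric'` mode (max of case- and
control-confidence) is available for direction-agnostic scans; it
stochastically inflates the null maximum and is provably conservative
(the suite asserts replicate-wise dominance).

Two properties the simulation tests quantify:

- **Calibration.** The null rejection rate of the *unfiltered* top
  corrected p (support screen only) is exact up to the 10/201
  granularity of R = 200 replicates. With the one-sided confidence
  screen at small sample sizes, passing patterns concentrate on few
  carriers and their G values on a coarse discrete grid; ties under the
  ≥ rule then make the corrected p conservative (attained size ≈ 0.02
  at nominal 0.05 for 100+100 individuals) — valid, but below nominal.
  The calibration study therefore measures the unfiltered statistic and
  the filtered pipeline is separately asserted never to exceed nominal.
- **Power.** Under a double-heterozygote model (penetrance 0.9 in the
  (2,2) cell vs 0.05 elsewhere, MAFs 0.3, 300+300 individuals, 20
  background variants) the causal pattern ranks first with corrected
  p ≤ 0.05 in well over 80% of simulated datasets.

RNG policy: every replicate r uses `SeedSequence((seed, r))`, so results
are reproducible and growing R never changes earlier replicates. All CLI
randomness flows from `--seed`.

The joint-effect statistic Σ_k (n_D,k/n_D − n_U,k/n_U)² over the 3ⁿ
patterns of 1–3 fixed variants uses the same permutation formula, with
n_D, n_U the full group totals (cell sums may fall short under
missingness).

## Trend-test pre-filter

The Cochran–Armitage trend chi-square uses equally spaced scores
(0, 1, 2) on the genotype codes — the conventional additive coding; the
test equals N·corr² between score and outcome, which the suite uses as
an independent closed form. `trend-filter` keeps the top-k variants
(default 2000, a size at which the pairwise pattern scan is still
tractable on one workstation) by this statistic, ties resolved by
original order.

## Simulator

`simulate_digenic` emulates the digenic study design: two causal
variants with HWE genotype frequencies at given MAFs, disease assigned
by an arbitrary 3×3 penetrance matrix, case/control quotas filled by
rejection sampling (exact for desk-scale prevalences; aborts if the
model is practically unattainable), background variants drawn
independently at MAFs uniform in a given range, and MCAR masking at a
given rate. All variants are in linkage equilibrium — the motivating
examples involve variants on different chromosomes — so the generator
does **not** reproduce LD structure, population stratification or
genotyping error; passing simulation tests demonstrate correctness and
calibration under independence, not robustness to confounding in real
cohorts. `reconstruct_from_counts` inverts tabulation exactly (cases
first, row-major cells), which is how the bundled worked-example data
are materialized.

Study-condition defaults used by the simulation tests: null calibration
at 20 variants, 100+100 individuals, 200 replicates, flat penetrance
0.5; power at penetrance 0.9 vs 0.05, MAFs 0.3, 300+300 individuals, 20
background variants, 500/100 dataset repetitions. These sizes keep the
full suite to a few minutes while leaving Monte-Carlo error well inside
the asserted bands.

## Known limitations

- Binary PLINK (.bed), VCF, multi-allelic variants and X-chromosome
  handling are out of scope.
- Pattern length is capped at 3; no closed/maximal itemset condensation.
- The permutation scheme is the straightforward label-permutation
  construction; sequential/adaptive stopping and covariate-preserving
  permutation are not implemented.
- Quantitative traits are not supported; dichotomize upstream if needed.
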