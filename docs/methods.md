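# Methods

This note documents the models and procedures implemented in
`antparentage`, their assumptions, the defaults and why, and what the
synthetic-data tests do and do not demonstrate.

## The detection problem

In a haplodiploid colony with one singly mated queen, males arise from
unfertilised eggs. A male laid by a worker or intermorph ("non-queen son")
carries one allele per locus drawn from his mother's two — one of which
came from the queen's mate. He is genetically distinguishable from a queen
son only when (i) the father's allele at some locus is absent from the
queen's genotype and (ii) his mother happened to transmit that paternal
allele. With unlinked loci indexed by l and informativeness indicator
δ_l ∈ {0, 1} (δ_l = 1 iff the father allele differs from both queen
alleles), the per-colony detection probability is

    P_d = 1 − Π_l (1 − δ_l / 2).

With two loci this yields exactly 0, 0.5 or 0.75. A colony with P_d = 0 is
refused outright: no estimate exists, and the pipeline reports it as
excluded (this mirrors how such colonies must be discarded in practice).

## The likelihood model

Observed per colony: `n_g` genotyped males out of `n_t` produced, `d` of
them detectable non-queen sons. Two stochastic layers separate `d` from the
quantity of interest, the true number of non-queen sons `n_c`:

1. **Sampling**: how many of the `n_g` genotyped males are non-queen sons
   (`n_s`). The default treats this as binomial with success probability
   `n_c*/n_t`; an exact hypergeometric term (simple random sampling without
   replacement) is available via `sampling="hypergeometric"`.
2. **Detection**: `d | n_s ~ Binomial(n_s, P_d)`, assuming fair meiosis and
   no viability effect of marker genotype.

For each hypothesised `n_c* = 0..n_t`,

    L(n_c*) = Σ_{n_s*=d}^{min(n_c*, n_g)} P_sample(n_s* | n_c*) · C(n_s*, d) P_d^d (1 − P_d)^{n_s*−d}.

The ML estimate is the argmax, with ties broken toward the smaller count
(conservative toward queen parentage). The two sampling terms, compared as
normalised vectors (the scale on which the confidence limits use them),
differ by less than 0.01 entrywise once `n_t ≥ 10·n_g`; the hypergeometric
mode is verified entrywise (≤ 1e-12) against an exhaustive combinatorial
enumeration of every genotyping sample and detection outcome for all
configurations up to `n_t = 12`.

### Discrete confidence limits

The likelihood vector is normalised to a discrete distribution over
`0..n_t` with CDF F. Each 95% limit is the innermost value with at least
α/2 = 0.025 of the mass strictly beyond it:

    lower = min { n : F(n − 1) ≥ α/2 },   upper = max { n : 1 − F(n) ≥ α/2 },

clamped so that lower ≤ n̂ ≤ upper (a single-support vector collapses to
lower = upper = n̂). Discreteness makes any such construction inexact; this
one runs marginally below nominal (≈ 0.94 achieved at 0.95 nominal on the
calibration harness below), rather than over-covering as the fully
inclusive alternative does (≈ 0.98). We prefer it because the estimator
this package reimplements reported exactly that slightly-below-nominal
behaviour, and because for a screening analysis an interval that honestly
reflects its resolution is more useful than one padded by construction.

### Simulation calibration

`run_validation` draws colonies with parameters uniform on documented
ranges — `n_t ∈ [5, 100]`, `n_g ∈ [3, min(30, n_t)]` (the genotyped range a
field study of this kind attains), `P_d ∈ [0.25, 0.75]` (between one
informative locus shared across patrilines and two fully informative loci),
`n_c ∈ [1, n_t]` — simulates `n_s` hypergeometrically and `d` binomially,
estimates, and summarises:

- **accuracy**: mean of n̂/n_c over colonies (all drawn with n_c ≥ 1;
  colonies with a true count of zero would leave the ratio undefined);
  raw argmax values are used, not CI-clipped ones;
- **coverage**: fraction of colonies whose true n_c falls inside the 95%
  limits.

At the full size of 18,450 colonies this takes a few seconds and gives
accuracy ≈ 0.96–0.98 (SE ≈ 0.006) and coverage ≈ 0.94, stable across
seeds. The mild downward bias of the ratio at small `P_d`·`n_g` is a
floor effect: colonies whose sample happens to contain no detectable male
are estimated at 0.

## Parental deduction

`infer_parental_genotypes` enumerates, per locus, every queen genotype
(pairs of alleles observed among workers) and minimal father-allele set
(≤ 2 fathers) such that every worker decomposes into one queen allele plus
one father allele, then combines loci, pairing father alleles into
haplotypes via the workers each allele co-occurs in. Candidates are ranked
by (i) number of fathers, (ii) log-likelihood = population-frequency prior
of the parental genotypes (Hardy–Weinberg queen, independent father
haplotypes) plus the likelihood of the worker genotypes themselves
(Mendelian segregation within a paternity-proportion mixture). The data
term matters: a role swap such as queen a/b + father c versus queen c/c
+ fathers a,b can have an identical frequency prior while fitting the
workers very differently.

Some ties are exact and unresolvable from workers — a queen homozygous a/a
mated to a b male produces the same daughters as a b/b queen mated to an
a male. When tied assignments disagree about which allele marks a non-queen
son, the assignment classifying the fewest males as detectable wins
(conservative toward queen parentage, consistent with the estimator's
downward tie rule). When no reference allele frequencies are supplied,
`estimate_colonies` estimates them by pooled counting over the whole
genotype table.

Males with two alleles at any locus are labelled `diploid-suspect` and
excluded from both `d` and `n_g` (diploid males are typically infertile
artefacts of complementary sex determination, not sons in the sense
modelled here); alleles matching neither parent trigger a warning and
exclusion (`foreign`: possible mutation or scoring error).

For a two-patriline assignment, detection probability is defined per
patriline; the paternity-weighted average is a documented extension behind
`multiple_patrilines="average"` (default: refuse).

## Kinship statistics

**Regression relatedness** uses the Queller–Goodnight ratio-of-sums
estimator pooled over colonies and loci: for each focal individual, each of
its allele positions contributes (mean nestmate within-genotype frequency −
reference frequency) to the numerator and (own within-genotype frequency −
reference frequency) to the denominator. Reference frequencies for each
colony's terms exclude that colony (bias correction), and the SE comes from
jackknifing colonies. The pedigree expectation for full sisters under one
singly mated queen is (1 + 1/2)/2 = 0.75 — shared paternal allele with
certainty, shared maternal allele half the time — and the estimator
recovers it to ±0.02 on ≥ 500 simulated single-patriline colonies.

**Effective mating frequency** uses the sample-size-corrected estimator
q_e = (n − 1)/(n·Σŷᵢ² − 1) from paternity proportions ŷᵢ among n genotyped
daughters; q_e is undefined (and reported as such) when n·Σŷᵢ² ≤ 1, which
can occur at very small n with even paternity.

## Sex-allocation economics

Cost ratio c = (f/m)^k with mean dry masses f (virgin queens) and m
(males) in mg and metabolic parameter k = 0.7 by default (the across-species
average used in ant sex-ratio work; configurable). Defaults f = 1.41,
m = 0.09 give c ≈ 6.86. Sexual production S = c·F + M (male equivalents);
numerical sex ratio F/(F + M), undefined and flagged when a colony produced
no sexuals. Life-for-life relatedness of workers and of the queen to the
colony's males is affine in the male-parentage composition with the
standard haplodiploid coefficients (worker: brother 0.25, nephew 0.375;
queen: son 0.5, grandson 0.25). Downstream GLM fits on S and the sex ratio
are ordinary quasi-binomial regressions best done in a general statistics
package; this module only constructs their covariates (including the
square-root-transformed intermorph count).

## The synthetic colony generator

`simulate_colony` draws a queen (two independent alleles per locus from the
population pool) and K father haplotypes (default K = 1; K = 2 defaults to
a 0.8/0.2 paternity split), builds workers and intermorphs as one random
queen allele plus the father allele per locus, and assigns each male a
mother class — queen, worker or intermorph — to match a configured true
non-queen-son proportion (realised count = round(p·n_males); default
p = 0, the queen-only null, since no field prior for this proportion
exists and it is the quantity under study). Non-queen sons take one random
allele of a randomly chosen mother of their class. Loci are unlinked and
simulated independently; mutation is ignored (a within-colony, two-locus
setting); there is no colony growth, spatial structure, or egg-survival
model. Defaults for composition (525 workers, 4 intermorphs) sit at the
observed medians of the study system; worker counts of 100–1400 are the
realistic range. A configurable masking rate (default 0) blanks genotypes
to exercise missing-data handling. A single seeded generator drives each
simulation run and the seed is recorded in the run log.

Because the generator implements exactly the pedigree assumptions the
estimator makes (single queen, fair meiosis, no genotyping error, no
linkage), passing tests demonstrate internal consistency and correct
mathematics — not robustness to the ways real colonies violate those
assumptions (queen turnover, scoring error, null alleles, linkage).

## Numerical and interface choices

- Likelihood vectors are computed with vectorised binomial/hypergeometric
  pmfs; no log-space tricks are needed at `n_t ≤ ~10⁴`.
- Argmax ties break to the smallest index; CI limits clamp to bracket the
  estimate; degenerate vectors collapse the CI to the estimate.
- CSVs are comma-separated UTF-8 with mandatory headers; missing genotypes
  are empty fields; allele labels are opaque strings. Exit codes: 0 OK,
  2 schema error, 3 estimation refused everywhere.
- Problem sizes in the test suite (18,450-colony calibration runs, 500- to
  2,000-colony relatedness simulations, exhaustive oracle up to n_t = 12)
  were chosen so the entire suite runs in well under a minute while leaving
  Monte-Carlo noise far below the tolerances asserted.

## Known limitations

- Parentage deduction supports at most two patrilines and reports
  inconsistency beyond that; no general sibship reconstruction.
- No genotyping-error model: a single mistyped worker can render a colony
  inconsistent rather than down-weighting the offending genotype.
- The accuracy/coverage calibration depends on the (documented) uniform
  parameter ranges; other ranges shift the summary statistics by a few
  percent.
- The SD of the cost ratio is not propagated from the mass SEs; c is
  reported as a point value.
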