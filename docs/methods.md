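# Methods notes

## Data model and conventions

Internal coordinates are 1-based inclusive (VCF-style) because variant
positions dominate the data model; BED input/output is converted at the
boundary (0-based half-open). A call set is a mapping from sample id to
`VariantRecord` lists; only single-base substitutions are modelled.
Trinucleotide contexts are collapsed to the pyrimidine strand, giving the
standard 96 substitution channels and a 32-context site census; collapsing
is an involution-respecting map, so purine- and pyrimidine-encoded
spellings of the same physical mutation land in the same channel. CpG
status is strand-symmetric: a variant is CpG iff its collapsed context has
a 3' G. "CpG>GpG" means C>G at a CpG; "CpG transversion" adds C>A.

## Mosaic filters

Post-calling filters run in a fixed order so removal reasons are
deterministic: VAF ≤ 0.40 (germline heterozygote cap), exact two-sided
binomial test of alt/total against 0.5 at p < 1e-6 (the VAF must be
significantly non-germline), population allele frequency ≤ 0.001 with a
missing frequency treated as 0 (novel), and ≥ 4 supporting alt reads.
Mapping-quality and duplicate-read criteria are alignment-level concerns
and are represented only through the read counts supplied. Filtering is
idempotent by construction.

## Burden model

Per-sample counts are NB(μ, k), Var = μ + μ²/k (statsmodels' α = 1/k),
log link, fitted by maximum likelihood; the AIC counts the dispersion as a
parameter, and a non-convergent NB falls back to a flagged Poisson GLM.
Covariate selection is forward and AIC-greedy from the intercept-only
model, with deterministic name-order tie-breaks. The staged scheme —
select covariates *without* diagnosis, then add diagnosis — is kept, and by
default permutations refit the final model on shuffled labels without
re-running selection (a flag enables full re-selection; it is slower and
stricter). The two-sided permutation p uses the add-one estimator so it is
never zero. Note that plain AIC forward selection admits a pure-noise
covariate with probability P(χ²₁ > 2) ≈ 0.157 each; this is a property of
the selection rule, not a defect, and the tests assert exactly that rate.

The power simulation keeps the case variance while dividing the case mean
by a fold f for controls, re-solving the NB size as m²/(v − m); an upward
shift (f < 1) can make the mean exceed the preserved variance, which is
reported as an error naming the fold. The test statistic is the NB group
Wald p at α = 0.05. At 60/25 the ML Wald test is mildly anticonservative
(null rejection ≈ 5.5–6%), which the calibration band accounts for.

## Track enrichment

The binomial log-link model uses S_i = region length × genomes in the
group as the sites available to be mutated, matching the per-genome
opportunity logic used throughout. The score enters as log(score + 1)
(raw-score option behind a flag); an indicator track reduces the model to
a region-set test. Because per-site rates are ≪ 1, the log-binomial MLE is
warm-started from the Poisson-offset solution; if the binomial fit fails,
the Poisson approximation is used and flagged. Permutation is at the
sample level (group sizes fixed) with group sums recomputed, since design
rows are group aggregates. Regions of a scored track are assumed disjoint;
overlapping regions should be merged upstream.

## Context-adjusted O/E

Genome rates are count/census per channel, computed once per cohort
(pooled across samples) to match the pooled O/E framing; a per-sample mode
exists for the cancer-style per-sample scan, using each sample's own
rates so the ratio reflects localisation rather than burden. Every genomic
site is counted once (both strands collapse to one context), and the
whole-genome expected count is identically the observed total.

Exact Poisson machinery: CI from χ² quantiles (lower q(.025, 2O)/2E, upper
q(.975, 2O+2)/2E); one-sided p = P(Pois(E) ≥ O); two-sided p doubles the
smaller tail, with the minimum-likelihood summation method behind a flag.
For O = 2, E = 0.083 this gives ratio 24.096, CI [2.92, 87.0] and
one-sided p = 0.0033; published analyses sometimes print slightly
different CI endpoints or p-values for these counts depending on rounding
and sidedness conventions, and no attempt is made to reverse-engineer
those choices.

Distance machinery: every mutation and every site is assigned to its
nearest midpoint (ties to the smaller coordinate), so overlapping windows
of nearby midpoints are implicitly unioned and nothing is double-counted.
Annulus differencing subtracts both counts and censuses of nested windows,
making annuli independent; observations are conserved by construction.
The binned case/control profile scales each bin's count by covered sites ×
genomes, and the two-group comparison is the exact conditional binomial
test of the two Poisson counts given their opportunity weights (with a
Clopper-Pearson-derived CI for the rate ratio) — the standard exact
treatment of unequal exposures. All reference sites count as opportunity;
a callable-site mask can be supplied where real data require it. DHS
activity thresholds default to the top decile for profiles and the top 5%
for genome-wide O/E.

## Hotspots and recurrence

The SVSS collision null places N mutations of the class independently and
uniformly over the n candidate sites (for T>G, the T/A census of the
actual reference), so the expected number of same-site pairs is
μ = C(N, 2)/n, tested by the upper Poisson tail; the null is validated
against a Monte-Carlo collision oracle rather than any published p-value,
whose exact conditioning is not specified. The two-rate bound drops the
cross terms of E[Nr] = (λ1²/2)n1 + (λ2²/2)n2, which is conservative, so
λ1 ≥ 2·Nr/N_mut; with Nr = 3 recurrent pairs among 266 T>G mutations over
1.7×10⁹ T/A sites this gives λ̄ = 1.56×10⁻⁷ and a hotspot fold of
1.44×10⁵. (An alternative reading of the algebra gives 0.027 for the
bound and hence 1.73×10⁵; the package uses the 2Nr/N form, which is the
internally consistent one.) The conditional recurrence density tallies,
over ordered sample pairs, mutations in the second sample at each absolute
distance 0–100 nt from a focal mutation in the first, divided by the
number of (pair, focal) opportunities and normalised to average 1 over
distances 91–100; allele identity is required for SVSS but not for the
density profile. Carrier stratification of per-sample O/E uses the
two-sided Wilcoxon rank-sum test, exact for groups ≤ 25 without ties.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test. The
toy genome is a single 5 Mb contig of i.i.d. bases at GC fraction 0.42 —
large enough for stable context statistics, small enough for desk-scale
runs. 400 TFBS of 20 bp are placed one per equal slot (guaranteed
disjoint) and each receives a DHS intensity from Gamma(shape 2, scale 1);
"active" means top decile by default. Promoters are the 2.5 kb upstream
of 120 TSS. The cohort defaults to 60 cases / 25 controls with per-sample
counts NB(mean 35, size 10) — variance ≈ 2.2× the mean, the overdispersion
regime the burden model exploits. VAFs are Beta(2.2, 30) truncated to
(0, 0.40], emulating clonal prenatal mosaics in the ~0.01–0.40 range, with
read support binomial at depth 239 conditioned on at least one alt read;
an optional contamination flag injects VAF ≈ 0.5 germline-like variants so
the filters can be exercised from the simulator itself.

Placement is an explicit mixture: uniform background over interior
(site, alt) pairs; for cases, an extra T>G component of weight
(fold − 1) per eligible T/A site within the enrichment halfwidth of an
active midpoint, and likewise for CpG>GpG — so the per-site rate of the
targeted class inside the windows is exactly the configured fold times
background, which is what the annulus O/E recovery tests assert. Hotspot
sites are drawn once among interior T/A positions and fire independently
per case with a per-sample probability, always emitting the same T>G
variant (mirroring the case-restricted recurrence the model targets).
Every record carries its generating class, and per-class counts in the
ground truth sum to the emitted records per sample.

Randomness uses one root seed with named spawned streams (reference,
tracks, cohort, covariates) and per-sample child streams, so adding
samples does not reshuffle earlier ones and identical configurations
reproduce files byte-identically.

What the generator does **not** emulate: realistic chromatin landscapes,
diploid genomes or phasing, sequencing error and mapping artefacts,
mutational-signature mixtures beyond the planted classes, and
inter-region rate heterogeneity beyond the planted processes. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under its stated assumptions, not performance on real call sets.

## Problem sizes used in tests

Simulation-backed tests are sized for a desk run: recovery tests use a
2 Mb genome with 12/8 samples; null-calibration suites use 80–100
replicate datasets with 99–199 permutations each (burden) or 150
permutation fits (track interaction); power calibration at fold 1 uses
500 replicates of 60/25 cohorts, and the CI-coverage check 400 draws per
expectation. The full suite runs in under two minutes on one CPU.

## Known limitations

- The forward-selection permutation default (selection fixed, labels
  shuffled) slightly understates selection uncertainty; the strict mode
  re-selects per permutation at ~10× cost.
- The log-binomial GLM can be fragile when per-site rates approach 1;
  the Poisson fallback is flagged but changes the link's interpretation
  marginally.
- The exact conditional rate-ratio CI is derived from the Clopper-Pearson
  interval and is conservative, as exact intervals are.
- Burden covariates are assumed complete-case; no imputation is provided.
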