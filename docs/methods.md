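# Methods

## The statistic

For a gene pair (i, j) and K cases, the rare-variant interaction burden
(RVIB) is

    Y_ij = sum_{k=1..K} max { w_{i,p} g_{i,p,k} * w_{j,q} g_{j,q,k} }

with the max over all cross-gene variant pairs (p, q), g the minor-allele
copy number (0/1/2; no-calls count 0), and w = ceil(s / b) an integer
functional weight derived from a pathogenicity score s in [0, 1] at bin
length b. Only subjects simultaneously mutated in both genes contribute.
Because all terms are nonnegative the max factorizes into per-gene maxima,
which is how the implementation computes it; the exhaustive double loop is
kept in the test suite as the oracle. The unweighted burden y_ij sets all
weights to 1. The same formula on control samples gives the seventh
regression predictor X7.

## Baseline model

Under the null, Y_ij for a background pair is modeled as a truncated
negative binomial, TNB(mu, theta, t): an NB with mean mu and variance
mu + mu^2/theta renormalized over {t+1, t+2, ...}. The truncation point
t in {0, 1, 2} absorbs the heavy excess of pairs with little or no
co-mutation, which no untruncated NB fits. mu denotes the parent NB mean
(the log link below targets this mu, not the truncated mean).

The log link regresses the baseline on products of six per-gene genomic
features — CDS length (X1), accumulated MAF of the gene's qualifying rare
variants (X2), their product (X3), missense and LoF observed/expected
constraint ratios (X4, X5), GC content (X6) — plus the pair's control
burden X7 when at least 50 controls are available:

    ln mu_ij = beta0 + sum_l beta_l X_{l,i} X_{l,j} + beta7 X7_ij

(beta, theta) are estimated jointly by maximum likelihood: L-BFGS-B on
(beta, log theta) with an analytic gradient (the truncation term has closed
form for small t), predictors standardized internally for conditioning and
coefficients reported on the original scale. Initialization: least squares
of log Y on the standardized design, dispersion by method of moments;
gradient tolerance 1e-6, at most 500 iterations. Only pairs with Y > t
enter the likelihood; a fit is refused when fewer than 5000 such pairs
remain, since a flexible baseline estimated on a small background overfits
and masks true signals.

Because the exponential link is an approximation trusted only where it was
estimated, predictions clip the linear predictor to the central 99.8%
quantile range of the background fit set's linear predictors. Without this
guard a pair whose control burden lies beyond the background range receives
an exponentially extrapolated (absurdly large) baseline; the quantile form,
rather than the absolute min/max, keeps a handful of extreme fit points —
potentially including a disease pair not yet purged from the background —
from defining the trusted range.

## Testing a pair

Enrichment is assessed by the signed deviance residual under the TNB
likelihood, d = sign(Y - mu_T) sqrt(2[l(Y; Y) - l(mu; Y)]) with mu_T the
truncated mean. Residuals are standardized over the background fit set:
z-scoring followed by a one-term Cornish-Fisher adjustment that removes the
background skewness (count deviances are right-skewed at low means), with
the quadratic term saturated at z = 3/skew so the map stays monotone for
extreme signal residuals. The standardized background has mean 0 and
variance 1 by construction. The one-sided p-value is 1 - Phi(d'); pairs
with Y <= t lie outside the truncated support, cannot show enrichment, and
receive p = 1. Plain z-scoring leaves the background's right skew in the
nominal normal tail and inflates far-tail rates under the null; the
skewness-adjusted form keeps the null calibration experiment inside its
nominal bands (see the replicate experiments).

## Recursive background purification

Disease-associated pairs must not contaminate the baseline. Starting from
all pairs with Y > t, the model is fitted, p-values computed for all pairs,
BH-FDR q-values formed, and pairs with q <= 0.1 removed from the
background; this repeats until the removal set is unchanged between
iterations or empty (at most 20 iterations; identical consecutive removal
sets operationalize "the significant set became stable"). A cell is
abandoned if the background would drop below 5000 pairs. Final p/q-values
for all pairs always come from the single stable model.

## Grid search over (b, t)

Score bin lengths b in {0.025, ..., 0.5} (step 0.025) and truncation
points t in {0, 1, 2} form a 60-cell grid. Per feasible cell the background
MLFC — mean |log2(p_(r) / (r/(n+1)))| over the ordered background p-values,
0 for perfect calibration — and the number of q < 0.05 pairs are computed.
Cells are ranked by MLFC (ascending) and significant count (descending);
the minimal rank sum wins, ties broken by lower MLFC, then smaller b, then
smaller t. Infeasible cells are excluded from ranking rather than
penalized. The MLFC is computed over the background (fit-set) p-values:
pairs outside the truncated support carry p = 1 by construction and say
nothing about calibration.

## QC and variant selection

Genotypes with DP < 8 or GQ < 20 become no-calls (each mask skipped when
the VCF lacks the field). Sites are dropped when the Hardy-Weinberg exact
test (Wigginton-style, computed on control genotypes only, where
association cannot distort it) gives p <= 1e-5, when they carry more than
four alleles, or when more than 20% of genotypes are missing after masking.
Masking precedes the HWE test so that the filter is idempotent and
low-quality calls do not drive it. The burden uses non-synonymous variants
(missense, start/stop-loss, stop-gain, splicing, frameshift,
non-frameshift) with reference-panel MAF strictly below the cutoff
(default 1%); genotypes are oriented to the reference panel's minor allele.
Candidate pairs require an interaction-prediction score strictly above the
threshold (default 0.8), both genes present in the feature table with at
least one retained rare variant, and neither gene in the exclusion list
(by default eight genes with extreme CDS length). X2 is the sum of
reference-panel MAFs over the gene's qualifying rare variants (in-sample
MAFs are available as an option).

## Two-locus disease models

Disease odds are alpha * m(gA, gB) with the multiplier tables:

| model          | m(gA, gB)                                                        |
|----------------|------------------------------------------------------------------|
| threshold      | 1 + theta once both loci carry a risk allele, else 1             |
| multiplicative | (1 + theta)^(gA * gB)                                            |
| classic        | 1 + 4 theta at (2,0) and (0,2); 1 + 2 theta at (1,1); 1 elsewhere |

theta is solved so the maximal-risk cell's odds ratio versus the
double-baseline cell equals the prescribed genotype OR (threshold:
1 + theta = OR; multiplicative: (1+theta)^4 = OR; classic: 1 + 4 theta =
OR), and alpha by Brent root-finding so the HWE-weighted penetrance equals
the prescribed prevalence (verified to 1e-10). Cohorts are built by drawing
two-locus genotypes under HWE and assigning disease with probability
alpha m / (1 + alpha m), rejection-sampling (capped at 1e7 draws) until the
case and control quotas are met.

## Synthetic cohorts: what they emulate and what they do not

The generator mimics the structure of a rare-variant case-control study:
500 background genes with lognormal coding lengths (median 1.3 kb, sigma
0.75), rare-variant counts proportional to CDS length (~1 per 750 bp),
reference MAFs log-uniform on (0.0008, 0.009), Hardy-Weinberg genotypes
independent across variants, pathogenicity scores skewed benign
(Beta(1, 3) — real deleteriousness spectra concentrate near 0, which is
what gives a confidently damaging variant its weight contrast), and 40000
candidate pairs with prediction scores above 0.8. This puts per-gene
cumulative carrier frequencies near 2%, so most pairs are co-mutated in no
or very few subjects — the regime that motivates the truncation — while
roughly 6000-7000 pairs carry enough burden to form the background fit
at n = 1000, comfortably above the 5000-pair rule in every replicate. Gene features genuinely drive the expected burden (variant count
scales with X1; X2 is the realized MAF sum), giving the regression real
signal; constraint and GC features are uninformative noise in the
generator. Optional stratified mode draws allele frequencies for half the
controls from a Balding-Nichols divergence (Fst = 0.1) of the case pool.

Planted signal: two causal variants (one per target gene, pathogenicity
score fixed at 0.9 — the inserted pair models a confidently deleterious
disease mechanism) become the only variants of two genes cleared of
background signal; their recorded reference-panel MAF is min(population
MAF, 0.009) since semi-simulated signal rides on vehicle variants that stay
rare in the reference panel even when simulated at higher population
frequency.

Not emulated: linkage disequilibrium (background genotypes are
independent), relatedness, sequencing artifacts correlated across samples,
realistic constraint-burden correlations, or annotation error. Passing the
synthetic experiments therefore shows the statistical machinery is
calibrated and powered under the stated generating process, not that real
cohorts will behave identically.

## Experiments and desk-scale choices

Replicate experiments use a reduced grid (b in {0.05, 0.1, 0.2}, t in
{0, 1}), 50 replicates per condition, and per-replicate seeds spawned from
a master seed. The null experiment (n = 1000, balanced labels, no signal)
reports the chosen cell's background MLFC per replicate and pooled
background tail rates at alpha in {1e-3, 1e-4, 1e-5}. Power experiments
plant one causal pair and report the fraction of replicates with the target
pair's final p-value below 0.05, with Clopper-Pearson exact 95% intervals.
These sizes keep a full replicate around one to four seconds while
preserving the 5000-pair background rule and the data-driven (b, t)
selection.

## Numerical notes and degenerate inputs

* Empty variant sets, zero controls, and all-missing genotypes are defined:
  empty maxima are 0, zero controls disable X7, missing genotypes carry no
  interaction evidence.
* tnb_pmf accepts t = -1 (plain NB); theta is bounded in [1e-4, 1e7] during
  optimization; the Poisson limit is reproduced at theta = 1e6 to 1e-4.
* Deviance under truncation can make the "saturated" likelihood at mu = Y
  slightly smaller than the fitted one for Y just above t; the squared
  deviance is floored at 0.
* Ties in the grid ranking are broken deterministically (MLFC, then b,
  then t); the whole pipeline is deterministic given its inputs.
* BH-FDR and the exact binomial intervals come from statsmodels and scipy
  respectively; the truncated-NB likelihood, its gradient, and the HWE
  exact test are implemented here (no installed package provides them) and
  are tested against scipy/enumeration oracles.

## Known limitations

* The log-linear form in raw feature products is the model's assumption,
  not the generator's truth; the quantile clipping and the recursive
  purification are what keep it calibrated at the extremes.
* Power bands are specific to the generator's carrier-frequency and score
  spectra; cohorts with very different background co-mutation rates will
  shift absolute power.
* The classic-model power setting is intrinsically limited by the
  probability that at least one case is simultaneously mutated at the
  planted loci (~0.85 at MAF 0.5%, OR 20, 2000 cases); misses there are
  irreducible, not a calibration failure.
* Case-only designs, >2-gene interactions, continuous traits, permutation
  p-values, and LD-aware simulation are out of scope.
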