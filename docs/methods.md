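# Methods

## Preference and isolation statistics

**Strength of preference.** For one dichotomous trial,
SOP = (T_C − T_H)/(T_C + T_H) with T_C, T_H the association-zone times
(seconds). The statistic is undefined when the focal fish never entered
either zone (T_C + T_H = 0); such records carry a missing value and are
excluded from summaries with a warning rather than scored as 0, because
0/0 has no preference interpretation and real assays acclimate fish
until both zones have been visited. Group summaries report the
arithmetic mean, SE = sample SD/√n, and a two-sided test against zero;
whether that test is a one-sample t or a Wilcoxon signed-rank is an
explicit argument (default t), since no principled switching rule exists
at these sample sizes. Pooling across populations within a geographic
context is n-weighted, which is identical to the mean of the
concatenated raw records.

**Isolation index.** For each population × species × behavior,
I = (C − H)/(C + H) on mean counts across replicates; both-means-zero
yields a missing value (not 0, not an error). Total isolation sums
counts over a behavior subset within each replicate × species and
applies the formula to the sums. Two aggregation paths exist and are
labelled in every output: per-replicate totals (the GLS response) and
population totals, which average the *summed counts* across replicates
before applying the formula — not the per-replicate index values, a
distinction that matters whenever replicates differ in activity.
Table-style output reports the n−1 sample SD across replicates
(undefined, not 0, for a single replicate).

## Linear model for preference

SOP is regressed on geographic context, sex, population nested within
context, and the population × sex interaction. Populations exist only
inside one context, so population enters through within-context
contrasts (no cross-context population main effect); the population ×
sex term spans the full between-population contrast space crossed with
sex, and therefore includes the context × sex degree of freedom (3 df
with four populations in two contexts). Encodings are sum-to-zero, and
term-wise F tests use Type III (marginal) sums of squares — the design
is unbalanced (one cell of 16 among cells of 18), so sequential sums
would confound term order with the tests; Type I remains available via
`ss_type="I"`.

Backward elimination refits after dropping the single eligible term
with the largest p-value above alpha (default 0.05). Eligibility
honours marginality: a term whose effective factor set is strictly
contained in a retained term's set is protected, so a significant
interaction keeps its main effects in the model and a nested term keeps
its outer factor.

Least-squares means average model predictions over a reference grid of
estimable cells (only observed population-within-context combinations
enter the grid) with equal weights. Pairwise contrasts use t statistics
on the residual degrees of freedom; the Bonferroni family is the set of
contrasts emitted in one call — the smallest defensible family absent a
stated convention.

## Heteroskedastic GLS for total isolation

Per-replicate total isolation is modelled with fixed effects
(default: context only) and a separate residual variance per level of a
grouping factor (default: context, the axis along which spread differs
most in this design). The fit iterates weighted least squares: given
group variances, estimate coefficients; given residuals, update each
group's variance as its residual sum of squares divided by its
observation count minus its summed leverage. The leverage correction
makes the saturated two-group model reproduce the Welch two-sample
closed form exactly (group variances become the usual n−1 sample
variances), and removes most small-sample bias elsewhere. Convergence
is declared when the largest relative variance change falls below 1e-8
(error after 200 iterations); a variance group needs at least two
observations. With a single variance group the fit is exactly ordinary
least squares.

Where a second, range-restricted species is present, its observations
can be recoded as sympatric before fitting (`resident_species`),
reflecting that a congener whose entire range lies inside the focal
species' range is sympatric in every trial. An exchangeable
within-replicate correlation can be supplied as a fixed value for
sensitivity checks; the default model omits it, matching the common
outcome that a replicate random effect adds nothing at three replicates
per population.

## Nonparametric tests and effect size

Mann–Whitney U and Wilcoxon signed-rank both return a tie-corrected,
continuity-corrected normal Z with its two-sided p, plus an exact
two-sided p from full enumeration where feasible (all group labelings
for combined n ≤ 20 without ties; all 2^n sign patterns for n ≤ 12).
Zero differences are dropped before signed-ranking (the Wilcoxon
convention). Two-sided exact p is twice the smaller tail, capped at 1.
The normal approximation tracks the exact p within 0.05 whenever the
smaller group has ≥ 3 observations (Mann–Whitney) or n ≥ 4 nonzero
differences (Wilcoxon) — verified exhaustively in the test suite; below
that the approximation is intrinsically crude for any implementation
and the exact p is the one to use. Degenerate inputs (identical pooled
samples, all-zero differences, zero variance) return results flagged
`degenerate`, never silent NaNs. Cohen's d uses the pooled n−1
standard deviation.

## Synthetic trial generator

**Dichotomous trials** use a two-stage beta allocation. Activity — the
fraction of the 900 s trial spent in either association zone — is
Beta-distributed with mean 0.7 and precision 10 (fish in breeding
condition spend most of the trial engaged, with realistic spread). The
conspecific share c of that active time is Beta with mean (1 + β)/2 and
precision κ, so SOP = 2c − 1 has expectation exactly β: the generator's
bias parameter is the estimand, which gives clean recovery targets, and
T_C + T_H ≤ duration holds by construction. The default κ = 5 puts
per-group standard errors at n = 18 in the 0.08–0.12 range typical of
published association-time assays. β = ±1 is allowed as a degenerate
boundary (share fixed at 1 or 0).

**Stream counts** draw, per replicate × species × behavior, a
conspecific count with mean λ(1 + ι)/2 and a heterospecific count with
mean λ(1 − ι)/2. With dispersion δ > 0 the Poisson mean is gamma-mixed
(negative-binomial-type marginal), since real tallies routinely show
standard deviations rivalling or exceeding their means; δ = 0 gives
pure Poisson. The per-behavior index converges to ι as λ grows.

**The study-condition dataset** (`make_paper_like_dataset`) emulates
four populations (two per context) × two sexes with n = 18 per cell
(one cell of 16), group biases matching published group means (females
0.73/0.31/0.27/0.02, males 0.30/0.48/0.11/0.20 for the two sympatric
and two allopatric populations), and three stream replicates per
population with λ per behavior on the published count scale
(solicitation ~180, chases ~100–130, spawning 2.5 so interspecific
spawning is rare) and δ = 0.35. The context signal in the stream data
is carried by male solicitation (ι = 0.95 sympatric vs 0.50–0.55
allopatric for the focal species; the range-restricted congener is
biased everywhere), so excluding solicitation behaviors removes the GLS
context effect — the built-in sensitivity structure.

Randomness: one global seed drives independent per-group substreams
derived from a CRC of the group label, so adding a group never perturbs
another group's draws; identical seeds give bit-identical datasets.

What the generator does **not** emulate: within-trial temporal dynamics
(no movement model, only allocation), side biases, repeated use of
stimulus fish across trials, or any dependence between an individual's
dichotomous and stream behavior. Passing tests therefore demonstrate
that the estimators and tests behave correctly under the assumed
allocation/count models at the study's sizes — not that those models
describe any particular field population.

## Calibration and power

Monte-Carlo routines simulate the two-context comparison directly from
the share model (activity cancels out of SOP). At n = 18 per group and
1,000 replicates, both the Mann–Whitney test and the context F test
reject a true null at rates consistent with the nominal 5% level. For
power, the bias β achieving a requested Cohen's d against β = 0 is
found by root-finding on the model's closed-form SOP standard deviation
2√(m(1−m)/(1+κ)), m = (1+β)/2. At n = 36 per group, power for a
medium effect (d ≈ 0.75) is roughly double that for a small effect
(d ≈ 0.44) — the pattern behind a female-significant /
male-nonsignificant pooled contrast. Problem sizes (1,000 null
replicates, 500 power replicates) keep each routine under a few seconds
while holding Monte-Carlo error on a rate near 0.05 to about ±0.007.

## Numerical and I/O choices

- CSV interchange: comma-separated UTF-8 with header; floats written
  with `%.17g` and parsed in round-trip mode, so read(write(x)) is
  bit-exact. Blank optional fields are missing, never zero.
- Neutral-zone time is not stored (duration − T_C − T_H by definition).
- Species labels are free text; only the five behavior classes and the
  context/sex/target enums are closed vocabularies.
- All computation runs at full precision; reports round half-even at
  render time (default two decimals) to avoid halfway-case drift.
- Rank-deficient designs raise an error naming the aliased terms;
  constant responses yield F = 0, p = 1 flagged degenerate.
- Pipeline outputs contain no timestamps or host information, so a
  rerun with the same seed is byte-identical.

## Known limitations

- The GLS estimates variances by iterated moment updates, not REML;
  with more variance groups than the two or three used here,
  small-sample behavior is unverified.
- Exact rank-test enumeration is combinatorial; it is capped at
  combined n = 20 (Mann–Whitney, no ties) and n = 12 (Wilcoxon).
- LS-means weight reference-grid cells equally; population-size-weighted
  margins are not implemented.
- The backward selection is the classical p-value-driven procedure, kept
  for fidelity to field practice; information-criterion selection is out
  of scope.
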