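# Methods

## The decision problem

Two strategies for creating a left-sided circular-stapled colorectal
anastomosis are compared: a manual circular stapler (MCS, €425 per device)
and a powered circular stapler (ECPS, €553). The clinically and economically
dominant event is anastomotic leakage (AL): leak patients consume imaging,
microbiology, interventional radiology, reoperation time, intensive care and
long hospital stays, and a subset end with a definitive (permanent) stoma.
The analysis chain is: construct comparable arms (propensity matching),
compare leak outcomes, account direct costs per patient, evaluate a decision
tree per strategy, and propagate parameter uncertainty by Monte Carlo.

## Bundled reference scenario

`staplecea.defaults` encodes a 330-patient matched comparison (165 per arm)
priced at 2021 Spanish regional tariffs. Key quantities: leak events 22/165
(MCS, 13.3%) vs 8/165 (ECPS, 4.8%); in the MCS arm 15 leaks were grade C
(reoperation) and 7 grade A/B (conservative); all 8 ECPS leaks were grade C.
Definitive stomas: 11 vs 5 (marginal counts). Per-resource unit prices and
per-arm cost totals and mean ± SD are tabulated per resource; the overall
means are €9,700.12 (MCS) and €6,238.38 (ECPS), and the mean cost among
leak patients is €30,649 — the generator's calibration constant.

Internal consistency caveats of the scenario ledger, all handled explicitly:

- the ECPS intensive-care row prints a mean (1.02) irreconcilable with its
  total; the package uses total/n = 91.02, reading the printed mean as a
  dropped-digit typo;
- the MCS stomatherapy and ostomy-device rows have means that disagree with
  total/n in ways no typo explains; the generator follows the mean ± SD
  column, the summary table reports both readings side by side;
- the per-resource mean column sums to €8,294.57 (MCS, incl. stapler) and
  €5,449.73 (ECPS), not the printed overall means. The package therefore
  keeps two deliberately separate calibrations: the **cohort generator**
  reproduces the per-resource component moments (so its expected arm mean is
  the component sum), while the **reference decision tree** reproduces the
  overall means (which feed the ICER). Tests pin each against its own
  target.

The scenario also carries two externally reported effectiveness figures
(98.27% / 93.69%). They match neither 1 − stoma proportion (96.97% / 93.33%)
nor 1 − leak rate, and their derivation is not recoverable; they are treated
as external inputs for one reference ICER computation and are never claimed
as model output.

## Synthetic cohort generator

One patient row = covariates (age, sex, Charlson index, ASA, diagnosis,
surgical approach), device arm, leak outcome and grade, definitive stoma,
per-resource utilization and derived total direct cost.

**Arm assignment** is a logistic function of age, Charlson index, diagnosis
and approach with mild default coefficients, so the pre-matching pool is
genuinely confounded (older, sicker, Hartmann-reversal patients receive ECPS
more often) and the matcher has real work to do.

**Outcomes.** Leak is Bernoulli per arm (defaults 22/165 and 8/165 — the
reference tables print both 8 and 9 powered-arm leaks; 8/165 = 4.8% is the
self-consistent reading and the default, with the count exposed as a
parameter). Grade is a per-arm A∪B vs C split; grades A and B are merged
because they share conservative management. Definitive stoma is conditional
on leak status: most stomas follow grade-C leaks, but leak-free stomas are
allowed (clinically real, e.g. very low anastomoses). Defaults apportion the
marginal counts as MCS 9/15 after grade C plus 2/143 without leak, ECPS 4/8
plus 1/157, reproducing the marginal 11 and 5 in expectation.

**Costs.** Each resource's per-patient cost is gamma-distributed
(method-of-moments from mean/SD; gamma because costs are non-negative and
right-skewed, the standard choice in health economics; zero SD degenerates
to a point mass). Costs are drawn per leak/no-leak stratum. The stratum
means derive from the marginal moments via a per-resource leak relative risk
ρ_r = 1 + s·e_r, where e_r are fixed clinical excess weights (ICU and
interventional radiology highest, operative time lowest) and the single
scalar s is solved numerically so the pooled expected cost among leak
patients equals €30,649. Stratum SDs keep the marginal coefficient of
variation. Utilization quantities are cost/unit-price (continuous
"expected-utilization" units), so per-patient accounting through the costing
module reproduces each draw exactly. Every patient consumes exactly one
stapler, priced by arm; the real-world possibility of multiple firings is
not emulated, which makes the within-arm stapler cost a point mass (see the
t-test convention below).

**What the generator does not emulate:** time-to-event structure, CRP or
imaging trajectories, correlated resource use within a patient beyond the
leak stratum, multi-firing stapler consumption, readmission clustering.
Passing tests therefore demonstrate the pipeline's correctness and
calibration, not the full covariance structure of real hospital data.

## Propensity matching

Scores are maximum-likelihood logistic regression of arm on covariates
(statsmodels), categoricals expanded to indicators against the largest
category; perfect or quasi-separation raises an explicit error rather than
returning boundary scores. Matching is greedy 1:1 nearest neighbour without
replacement on the logit of the score, treated patients processed in
descending score order with ties broken by patient id — determinism is
preferred over optimal (network-flow) matching, and greedy pairing is not
guaranteed maximum-cardinality. The caliper is 0.2 × SD of the logit scores
by default (the dominant convention when a bare "0.2 caliper" is specified);
absolute-logit and probability-scale calipers are configuration options.
Balance is summarized as standardized mean differences,
(m_t − m_c)/√((s_t² + s_c²)/2), with sample variances.

## Outcome statistics

The 2×2 leak table is tested with the chi-square statistic written out in
closed form: Pearson n(ad−bc)²/(r₁r₂c₁c₂), Yates with |ad−bc| reduced by n/2
(floored at zero). Yates is the default because a continuity-corrected test
on the reference table gives p ≈ 0.0128, matching the scenario's reported
two-decimal p-value; Pearson (p ≈ 0.0073) and Fisher exact are reported for
transparency. The odds ratio is the crude ad/bc with a 95% Wald interval on
the log scale; with any zero cell the Haldane–Anscombe +0.5 correction is
applied (policy-controlled). The scenario's own reported OR (0.510) is not
reproducible from its 2×2 table (crude OR ≈ 0.331) and is presumably
covariate-adjusted; the package reports the crude OR and does not guess.
NNT is ⌈1/(r_c − r_t)⌉, the conservative integer.

## Costing

Costs are exact sums quantity × unit price, kept at full floating precision
internally; rounding to cents is presentation-only, so conservation (overall
total = Σ per-resource totals) holds exactly. Between-arm comparisons are
two-sample Student t tests (Welch optional) computed on pooled z-score
standardized columns; the t statistic is invariant under that affine
transform, which the tests assert by computing both ways. A column constant
within both arms but different between them (the stapler) is a deterministic
price difference: it is reported as t = ±∞, p = 0 with a `degenerate` flag
rather than skipped, so direction and significance remain visible; columns
constant everywhere are skipped with a warning.

## Decision model

Default topology per strategy: chance node on leak → management split
(conservative A∪B vs surgical C) → definitive-stoma terminals; the no-leak
branch also ends in stoma/no-stoma terminals. Terminal payoffs are the
stratum mean cost (means, not medians, matching the ledger's "average cost"
usage) and effectiveness 1 (no definitive stoma) or 0, so rollback yields
exactly the arm mean cost and 1 − stoma proportion — an identity the tests
check against counting oracles. Rollback is exact arithmetic; empty strata
collapse with a logged warning and probability mass goes to the observed
branches. ICER deltas are ECPS − MCS; dominance is classified by the signs
of (ΔE, ΔC), with "dominant" = cheaper and more effective. Trees serialize
losslessly to YAML, and `reference_tree()` builds the scenario tree: leak
terminals carry the €30,649 leak-patient mean, no-leak terminals the
complementary mean that reproduces each arm's overall mean cost.

## Probabilistic sensitivity analysis

Conventions (all config-overridable, since no single standard is mandated):

- probabilities ← Beta(events, non-events); multi-way splits ←
  Dirichlet(counts). Branches with a zero count are *structural* and stay
  fixed: a Beta/Dirichlet with zero concentration is undefined, and
  resampling a branch no patient occupied would invent events;
- terminal mean costs ← gamma by method of moments around the stratum mean
  with SD equal to the **standard error of the mean** (SD/√n): the PSA
  propagates uncertainty in the parameter, not patient-level heterogeneity.
  The patient-level-SD variant is available (`cost_uncertainty="sd"`). The
  within-stratum SD behind the reference tree's standard errors comes from a
  law-of-total-variance decomposition of each arm's marginal cost SD against
  the leak/no-leak mean split, with equal SD assumed in both strata;
- parameters are sampled independently (no correlation information exists in
  the scenario) from one seeded generator in fixed path-sorted order, so
  results are reproducible; point-mass parameters reproduce the
  deterministic rollback exactly (asserted).

Quadrant convention on the cost-effectiveness plane (effectiveness on x,
cost on y): quadrant II (ΔE > 0, ΔC < 0) is the dominant region; boundary
draws are assigned half-open (ΔE ≥ 0 east, ΔC ≥ 0 north) and counted. The
CEAC reports, per willingness-to-pay λ, the fraction of draws with positive
incremental net monetary benefit λ·ΔE − ΔC.

With the reference tree's count-based distributions, the dominant-quadrant
share is about 93–95% per 1000-draw run. This is an information bound, not a
modelling artifact: dominance requires ΔE > 0, and with effectiveness
defined through definitive stomas, P(ΔE > 0) is essentially the posterior
probability that the MCS stoma rate exceeds the ECPS rate given 11 vs 5
events per 165 — about 0.94. The stoma contrast is simply not strong enough
for more, which the scenario's own non-significant stoma p-value reflects;
the cost side is nearly certain (P(ΔC < 0) ≈ 0.99).

## Numerical choices and problem sizes

- Monte Carlo test bounds: exact binomial 99% intervals for event-rate
  recovery; cost-moment recovery is asserted at 5% relative error wherever
  5% is at least ~3.3 Monte Carlo standard errors at the realized stratum
  size, and at a 3.3-SE (99.9%) bound for heavier-tailed components — some
  resources have per-patient CV near 20, for which no desk-scale n can pin
  the mean to 5%.
- Default problem sizes: 395-patient pools for pipeline runs, 2,000 for
  matching diagnostics, 20,000 for recovery checks, 1,000 PSA draws —
  chosen so the full suite exercises every property at meaningful
  resolution while remaining quick on one CPU.
- Ties in matching resolve lexicographically by patient id; gamma draws with
  zero mean or SD degenerate to point masses; seeds are plain integers fed
  to `numpy.random.default_rng`.

## Known limitations

- Single care episode: no Markov extension, discounting, or long-term
  oncological outcomes; indirect and pharmaceutical costs are out of scope.
- The crude OR and the stoma-based effectiveness deliberately do not
  reproduce the scenario's externally reported OR (0.510) and effectiveness
  (98.27/93.69%), whose derivations are not recoverable; both discrepancies
  are surfaced rather than fitted.
- Greedy matching can leave attainable pairs unmatched on adversarial
  inputs; an optimal matcher is a non-goal.
- PSA parameters are independent; correlation between, e.g., leak
  probability and leak cost is not modelled.
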