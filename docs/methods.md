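# Methods

## Detection model

Tumor-informed MRD detection conditions the plasma analysis on the
patient's own tissue variants. For a tracked site the number of
MQ-passing alt reads under the no-tumor null is modeled as
K ~ Binomial(depth, e), where e is the site's background error rate taken
from the evidence file (estimated upstream, e.g. from control plasma — the
pipeline deliberately never estimates e from the sample being tested, which
would be circular). The site p-value is the exact one-sided upper tail
P(K ≥ k); no parametric approximation is used at any depth. A site is
*detected* when both conditions hold:

* p < α (default α = 0.01, per site, no multiple-testing correction — the
  hard read floors below are the stringency mechanism; α is configurable);
* the read-support floor is met: ≥ 2 MQ > 30 alt reads for driver-gene
  sites, ≥ 5 for non-driver sites. Driver status is gene-list membership
  only; the shipped list covers recurrently mutated ESCC drivers and is
  user-overridable.

The floors and the test are combined as a conjunction (support *and*
significance), matching the reading that read support is *required* on top
of a reliable signal. A patient-timepoint is positive iff ≥ 1 tracked site
is detected ("any-site" rule), negative if sites were tracked and none
detected, and not evaluable when the tracked set is empty. Preoperative
"ctDNA-positive" and postoperative "MRD-positive" use the identical rule;
only the timepoint differs. `error_floor` (default 1e-7) bounds e away from
zero so a reported e = 0 cannot produce a degenerate p = 0.

Monotonicity properties hold by construction and are enforced by tests:
detection is non-decreasing in alt reads and non-increasing in background
error.

## Germline / CHIP subtraction

A tissue variant is dropped when the same (chrom, pos, ref, alt) key is
present in the matched leukocyte calls at VAF ≥ 0.02 (CHIP threshold;
matches at VAF ≥ 0.25 are labeled germline). Both classes are excluded
identically — there is no principled reason at MRD depths to track a site
the patient's leukocytes can generate — but the reason codes are logged
separately for auditability. Matching is exact on coordinates (1-based,
VCF convention): tracked sites come from the same pipeline's coordinate
system, so positional fuzzing would only admit artifacts.

## Clinical statistics

All inferential machinery is implemented in this package and cross-checked
in the test suite against independent implementations (scipy, lifelines);
only distribution primitives (binomial/hypergeometric pmf, χ², normal) come
from scipy.

**Fisher's exact test.** Two-sided p by the probability-mass rule: the sum
of central-hypergeometric probabilities of all tables with the observed
margins at most as probable as the observed table (relative tie slack
1e-7). The odds-ratio point estimate is the conditional MLE: the ψ solving
E[a | margins, ψ] = a under Fisher's noncentral hypergeometric
distribution, found by bracketed root search on log ψ (|log ψ| ≤ 60,
solved to machine-level tolerance; the self-consistency E[a|ψ̂] = a is
tested to 1e-6). Boundary tables (a at the support minimum/maximum) return
0 or ∞. Confidence intervals are exact conditional (Cornfield) equal-tail
intervals. Note the estimator is solver-sensitive in sparse tables: for
the table (5, 1, 1, 28) the exact conditional MLE is 88.7506, while a root
search stopped at a typical default tolerance on the reciprocal scale
(as in R's `fisher.test`, tol = ε^0.25) reports 88.91; re-running that
search at tol = 1e-12 recovers 88.7506. This package reports the
tightly-converged value. The cross-product ratio for the same table is
140 — a further reason to prefer the conditional MLE in sparse tables.

**Kaplan–Meier / log-rank.** Standard product-limit estimator; censoring
at a death time is handled after the deaths (censored subjects count in
the risk set at that time). The two-group log-rank statistic uses the
hypergeometric variance with the (N−d)/(N−1) tie correction; the O/E
hazard-ratio summary is reported as a descriptive companion, not a model
estimate.

**Cox proportional hazards.** Breslow partial likelihood maximized by
Newton–Raphson with step halving; convergence at max |score| < 1e-8 (the
documented contract is < 1e-6). The global score test at β = 0 is exposed;
on tie-free two-group data it equals the log-rank χ², which is verified
numerically. Monotone likelihood (separation) — e.g. all events in one
MRD group, entirely plausible at n = 35 — is detected when a coefficient
reaches the internal cap (|β| = 15) with the score still pushing outward;
the affected covariate is reported with HR ∞ (or 0), a likelihood-ratio p,
and a profile-likelihood interval, instead of a spuriously huge finite
Wald HR. Stage is encoded ordinally (I/II/III → 1/2/3); booleans and
positive/negative statuses as 0/1; patients with non-evaluable status are
excluded listwise with a logged count (also from 2×2 tables).

**Wilcoxon rank-sum.** Midranks; U of the first sample. Exact p by full
enumeration of label assignments when n₁ + n₂ ≤ 12 (two-sided as total
probability of |U − μ| at least as extreme); otherwise normal approximation
with tie-corrected variance and 0.5 continuity correction.

## Synthetic cohorts

The generator emulates exactly the structure the caller assumes, so that
every downstream stage can be tested against known truth:

* Each patient carries a panel of somatic sites (default 20; panel sizes
  and plasma depths are not published for the motivating cohort, so these
  are explicit assumptions surfaced in `SimulationConfig`), plus germline
  and CHIP confounder sites present in both tissue and leukocyte VCFs.
* Plasma alt counts are Binomial(depth, e + f/2) for shedders — f is the
  circulating tumor fraction, f/2 the heterozygous-equivalent allele
  fraction — and Binomial(depth, e) otherwise. Depth is Poisson around
  10 000×; e is log-uniform on [1e-6, 1e-4] per site.
* Shedding prevalence defaults: 54.3% preop, 17.1% postop, with postop
  shedders a subset of preop shedders. Tumor fractions are lognormal with
  medians 2% (preop) and 0.1% (postop, MRD-level), σ = 0.8 on the log
  scale — values typical of resectable disease.
* Outcomes follow two channels coupled through true postop shedding: the
  recurrence indicator is Bernoulli with P(rec | shed) = 5/6 and
  P(rec | no shed) = 1/29, while DFS/OS times are exponential with hazard
  multiplied by 4.42 for shedders and administrative censoring at 24
  months (baseline 0.02 events/month). The two channels are deliberately
  separate: the observed conditional recurrence rates and the survival
  hazard ratio are not jointly representable by a single exponential
  proportional-hazards channel, and keeping both lets the 2×2 statistics
  and the Cox/KM recovery each be validated against their own truth.

What the generator does **not** emulate: read-level data (UMIs, duplex
strands, mapping artifacts), site-to-site error correlation, cfDNA
kinetics between more than two timepoints, and panel dropout. Passing
tests therefore demonstrate statistical correctness of the pipeline under
its stated model, not robustness to real-world sequencing artifacts.

## Reference cohort

`esccmrd.fixture.paper_fixture()` reconstructs the 35-patient perioperative
ESCC cohort exactly at the level of published counts: 19 preop-positive
(6 recurrent, 13 not; no recurrence among 16 negatives) and 6
postop-positive (5 recurrent, 1 not; the single postop-negative recurrence
is preop-positive). Site evidence is engineered (depth 10 000, e = 1e-5,
signal sites at 8–32 alt reads, background sites at ≤ 1 stray read) so the
default caller reproduces these statuses exactly; the clinical table
matches the published composition (median age 57, range 43–77, 17 female,
stages 6/19/10, 29 adjuvant-treated). The joint layout across the three
binary labels is not published — only the margins are — so the most
parsimonious layout consistent with all of them is used (postop-positives
⊂ preop-positives) and recorded in the bundle metadata. Ages are
interleaved against patient index so that age is not artificially
collinear with recurrence. Individual survival times are likewise not
published; the fixture's times are synthetic placeholders consistent with
the recurrence labels, which is why no published hazard ratio is asserted
anywhere — Cox and KM are validated by simulation recovery instead.

## Problem sizes and numerical choices

Test-suite simulation scales, chosen to give stable Monte-Carlo margins:
calibration checks use 2000-patient cohorts (3 MC SE tolerances); the
null false-positive check uses 2000 patients × 20 sites against the
union bound 1 − (1 − α)^20; Cox CI coverage uses 200 replicates at
n = 500 against a ≥ 90% criterion for a nominal 95% interval. Exhaustive
agreement checks run the full grid: every 2×2 table with total ≤ 40
against enumeration, every binomial tail with depth ≤ 50 against direct
summation. Determinism is end-to-end: one integer seed drives all
randomness through `numpy.random.default_rng`, output files are written
with fixed float formatting, and two identical runs produce byte-identical
bundles (verified by sha256 in the run manifest).
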