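# esccmrd

Tumor-informed circulating-tumor-DNA (ctDNA) detection of molecular
residual disease (MRD), with the clinical statistics used to evaluate it in
perioperative cohorts. The package is aimed at translational-oncology
analysts working with esophageal squamous cell carcinoma (ESCC) or similar
solid-tumor MRD studies: it takes per-patient tissue and leukocyte variant
calls plus tabulated plasma read evidence, decides who is ctDNA-positive,
and quantifies how that status relates to recurrence and survival.

## The method

**Variant tracking.** Somatic variants called in a patient's tumor tissue
define that patient's plasma search space. Variants also present in matched
leukocyte DNA are removed before tracking — high-VAF matches are germline,
low-VAF matches are clonal hematopoiesis (CHIP) — and the survivors are
annotated as driver / non-driver by membership in a configurable gene list.

**Site-level detection.** At a tracked site with plasma depth *n*,
background error rate *e* and *k* alt-supporting reads with mapping quality
> 30, the null hypothesis "no tumor DNA" gives *K* ~ Binomial(*n*, *e*); the
site p-value is the one-sided upper tail P(*K* ≥ *k*). A site is *detected*
when p < α (default 0.01) **and** a hard read-support floor is met: ≥ 2
MQ-passing alt reads for driver-gene sites, ≥ 5 for non-driver sites.

**Patient-level call.** A patient-timepoint is ctDNA-positive (preop) or
MRD-positive (postop) if at least one tracked site is detected; negative if
none is; not evaluable if no site is tracked.

**Clinical statistics**, implemented from first principles and cross-checked
against scipy and lifelines in the test suite:

* 2×2 diagnostics (sensitivity, specificity, PPV, NPV) of ctDNA status
  against clinical recurrence;
* Fisher's exact test (probability-mass two-sided rule) with the
  conditional-MLE odds ratio — the ψ solving E[a | margins, ψ] = a under the
  noncentral hypergeometric likelihood — and exact conditional CIs. The
  conditional MLE, not the cross-product ratio, is the estimator associated
  with the exact test and behaves sensibly in sparse tables;
* Kaplan–Meier product-limit curves with the two-group log-rank test;
* Cox proportional hazards (Breslow partial likelihood, Newton–Raphson)
  with explicit detection of monotone likelihood (separation), reporting
  profile-likelihood intervals instead of meaningless Wald intervals;
* Wilcoxon rank-sum with midranks, exact enumeration for small samples.

A synthetic-cohort generator produces cohorts with the generative structure
the caller assumes (binomial read counts at *e* + *f*/2 for shedders,
exponential proportional-hazards outcomes), and a packaged deterministic
35-patient reference cohort reconstructs the published perioperative ESCC
study at the level of every printed count.

## Worked example

Run the full pipeline on the packaged reference cohort:

```bash
esccmrd run --fixture --out report/
```

prints

```
preop: positivity 54.3% (19/35)
postop: positivity 17.1% (6/35)
report bundle -> report/
```

and `report/metrics.json` contains (postoperative timepoint):

```json
{
 "fisher_p": 0.00010781438675176819,
 "n_positive": 6,
 "or_cmle": 88.75059854352597,
 "positivity_pct": 17.1,
 "ppv": 0.8333333333333334,
 "sensitivity": 0.8333333333333334,
 "specificity": 0.9655172413793104,
 "table": {"a": 5, "b": 1, "c": 1, "d": 28}
}
```

Reading: 6/35 patients (17.1%) are MRD-positive one month after surgery;
5 of those 6 recur (PPV 83.3%), versus 1 of 29 MRD-negative patients
(specificity 96.6%); the association with recurrence has conditional-MLE
odds ratio 88.75 with exact p ≈ 1.1 × 10⁻⁴. Preoperatively, 19/35 (54.3%)
are ctDNA-positive; all 6 recurrences are in that group (sensitivity 100%,
specificity 55.2%, PPV 31.6%, Fisher p = 0.022). The report directory also
holds per-site detail, Kaplan–Meier curve points, a Cox summary and a
manifest with a sha256 for every output; identical inputs give
hash-identical bundles.

The same stages are available piecewise (`esccmrd simulate | fixture |
track | call | stats`) and as library functions (`esccmrd.site_pvalue`,
`esccmrd.call_cohort`, `esccmrd.fisher_exact`, `esccmrd.cox_ph`, ...).

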