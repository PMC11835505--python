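"""Site-level ctDNA detection against background error, and patient-level MRD calls.

Each tracked site is tested with a one-sided exact binomial test: under the
null (no tumor DNA) the count of MQ-passing alt reads is Binomial(depth, e)
where e is the site's background error rate, so the site p-value is the
upper tail P(X >= alt_mq_pass).  A site is *detected* when it clears both
the significance level and a hard read-support floor — two MQ>30 reads for
driver-gene sites, five for non-driver sites.  A patient-timepoint is
ctDNA-positive (preop) / MRD-positive (postop) if at least one tracked site
is detected, negative if none is, and not evaluable when no site is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

TIMEPOINTS = ("preop", "postop")

#: Columns of the site-evidence table.
EVIDENCE_COLUMNS = [
    "patient_id", "timepoint", "chrom", "pos", "ref", "alt",
    "depth", "alt_mq_pass", "background_error_rate",
]

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class CallerConfig:
    """Detection thresholds.

    mq_min is the mapping-quality cut applied upstream when counting
    ``alt_mq_pass`` (strict inequality, reads with MQ > mq_min).  The
    support floors are the field-standard asymmetric rule: driver sites
    need fewer supporting reads than non-driver sites.  ``alpha`` is the
    per-site significance level, with no multiple-testing correction —
    the support floors are the stringency mechanism.  ``error_floor``
    keeps the null binomial non-degenerate when a site's estimated
    background error is exactly zero.
    """

    mq_min: int = 30
    min_reads_driver: int = 2
    min_reads_nondriver: int = 5
    alpha: float = 0.01
    error_floor: float = 1e-7

    def __post_init__(self) -> None:
        if not self.min_reads_driver <= self.min_reads_nondriver:
            raise ValueError("min_reads_driver must be <= min_reads_nondriver")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 < self.error_floor < 1.0:
            raise ValueError("error_floor must be in (0,1)")


@dataclass(frozen=True)
class SiteEvidence:
    """Plasma read support at one tracked site."""

    patient_id: str
    timepoint: Literal["preop", "postop"]
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_mq_pass: int
    background_error_rate: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.alt_mq_pass <= self.depth:
            raise ValueError(
                f"alt_mq_pass must be in [0, depth], got {self.alt_mq_pass}/{self.depth}"
            )
        if not 0.0 <= self.background_error_rate < 1.0:
            raise ValueError("background_error_rate must be in [0,1)")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.alt_mq_pass / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class SiteCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    timepoint: str
    p_value: float
    passes_support: bool
    detected: bool
    vaf: float


@dataclass(frozen=True)
class PatientCall:
    patient_id: str
    timepoint: str
    status: Literal["positive", "negative", "not_evaluable"]
    n_sites_tracked: int
    n_sites_detected: int
    mean_detected_vaf: float  # NaN when nothing detected
    min_site_p: float  # NaN when nothing tracked


def site_pvalue(evidence: SiteEvidence, cfg: CallerConfig | None = None) -> float:
    """One-sided upper-tail binomial p-value for one site.

    P(X >= alt_mq_pass) with X ~ Binomial(depth, max(error, error_floor));
    returns exactly 1.0 when alt_mq_pass = 0 (the empty tail condition).
    """
    cfg = cfg or CallerConfig()
    return float(
        _site_pvalues(
            np.asarray([evidence.alt_mq_pass]),
            np.asarray([evidence.depth]),
            np.asarray([evidence.background_error_rate]),
            cfg,
        )[0]
    )


def _site_pvalues(
    alt: np.ndarray, depth: np.ndarray, error: np.ndarray, cfg: CallerConfig
) -> np.ndarray:
    if np.any(alt > depth):
        bad = np.flatnonzero(alt > depth)
        raise ValueError(f"alt_mq_pass > depth at rows {bad.tolist()}")
    if np.any(alt < 0) or np.any(depth < 0):
        raise ValueError("negative read counts")
    p_err = np.maximum(np.asarray(error, dtype=float), cfg.error_floor)
    # sf(k-1) = P(X >= k); alt = 0 gives exactly 1.
    pv = stats.binom.sf(alt - 1, depth, p_err)
    return np.where(alt == 0, 1.0, pv)


def test_site(evidence: SiteEvidence, variant, cfg: CallerConfig | None = None) -> SiteCall:
    """Test one site; `variant` is the matching TrackedVariant (driver flag source)."""
    cfg = cfg or CallerConfig()
    if evidence.key != variant.key:
        raise ValueError(
            f"site key mismatch: evidence {evidence.key} vs tracked {variant.key}"
        )
    p = site_pvalue(evidence, cfg)
    floor = cfg.min_reads_driver if variant.is_driver else cfg.min_reads_nondriver
    passes = evidence.alt_mq_pass >= floor
    return SiteCall(
        chrom=evidence.chrom, pos=evidence.pos, ref=evidence.ref, alt=evidence.alt,
        patient_id=evidence.patient_id, timepoint=evidence.timepoint,
        p_value=p, passes_support=passes, detected=passes and p < cfg.alpha,
        vaf=evidence.vaf,
    )


def call_patient(
    site_calls: Iterable[SiteCall],
    patient_id: str | None = None,
    timepoint: str | None = None,
) -> PatientCall:
    """Aggregate site calls into one patient-timepoint MRD status (any-site rule)."""
    calls = list(site_calls)
    if not calls:
        return PatientCall(
            patient_id=patient_id or "", timepoint=timepoint or "",
            status="not_evaluable", n_sites_tracked=0, n_sites_detected=0,
            mean_detected_vaf=float("nan"), min_site_p=float("nan"),
        )
    pids = {c.patient_id for c in calls}
    tps = {c.timepoint for c in calls}
    if len(pids) > 1 or len(tps) > 1:
        raise ValueError(f"mixed patients/timepoints in call_patient: {pids}, {tps}")
    detected = [c for c in calls if c.detected]
    return PatientCall(
        patient_id=calls[0].patient_id, timepoint=calls[0].timepoint,
        status="positive" if detected else "negative",
        n_sites_tracked=len(calls), n_sites_detected=len(detected),
        mean_detected_vaf=(
            float(np.mean([c.vaf for c in detected])) if detected else float("nan")
        ),
        min_site_p=float(min(c.p_value for c in calls)),
    )


def call_cohort(
    evidence: pd.DataFrame,
    tracked: pd.DataFrame,
    cfg: CallerConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Vectorized cohort-level calling.

    Parameters
    ----------
    evidence : table with EVIDENCE_COLUMNS (one row per site per timepoint).
    tracked : tracked-set table (see :mod:`esccmrd.tracking`).

    Returns
    -------
    (calls, site_detail, excluded) : patient-timepoint calls; per-site detail
    with p-values and detected flags; and evidence rows with no matching
    tracked site (reported, never silently dropped).  Patients whose tracked
    set is empty but who appear in the evidence with zero matching rows do
    not occur by construction; a patient with tracked sites and no evidence
    rows at a timepoint is simply absent at that timepoint.
    """
    cfg = cfg or CallerConfig()
    ev = evidence.copy()
    missing = set(EVIDENCE_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")

    key = ["patient_id", *_SITE_KEY]
    merged = ev.merge(
        tracked[[*key, "is_driver"]], on=key, how="left", indicator=True
    )
    excluded = (
        merged.loc[merged["_merge"] == "left_only", EVIDENCE_COLUMNS]
        .reset_index(drop=True)
    )
    detail = merged.loc[merged["_merge"] == "both"].drop(columns="_merge").copy()

    alt = detail["alt_mq_pass"].to_numpy(dtype=np.int64)
    depth = detail["depth"].to_numpy(dtype=np.int64)
    err = detail["background_error_rate"].to_numpy(dtype=float)
    detail["p_value"] = _site_pvalues(alt, depth, err, cfg)
    floor = np.where(
        detail["is_driver"].to_numpy(dtype=bool),
        cfg.min_reads_driver, cfg.min_reads_nondriver,
    )
    detail["passes_support"] = alt >= floor
    detail["detected"] = detail["passes_support"] & (detail["p_value"] < cfg.alpha)
    with np.errstate(invalid="ignore"):
        detail["vaf"] = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)

    rows = []
    for (pid, tp), grp in detail.groupby(["patient_id", "timepoint"], sort=True):
        det = grp.loc[grp["detected"]]
        rows.append(
            {
                "patient_id": pid, "timepoint": tp,
                "status": "positive" if len(det) else "negative",
                "n_sites_tracked": len(grp),
                "n_sites_detected": len(det),
                "mean_detected_vaf": det["vaf"].mean() if len(det) else np.nan,
                "min_site_p": grp["p_value"].min(),
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "status", "n_sites_tracked",
            "n_sites_detected", "mean_detected_vaf", "min_site_p",
        ],
    )
    return calls, detail.reset_index(drop=True), excluded


def read_evidence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence TSV {path} missing columns: {sorted(missing)}")
    return df


def write_evidence_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
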