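"""Synthetic perioperative ctDNA cohorts.

The generator emulates the statistical structure a tumor-informed MRD
analysis assumes: each patient carries a panel of tissue-confirmed somatic
sites; plasma read support at a tracked site arises from sequencing
background error alone (non-shedders) or from background error plus
circulating tumor DNA at heterozygous-equivalent allele fraction f/2
(shedders), with alt counts drawn Binomial(depth, e + shed * f/2).
Clinical outcomes follow two coupled channels keyed on true postoperative
shedding: a recurrence indicator with configured conditional probabilities,
and exponential proportional-hazards event times with a configured hazard
ratio, censored administratively at end of follow-up.

Everything is driven by one integer seed; identical configs and seeds give
byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

CHROMS = [f"chr{i}" for i in range(1, 23)]
_BASES = np.array(list("ACGT"))

DRIVER_GENE_POOL = ["TP53", "NOTCH1", "CCND1", "MYC", "PIK3CA", "NFE2L2", "CDKN2A", "KMT2D"]
NONDRIVER_GENE_POOL = [
    "ZNF750", "AJUBA", "MUC16", "TTN", "SYNE1", "LRP1B", "CSMD3", "DNAH5", "PCLO", "FLG",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generative parameters.

    Shedding prevalences default to the observed perioperative positivity
    of the study population (54.3% before surgery, 17.1% one month after);
    the conditional recurrence probabilities default to the observed 5/6
    and 1/29.  Tumor fractions are lognormal (mu, sigma on the natural-log
    scale): medians of 2% preoperatively and 0.1% postoperatively are
    typical of resectable disease and of MRD-level shedding respectively.
    Panel size and plasma depth are stated assumptions (not reported for
    the study population) and are fully configurable.
    """

    n_patients: int = 35
    n_tracked_sites_per_patient: int = 20
    driver_fraction: float = 0.2
    plasma_depth_mean: float = 10000.0
    background_error_rate_range: tuple[float, float] = (1e-6, 1e-4)
    preop_shedding_prevalence: float = 0.543
    postop_shedding_prevalence: float = 0.171
    tumor_fraction_preop: tuple[float, float] = (math.log(0.02), 0.8)
    tumor_fraction_postop: tuple[float, float] = (math.log(1e-3), 0.8)
    recurrence_prob_given_postop_positive: float = 5 / 6
    recurrence_prob_given_postop_negative: float = 1 / 29
    dfs_hazard_ratio_positive: float = 4.42
    baseline_event_rate: float = 0.02  # events per month in non-shedders
    followup_months: float = 24.0
    n_germline_sites: int = 2
    n_chip_sites: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_tracked_sites_per_patient <= 0:
            raise ValueError("n_tracked_sites_per_patient must be positive")
        if self.plasma_depth_mean <= 0:
            raise ValueError("plasma_depth_mean must be positive")
        for name in (
            "driver_fraction", "preop_shedding_prevalence", "postop_shedding_prevalence",
            "recurrence_prob_given_postop_positive", "recurrence_prob_given_postop_negative",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1], got {v}")
        lo, hi = self.background_error_rate_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("background_error_rate_range must satisfy 0 < lo <= hi < 1")
        if self.dfs_hazard_ratio_positive <= 0:
            raise ValueError("dfs_hazard_ratio_positive must be positive")
        if self.baseline_event_rate < 0 or self.followup_months <= 0:
            raise ValueError("invalid survival parameters")


@dataclass
class CohortBundle:
    """In-memory cohort: variant tables, plasma evidence, clinical outcomes, truth."""

    tissue_variants: pd.DataFrame    # incl. germline/CHIP rows destined for subtraction
    leukocyte_variants: pd.DataFrame
    tracked_truth: pd.DataFrame      # the somatic sites a correct tracker recovers
    evidence: pd.DataFrame           # site evidence, both timepoints
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical["patient_id"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as plain-text files (VCF 4.2, TSV, CSV, JSON)."""
        outdir = Path(outdir)
        (outdir / "vcf").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for pid, grp in self.tissue_variants.groupby("patient_id", sort=True):
            p = outdir / "vcf" / f"{pid}.tissue.vcf"
            write_vcf(p, grp, sample="TISSUE")
            paths[f"tissue_vcf:{pid}"] = p
        for pid, grp in self.leukocyte_variants.groupby("patient_id", sort=True):
            p = outdir / "vcf" / f"{pid}.leukocyte.vcf"
            write_vcf(p, grp, sample="LEUKOCYTE")
            paths[f"leukocyte_vcf:{pid}"] = p
        # patients with no leukocyte variants still need an (empty-body) VCF
        for pid in self.patient_ids:
            p = outdir / "vcf" / f"{pid}.leukocyte.vcf"
            if not p.exists():
                write_vcf(p, self.leukocyte_variants.iloc[0:0], sample="LEUKOCYTE")
                paths[f"leukocyte_vcf:{pid}"] = p

        paths["evidence"] = outdir / "evidence.tsv"
        self.evidence.to_csv(paths["evidence"], sep="\t", index=False)
        paths["clinical"] = outdir / "clinical.csv"
        self.clinical.to_csv(paths["clinical"], index=False)
        paths["tracked_truth"] = outdir / "tracked_truth.tsv"
        self.tracked_truth.to_csv(paths["tracked_truth"], sep="\t", index=False)
        paths["ground_truth"] = outdir / "ground_truth.json"
        gt = {
            "metadata": self.metadata,
            "patients": self.ground_truth.to_dict(orient="records"),
        }
        paths["ground_truth"].write_text(
            json.dumps(gt, indent=1, sort_keys=True, default=float) + "\n"
        )
        return paths


_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _chrom_order(chrom: str) -> int:
    return int(chrom.replace("chr", ""))


def write_vcf(path: str | Path, variants: pd.DataFrame, sample: str) -> None:
    """Emit a minimal deterministic single-sample VCF 4.2.

    Expects columns chrom, pos, ref, alt, gene, vaf, depth.  Records are
    sorted by genomic coordinate; float formatting is fixed so identical
    inputs give byte-identical files.
    """
    contigs = "".join(f"##contig=<ID={c},length=250000000>\n" for c in CHROMS)
    lines = [_VCF_HEADER.format(contigs=contigs, sample=sample)]
    if len(variants):
        vs = variants.sort_values(
            by=["chrom", "pos"],
            key=lambda s: s.map(_chrom_order) if s.name == "chrom" else s,
            kind="stable",
        )
        for row in vs.itertuples(index=False):
            depth = int(row.depth)
            alt_reads = int(round(row.vaf * depth))
            ref_reads = depth - alt_reads
            lines.append(
                f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"GENE={row.gene}\tGT:AD:DP:AF\t"
                f"0/1:{ref_reads},{alt_reads}:{depth}:{row.vaf:.6g}\n"
            )
    Path(path).write_text("".join(lines))


def _site_table(
    rng: np.random.Generator, patient_ids: np.ndarray, n_sites: int,
    first_window: int, is_driver: np.ndarray,
) -> pd.DataFrame:
    """Random site keys: each site index owns a disjoint position window, so
    keys are unique within a patient by construction."""
    n = len(patient_ids)
    total = n * n_sites
    site_idx = np.tile(np.arange(n_sites), n)
    chrom = rng.choice(CHROMS, size=total)
    pos = (
        1_000_000
        + (first_window + site_idx) * 10_000_000
        + rng.integers(0, 9_000_000, size=total)
    )
    ref_i = rng.integers(0, 4, size=total)
    alt_i = (ref_i + rng.integers(1, 4, size=total)) % 4
    gene = np.where(
        is_driver,
        rng.choice(DRIVER_GENE_POOL, size=total),
        rng.choice(NONDRIVER_GENE_POOL, size=total),
    )
    return pd.DataFrame(
        {
            "patient_id": np.repeat(patient_ids, n_sites),
            "chrom": chrom, "pos": pos,
            "ref": _BASES[ref_i], "alt": _BASES[alt_i],
            "gene": gene, "is_driver": is_driver,
        }
    )


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one synthetic cohort. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    m = config.n_tracked_sites_per_patient
    width = max(4, len(str(n)))
    pids = np.array([f"SIM-{i + 1:0{width}d}" for i in range(n)])

    # --- somatic tracked sites -------------------------------------------
    is_driver = rng.random(n * m) < config.driver_fraction
    sites = _site_table(rng, pids, m, first_window=0, is_driver=is_driver)
    sites["tissue_vaf"] = np.round(
        np.clip(rng.beta(2.0, 6.0, size=n * m), 0.02, 0.98), 6
    )
    lo, hi = config.background_error_rate_range
    sites["background_error_rate"] = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n * m)
    )
    sites["depth"] = rng.integers(500, 1200, size=n * m)  # tissue sequencing depth
    sites["vaf"] = sites["tissue_vaf"]

    # --- germline + CHIP contamination (present in both tissue and leukocyte)
    n_conf = config.n_germline_sites + config.n_chip_sites
    conf_driver = np.zeros(n * n_conf, dtype=bool)
    confounders = _site_table(rng, pids, n_conf, first_window=m, is_driver=conf_driver)
    kind = np.tile(
        np.array(
            ["germline"] * config.n_germline_sites + ["chip"] * config.n_chip_sites
        ),
        n,
    )
    leuk_vaf = np.where(
        kind == "germline",
        rng.uniform(0.40, 0.60, size=n * n_conf),
        rng.uniform(0.03, 0.15, size=n * n_conf),
    )
    confounders["vaf"] = np.round(leuk_vaf, 6)
    confounders["depth"] = rng.integers(500, 1200, size=n * n_conf)
    confounders["kind"] = kind

    tissue = pd.concat(
        [
            sites[["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]],
            confounders[["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]],
        ],
        ignore_index=True,
    )
    leukocyte = confounders[
        ["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]
    ].copy()

    # --- shedding status and tumor fractions -----------------------------
    shed_pre = rng.random(n) < config.preop_shedding_prevalence
    if config.preop_shedding_prevalence > 0:
        cond = min(
            1.0, config.postop_shedding_prevalence / config.preop_shedding_prevalence
        )
    else:
        cond = 0.0
    shed_post = shed_pre & (rng.random(n) < cond)
    mu_pre, sd_pre = config.tumor_fraction_preop
    mu_post, sd_post = config.tumor_fraction_postop
    tf_pre = np.where(shed_pre, np.clip(rng.lognormal(mu_pre, sd_pre, n), 0, 0.9), 0.0)
    tf_post = np.where(
        shed_post, np.clip(rng.lognormal(mu_post, sd_post, n), 0, 0.9), 0.0
    )

    # --- plasma evidence: Binomial(depth, e + shed * f/2) ----------------
    err = sites["background_error_rate"].to_numpy()
    frames = []
    for tp, tf in (("preop", tf_pre), ("postop", tf_post)):
        depth = np.maximum(rng.poisson(config.plasma_depth_mean, size=n * m), 1)
        p_alt = np.clip(err + np.repeat(tf, m) / 2.0, 0.0, 1.0)
        alt = rng.binomial(depth, p_alt)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": sites["patient_id"],
                    "timepoint": tp,
                    "chrom": sites["chrom"], "pos": sites["pos"],
                    "ref": sites["ref"], "alt": sites["alt"],
                    "depth": depth, "alt_mq_pass": alt,
                    "background_error_rate": err,
                }
            )
        )
    evidence = pd.concat(frames, ignore_index=True)

    # --- clinical outcomes ------------------------------------------------
    p_rec = np.where(
        shed_post,
        config.recurrence_prob_given_postop_positive,
        config.recurrence_prob_given_postop_negative,
    )
    recurrence = rng.random(n) < p_rec
    rate_dfs = config.baseline_event_rate * np.where(
        shed_post, config.dfs_hazard_ratio_positive, 1.0
    )
    t_dfs = rng.exponential(1.0 / np.maximum(rate_dfs, 1e-12), size=n)
    dfs_event = t_dfs < config.followup_months
    dfs_months = np.minimum(t_dfs, config.followup_months)
    rate_os = 0.5 * rate_dfs
    t_os = rng.exponential(1.0 / np.maximum(rate_os, 1e-12), size=n)
    os_event = t_os < config.followup_months
    os_months = np.minimum(t_os, config.followup_months)

    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "age": rng.integers(43, 78, size=n),
            "sex": rng.choice(["F", "M"], size=n),
            "stage": rng.choice(["I", "II", "III"], size=n, p=[0.171, 0.543, 0.286]),
            "adjuvant": rng.random(n) < 0.829,
            "recurrence": recurrence.astype(int),
            "dfs_months": np.round(dfs_months, 4),
            "dfs_event": dfs_event.astype(int),
            "os_months": np.round(os_months, 4),
            "os_event": os_event.astype(int),
        }
    )
    ground_truth = pd.DataFrame(
        {
            "patient_id": pids,
            "shed_preop": shed_pre.astype(int),
            "shed_postop": shed_post.astype(int),
            "tumor_fraction_preop": tf_pre,
            "tumor_fraction_postop": tf_post,
            "recurrence": recurrence.astype(int),
        }
    )
    tracked_truth = sites[
        ["patient_id", "chrom", "pos", "ref", "alt", "gene", "tissue_vaf", "is_driver"]
    ].copy()

    meta = {"generator": "esccmrd.simulate.generate_cohort", "config": _config_dict(config)}
    return CohortBundle(
        tissue_variants=tissue, leukocyte_variants=leukocyte,
        tracked_truth=tracked_truth, evidence=evidence,
        clinical=clinical, ground_truth=ground_truth, metadata=meta,
    )


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["background_error_rate_range"] = list(d["background_error_rate_range"])
    d["tumor_fraction_preop"] = list(d["tumor_fraction_preop"])
    d["tumor_fraction_postop"] = list(d["tumor_fraction_postop"])
    return d
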