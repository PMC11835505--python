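"""End-to-end orchestration: simulate/fixture -> track -> call -> stats -> report.

A run is driven by one :class:`PipelineConfig` (loadable from YAML with
per-stage sections).  Every stage records its parameters and outputs in a
machine-readable manifest with content hashes; runs are deterministic
given identical inputs and seed, so two runs produce hash-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import caller as _caller
from . import stats as _stats
from . import tracking as _tracking
from .fixture import paper_fixture
from .simulate import CohortBundle, SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """One config object for the whole run.

    Exactly one input source: ``fixture=True``, a ``simulate`` section, or
    explicit ``input_*`` paths (a directory of per-patient VCFs named
    ``{patient}.tissue.vcf`` / ``{patient}.leukocyte.vcf``, a site-evidence
    TSV and a clinical CSV).
    """

    fixture: bool = False
    simulate: SimulationConfig | None = None
    input_vcf_dir: str | None = None
    input_evidence: str | None = None
    input_clinical: str | None = None
    tracking: _tracking.TrackingConfig = field(default_factory=_tracking.TrackingConfig)
    caller: _caller.CallerConfig = field(default_factory=_caller.CallerConfig)
    timepoints: tuple[str, ...] = ("preop", "postop")
    cox_covariates: tuple[str, ...] = ("postop_status", "stage", "adjuvant")
    plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw.pop("simulate"))
            for k in ("background_error_rate_range", "tumor_fraction_preop",
                      "tumor_fraction_postop"):
                if k in sim:
                    sim[k] = tuple(sim[k])
            kwargs["simulate"] = SimulationConfig(**sim)
        if "tracking" in raw and raw["tracking"] is not None:
            tr = dict(raw.pop("tracking"))
            if "driver_genes" in tr:
                tr["driver_genes"] = frozenset(tr["driver_genes"])
            kwargs["tracking"] = _tracking.TrackingConfig(**tr)
        if "caller" in raw and raw["caller"] is not None:
            kwargs["caller"] = _caller.CallerConfig(**raw.pop("caller"))
        for k in ("timepoints", "cox_covariates"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d: dict = {
            "fixture": self.fixture,
            "input_vcf_dir": self.input_vcf_dir,
            "input_evidence": self.input_evidence,
            "input_clinical": self.input_clinical,
            "timepoints": list(self.timepoints),
            "cox_covariates": list(self.cox_covariates),
            "plots": self.plots,
            "log_level": self.log_level,
            "caller": dataclasses.asdict(self.caller),
            "tracking": {
                "germline_vaf_threshold": self.tracking.germline_vaf_threshold,
                "chip_vaf_threshold": self.tracking.chip_vaf_threshold,
                "driver_genes": sorted(self.tracking.driver_genes),
            },
        }
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
            for k in ("background_error_rate_range", "tumor_fraction_preop",
                      "tumor_fraction_postop"):
                d["simulate"][k] = list(d["simulate"][k])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sanitize(obj):
    """Strict-JSON form: non-finite floats become 'inf'/'-inf'/'nan' strings."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not math.isfinite(obj):
        return repr(float(obj))
    return obj


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(_sanitize(obj), indent=1, sort_keys=True, default=_json_default)
        + "\n"
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("acquire")
def _acquire(cfg: PipelineConfig, outdir: Path) -> tuple[Path, Path, Path]:
    """Produce or locate the raw inputs; returns (vcf_dir, evidence, clinical)."""
    if cfg.fixture or cfg.simulate is not None:
        bundle: CohortBundle = (
            paper_fixture() if cfg.fixture else generate_cohort(cfg.simulate)
        )
        data_dir = outdir / "cohort"
        bundle.write(data_dir)
        return data_dir / "vcf", data_dir / "evidence.tsv", data_dir / "clinical.csv"
    for name, val in (
        ("input_vcf_dir", cfg.input_vcf_dir),
        ("input_evidence", cfg.input_evidence),
        ("input_clinical", cfg.input_clinical),
    ):
        if val is None:
            raise PipelineError(f"stage 'acquire' failed: {name} not configured")
        if not Path(val).exists():
            raise PipelineError(f"stage 'acquire' failed: missing file {val}")
    return Path(cfg.input_vcf_dir), Path(cfg.input_evidence), Path(cfg.input_clinical)


@_stage("track")
def _track(cfg: PipelineConfig, vcf_dir: Path, patient_ids: list[str], outdir: Path) -> pd.DataFrame:
    frames = []
    for pid in patient_ids:
        tissue_path = vcf_dir / f"{pid}.tissue.vcf"
        leuk_path = vcf_dir / f"{pid}.leukocyte.vcf"
        if not tissue_path.exists():
            raise FileNotFoundError(f"missing tissue VCF {tissue_path}")
        tissue = _tracking.load_vcf(tissue_path)
        leuk = _tracking.load_vcf(leuk_path) if leuk_path.exists() else []
        tracked = _tracking.build_tracked_set(tissue, leuk, cfg.tracking)
        frames.append(_tracking.tracked_to_frame(pid, tracked))
    df = pd.concat(frames, ignore_index=True)
    _tracking.write_tracked_tsv(df, outdir / "tracked.tsv")
    return df


@_stage("call")
def _call(cfg: PipelineConfig, evidence: pd.DataFrame, tracked: pd.DataFrame, outdir: Path):
    calls, detail, excluded = _caller.call_cohort(evidence, tracked, cfg.caller)
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    detail.to_csv(outdir / "site_detail.tsv", sep="\t", index=False)
    excluded.to_csv(outdir / "excluded_evidence.tsv", sep="\t", index=False)
    if len(excluded):
        logger.warning("%d evidence rows had no matching tracked site", len(excluded))
    return calls


def annotate_statuses(clinical: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Merge patient-timepoint calls onto the clinical table as status columns."""
    out = clinical.copy()
    for tp in _caller.TIMEPOINTS:
        sub = calls[calls["timepoint"] == tp][["patient_id", "status"]]
        col = sub.rename(columns={"status": f"{tp}_status"})
        out = out.merge(col, on="patient_id", how="left")
        out[f"{tp}_status"] = out[f"{tp}_status"].fillna("not_evaluable")
    return out


@_stage("stats")
def _stats_stage(cfg: PipelineConfig, clinical: pd.DataFrame, calls: pd.DataFrame, outdir: Path) -> dict:
    ann = annotate_statuses(clinical, calls)
    ann.to_csv(outdir / "clinical_annotated.csv", index=False)
    report: dict = {"timepoints": {}}
    for tp in cfg.timepoints:
        col = f"{tp}_status"
        n_eval = int(ann[col].isin(["positive", "negative"]).sum())
        n_pos = int((ann[col] == "positive").sum())
        t = _stats.build_contingency(ann, tp)
        metrics = _stats.diagnostic_metrics(t)
        fish = _stats.fisher_exact(t)
        entry = {
            "n_evaluable": n_eval,
            "n_positive": n_pos,
            "positivity_pct": round(100.0 * n_pos / n_eval, 1) if n_eval else None,
            "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv,
            "npv": metrics.npv,
            "fisher_p": fish.p_two_sided,
            "or_cmle": fish.or_cmle,
            "or_ci": list(fish.or_ci) if fish.or_ci else None,
        }
        pd.DataFrame([{"a": t.a, "b": t.b, "c": t.c, "d": t.d}]).to_csv(
            outdir / f"contingency_{tp}.tsv", sep="\t", index=False
        )
        report["timepoints"][tp] = entry

    # survival by postop MRD status (DFS), where both groups exist
    surv = ann[ann["postop_status"].isin(["positive", "negative"])]
    if surv["postop_status"].nunique() == 2 and len(surv):
        km = _stats.km_logrank(
            surv["dfs_months"], surv["dfs_event"].astype(bool), surv["postop_status"]
        )
        report["km_logrank_dfs_by_postop"] = {
            "chi2": km.chi2, "p": km.p_value, "hazard_ratio_oe": km.hazard_ratio_oe,
        }
        frames = []
        for g, curve in km.curves.items():
            frames.append(curve.assign(group=g))
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "km_dfs_by_postop.tsv", sep="\t", index=False
        )
        if cfg.plots:
            _plot_km(km, outdir / "km_dfs_by_postop.svg")

    if cfg.cox_covariates and int(ann["dfs_event"].sum()) > 0:
        cox = _stats.cox_fit(ann, list(cfg.cox_covariates))
        cox.summary().to_csv(outdir / "cox_dfs.tsv", sep="\t", index=False)
        report["cox_dfs"] = {
            "covariates": cox.names,
            "hr": [None if not np.isfinite(h) else float(h) for h in cox.hr],
            "p": [None if not np.isfinite(p) else float(p) for p in cox.p_wald],
            "separated": cox.separated.astype(bool).tolist(),
        }
    _write_json(report, outdir / "metrics.json")
    return report


def _plot_km(km: _stats.KMLogRankResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "esccmrd"
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in km.curves.items():
        ax.step(
            [0.0, *curve["time"]], [1.0, *curve["survival"]],
            where="post", label=str(g),
        )
    ax.set_xlabel("months")
    ax.set_ylabel("disease-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in order; returns the report dict.

    Writes the full report bundle plus ``manifest.json`` (stage parameters
    and a sha256 for every output file) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))

    vcf_dir, evidence_path, clinical_path = _acquire(cfg, outdir)
    evidence = _caller.read_evidence_tsv(evidence_path)
    clinical = pd.read_csv(clinical_path, dtype={"patient_id": str})
    patient_ids = sorted(clinical["patient_id"].unique())

    tracked = _track(cfg, vcf_dir, patient_ids, outdir)
    calls = _call(cfg, evidence, tracked, outdir)
    report = _stats_stage(cfg, clinical, calls, outdir)

    manifest = {
        "config": cfg.to_dict(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return report
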