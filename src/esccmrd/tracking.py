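"""Patient-specific tracked-variant sets from tissue and leukocyte VCFs.

Tumor-informed MRD restricts the plasma search space to somatic variants
first identified in the patient's tumor tissue.  Variants also present in
matched leukocyte DNA are removed before tracking: high-VAF matches are
germline, low-but-real leukocyte support indicates clonal hematopoiesis
(CHIP), and both would confound plasma calls.  Surviving sites are
annotated as driver / non-driver by membership in a configurable gene
list; driver sites are granted a relaxed read-support floor downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Columns of the tracked-set table, in output order.
TRACKED_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "tissue_vaf", "is_driver",
]


@dataclass(frozen=True)
class Variant:
    """One ALT allele at one locus (VCF convention, 1-based positions)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    vaf: float | None = None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class TrackedVariant(Variant):
    """A tissue variant that survived leukocyte subtraction."""

    is_driver: bool = False


def default_driver_genes() -> frozenset[str]:
    """Driver gene list shipped with the package (one symbol per line, '#' comments)."""
    text = resources.files("esccmrd").joinpath("data/driver_genes.txt").read_text()
    genes = {
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(genes)


def load_driver_genes(path: str | Path) -> frozenset[str]:
    """Read a driver-gene list file (one symbol per line, '#' comments)."""
    lines = Path(path).read_text().splitlines()
    return frozenset(
        ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
    )


@dataclass(frozen=True)
class TrackingConfig:
    """Subtraction thresholds and the driver-gene list.

    A leukocyte match at VAF >= ``germline_vaf_threshold`` is germline; a
    match at VAF >= ``chip_vaf_threshold`` (but below germline) is CHIP.
    Both are excluded from tracking — one rule, distinct reason codes.
    """

    germline_vaf_threshold: float = 0.25
    chip_vaf_threshold: float = 0.02
    driver_genes: frozenset[str] = field(default_factory=default_driver_genes)

    def __post_init__(self) -> None:
        if not 0.0 <= self.chip_vaf_threshold <= 1.0:
            raise ValueError("chip_vaf_threshold must be in [0,1]")
        if not self.chip_vaf_threshold < self.germline_vaf_threshold <= 1.0:
            raise ValueError("chip threshold must be < germline threshold <= 1")


class VCFParseError(ValueError):
    """Malformed VCF input."""


def _get_field(mapping, key):
    """Field lookup tolerant of keys absent from the VCF header."""
    try:
        return mapping.get(key)
    except (KeyError, ValueError):
        return None


def _variant_from_record(rec, alt: str, alt_index: int) -> Variant:
    """Build one Variant for one ALT allele of a pysam record."""
    gene = ""
    info_gene = _get_field(rec.info, "GENE")
    if info_gene is not None:
        gene = info_gene[0] if isinstance(info_gene, tuple) else str(info_gene)

    vaf: float | None = None
    depth: int | None = None
    # Prefer per-sample AF/AD from the first sample; fall back to INFO AF.
    if rec.samples:
        sample = rec.samples[0]
        ad = _get_field(sample, "AD")
        dp = _get_field(sample, "DP")
        if dp is not None:
            depth = int(dp)
        elif ad is not None and all(x is not None for x in ad):
            depth = int(sum(ad))
        af = _get_field(sample, "AF")
        if af is not None:
            af_t = af if isinstance(af, tuple) else (af,)
            if alt_index < len(af_t) and af_t[alt_index] is not None:
                vaf = float(af_t[alt_index])
        if vaf is None and ad is not None and len(ad) > alt_index + 1:
            ref_n = ad[0]
            alt_n = ad[alt_index + 1]
            if ref_n is not None and alt_n is not None and sum(
                x for x in ad if x is not None
            ) > 0:
                vaf = alt_n / sum(x for x in ad if x is not None)
    if vaf is None:
        info_af = _get_field(rec.info, "AF")
        if info_af is not None:
            af_t = info_af if isinstance(info_af, tuple) else (info_af,)
            if alt_index < len(af_t) and af_t[alt_index] is not None:
                vaf = float(af_t[alt_index])
    if vaf is None:
        logger.warning(
            "no AF or AD at %s:%d %s>%s — vaf left unset", rec.chrom, rec.pos, rec.ref, alt
        )
    return Variant(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt, gene=gene,
        vaf=vaf, depth=depth,
    )


def load_vcf(path: str | Path) -> list[Variant]:
    """Parse a VCF 4.x file into a flat list of per-ALT-allele variants.

    Multi-allelic records are split into one :class:`Variant` per ALT.
    VAF comes from per-sample AF when present, else is computed from AD,
    else from INFO/AF; a variant with none of these is emitted with
    ``vaf=None`` and a logged warning.
    """
    path = Path(path)
    variants: list[Variant] = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.alts is None:
                    continue
                for i, alt in enumerate(rec.alts):
                    variants.append(_variant_from_record(rec, alt, i))
    except (ValueError, OSError) as exc:
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc
    return variants


def build_tracked_set(
    tissue: list[Variant],
    leukocyte: list[Variant],
    cfg: TrackingConfig | None = None,
) -> list[TrackedVariant]:
    """Subtract leukocyte-supported variants from the tissue set and annotate drivers.

    A tissue variant is excluded when the same (chrom, pos, ref, alt) key
    appears in the leukocyte set with VAF >= ``chip_vaf_threshold`` (or with
    unknown VAF, treated conservatively as leukocyte-supported).  Output is
    sorted by (chrom, pos, ref, alt) regardless of input order.  An empty
    tissue list yields an empty tracked set — the patient is downstream
    "not evaluable", not an error.
    """
    cfg = cfg or TrackingConfig()
    exclude: set[tuple[str, int, str, str]] = set()
    for lv in leukocyte:
        if lv.vaf is None or lv.vaf >= cfg.chip_vaf_threshold:
            reason = (
                "germline"
                if lv.vaf is not None and lv.vaf >= cfg.germline_vaf_threshold
                else "chip_or_unknown"
            )
            exclude.add(lv.key)
            logger.debug("excluding %s:%d %s>%s (%s)", *lv.key, reason)

    tracked = [
        TrackedVariant(
            chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
            vaf=v.vaf, depth=v.depth, is_driver=v.gene in cfg.driver_genes,
        )
        for v in tissue
        if v.key not in exclude
    ]
    tracked.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return tracked


def tracked_to_frame(patient_id: str, tracked: list[TrackedVariant]) -> pd.DataFrame:
    """Tracked set as a table with TRACKED_COLUMNS."""
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id, "chrom": v.chrom, "pos": v.pos,
                "ref": v.ref, "alt": v.alt, "gene": v.gene,
                "tissue_vaf": v.vaf, "is_driver": v.is_driver,
            }
            for v in tracked
        ],
        columns=TRACKED_COLUMNS,
    )


def read_tracked_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    missing = set(TRACKED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tracked-set TSV {path} missing columns: {sorted(missing)}")
    df["is_driver"] = df["is_driver"].astype(bool)
    return df


def write_tracked_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
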