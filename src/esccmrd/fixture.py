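"""Deterministic 35-patient reference cohort.

Reconstructs the perioperative study population at the level of every
published count: 19/35 preoperative ctDNA-positive patients (6 of whom
recur, none of the 16 negatives recur) and 6/35 postoperative MRD-positive
patients (5 recurrent, 1 not; the single postop-negative recurrence is
preop-positive).  Site evidence is engineered so the MRD caller under its
default configuration reproduces exactly these statuses; the clinical
table matches the published cohort composition (median age 57, 17 female,
stages 6/19/10, 29 adjuvant-treated).

The joint preop-by-postop-by-recurrence layout is not published — only its
margins are.  The layout used here is the most parsimonious one consistent
with all printed marginals (postop-positive patients are a subset of
preop-positive patients); it is recorded in the bundle metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CHROMS, CohortBundle

_FIXTURE_RNG_SEED = 20230207  # cosmetic randomness only (site coordinates)

N_PATIENTS = 35
RECURRENT = set(range(1, 7))            # patients 1..6
PREOP_POSITIVE = set(range(1, 20))      # patients 1..19
POSTOP_POSITIVE = {1, 2, 3, 4, 5, 7}    # subset of preop-positive

_DRIVER_GENES = ["TP53", "NOTCH1", "PIK3CA", "CCND1"]
_NONDRIVER_GENES = [
    "ZNF750", "AJUBA", "MUC16", "TTN", "SYNE1", "LRP1B", "CSMD3", "DNAH5",
    "PCLO", "FLG", "DNAH9", "RYR2", "XIRP2", "SPTA1", "USH2A", "PKHD1L1",
]

_DEPTH = 10000
_ERROR = 1e-5

# alt-read counts at the engineered signal sites (site index -> reads)
_PREOP_SIGNAL_RECURRENT = {0: 32, 1: 28, 4: 24, 5: 21}
_PREOP_SIGNAL_NONRECURRENT = {0: 26, 4: 18}
_POSTOP_SIGNAL = {0: 12, 5: 8}

# 35 ages, range 43-77, median = 57; deliberately interleaved so age is not
# collinear with patient index (and hence not with recurrence status)
_AGES = [
    58, 43, 63, 55, 70, 49, 57, 66, 46, 61, 53, 75, 50, 57, 68, 45, 59, 56,
    73, 48, 64, 55, 77, 51, 60, 56, 71, 52, 62, 54, 67, 56, 65, 58, 57,
]

_DFS_RECURRENT = [4.1, 5.8, 7.3, 9.6, 11.2, 14.5]
_OS_DEATHS = {1: 9.8, 2: 13.4, 3: 17.9}
_FOLLOWUP = 24.0


def _pid(i: int) -> str:
    return f"ESCC-{i:02d}"


def _background_alt(site_idx: int) -> int:
    """Sub-threshold background noise: a single stray read at every third site."""
    return 1 if site_idx % 3 == 0 else 0


def paper_fixture() -> CohortBundle:
    """Build the reference cohort. Fully deterministic; no inputs."""
    rng = np.random.default_rng(_FIXTURE_RNG_SEED)

    site_rows, conf_rows, ev_rows = [], [], []
    for i in range(1, N_PATIENTS + 1):
        pid = _pid(i)
        preop_pos = i in PREOP_POSITIVE
        postop_pos = i in POSTOP_POSITIVE
        recurrent = i in RECURRENT
        if preop_pos:
            preop_signal = (
                _PREOP_SIGNAL_RECURRENT if recurrent else _PREOP_SIGNAL_NONRECURRENT
            )
        else:
            preop_signal = {}
        postop_signal = _POSTOP_SIGNAL if postop_pos else {}

        # 20 somatic tracked sites: 4 driver-gene, 16 non-driver
        for s in range(20):
            driver = s < 4
            gene = _DRIVER_GENES[s] if driver else _NONDRIVER_GENES[s - 4]
            chrom = CHROMS[int(rng.integers(0, 22))]
            pos = int(1_000_000 + s * 10_000_000 + rng.integers(0, 9_000_000))
            ref, alt = [("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")][s % 4]
            vaf = round(0.08 + 0.02 * (s % 12), 6)
            site_rows.append(
                {
                    "patient_id": pid, "chrom": chrom, "pos": pos, "ref": ref,
                    "alt": alt, "gene": gene, "tissue_vaf": vaf,
                    "is_driver": driver, "vaf": vaf, "depth": 900,
                }
            )
            for tp, signal in (("preop", preop_signal), ("postop", postop_signal)):
                ev_rows.append(
                    {
                        "patient_id": pid, "timepoint": tp, "chrom": chrom,
                        "pos": pos, "ref": ref, "alt": alt, "depth": _DEPTH,
                        "alt_mq_pass": signal.get(s, _background_alt(s)),
                        "background_error_rate": _ERROR,
                    }
                )

        # germline + CHIP confounders, present in tissue and leukocyte VCFs
        for c, (kind, t_vaf, l_vaf, gene) in enumerate(
            [
                ("germline", 0.49, 0.48, "TTN"),
                ("germline", 0.51, 0.52, "MUC16"),
                ("chip", 0.08, 0.06, "SYNE1"),
            ]
        ):
            chrom = CHROMS[int(rng.integers(0, 22))]
            pos = int(1_000_000 + (20 + c) * 10_000_000 + rng.integers(0, 9_000_000))
            conf_rows.append(
                {
                    "patient_id": pid, "chrom": chrom, "pos": pos, "ref": "G",
                    "alt": "T", "gene": gene, "tissue_vaf": t_vaf,
                    "leukocyte_vaf": l_vaf, "kind": kind,
                }
            )

    sites = pd.DataFrame(site_rows)
    confounders = pd.DataFrame(conf_rows)

    tissue = pd.concat(
        [
            sites[["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]],
            confounders.assign(vaf=confounders["tissue_vaf"], depth=900)[
                ["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]
            ],
        ],
        ignore_index=True,
    )
    leukocyte = confounders.assign(vaf=confounders["leukocyte_vaf"], depth=700)[
        ["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth"]
    ]
    evidence = pd.DataFrame(ev_rows)
    tracked_truth = sites[
        ["patient_id", "chrom", "pos", "ref", "alt", "gene", "tissue_vaf", "is_driver"]
    ].copy()

    clinical, ground_truth = _clinical_tables()
    meta = {
        "generator": "esccmrd.fixture.paper_fixture",
        "layout_note": (
            "Joint preop x postop x recurrence layout is not published; "
            "chosen as the most parsimonious arrangement consistent with all "
            "printed marginals: recurrent = patients 1-6; preop-positive = "
            "1-19; postop-positive = {1-5, 7} (subset of preop-positive); the "
            "single postop-negative recurrence (patient 6) is preop-positive."
        ),
    }
    return CohortBundle(
        tissue_variants=tissue, leukocyte_variants=leukocyte,
        tracked_truth=tracked_truth, evidence=evidence,
        clinical=clinical, ground_truth=ground_truth, metadata=meta,
    )


def _clinical_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, truth = [], []
    for i in range(1, N_PATIENTS + 1):
        recurrent = i in RECURRENT
        # stage margins: III for 1-10 (recurrences skew advanced), I for 11-16, II for 17-35
        stage = "III" if i <= 10 else ("I" if i <= 16 else "II")
        dfs = _DFS_RECURRENT[i - 1] if recurrent else _FOLLOWUP
        osm = _OS_DEATHS.get(i, _FOLLOWUP)
        rows.append(
            {
                "patient_id": _pid(i),
                "age": _AGES[i - 1],
                "sex": "F" if i % 2 == 0 else "M",  # 17 F, 18 M
                "stage": stage,
                "adjuvant": int(i <= 29),  # 29 treated, 6 not
                "recurrence": int(recurrent),
                "dfs_months": dfs,
                "dfs_event": int(recurrent),
                "os_months": osm,
                "os_event": int(i in _OS_DEATHS),
            }
        )
        pre = i in PREOP_POSITIVE
        post = i in POSTOP_POSITIVE
        truth.append(
            {
                "patient_id": _pid(i),
                "shed_preop": int(pre),
                "shed_postop": int(post),
                "tumor_fraction_preop": round(2 * (0.0026 - _ERROR), 6) if pre else 0.0,
                "tumor_fraction_postop": round(2 * (0.0010 - _ERROR), 6) if post else 0.0,
                "recurrence": int(recurrent),
                "expected_preop_status": "positive" if pre else "negative",
                "expected_postop_status": "positive" if post else "negative",
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)
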