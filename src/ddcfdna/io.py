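"""Readers and writers for the plain-text interchange formats.

Panel CSV: locus_id, chrom, ref, alt, alt_freq
Pileup TSV: locus_id, count_A, count_C, count_G, count_T
Typings CSV: patient_id, role (donor|recipient), locus, allele1, allele2
Eplet table CSV: allele, eplet, class
Tacrolimus series CSV: patient_id, day, level_ng_ml, dose_mg
Outcomes CSV: patient_id + binary labels + covariates

All writers emit a header line; all readers validate column names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eplets import EpletTable, HlaTyping
from .exposure import TacrolimusSeries
from .panel import BASES, SNPPanel
from .quant import CfDNASample
from .simulate import CohortDataset

PILEUP_COLUMNS = ["locus_id", "count_A", "count_C", "count_G", "count_T"]
SERIES_COLUMNS = ["patient_id", "day", "level_ng_ml", "dose_mg"]
TYPING_COLUMNS = ["patient_id", "role", "locus", "allele1", "allele2"]
OUTCOME_COLUMNS = [
    "patient_id", "abmr", "acute_rejection", "troubled_graft",
    "first_year_rejection", "egfr", "albuminuria", "mpa_trough",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} {path}: missing columns {missing}")


# -- panel ------------------------------------------------------------------

def write_panel_csv(panel: SNPPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> SNPPanel:
    df = pd.read_csv(path)
    _require_columns(df, ["locus_id", "chrom", "ref", "alt", "alt_freq"], "panel CSV", path)
    return SNPPanel.from_frame(df)


# -- pileups ----------------------------------------------------------------

def write_pileup_tsv(sample: CfDNASample, path: str | Path) -> None:
    df = pd.DataFrame(sample.counts, columns=[f"count_{b}" for b in BASES])
    df.insert(0, "locus_id", sample.locus_ids)
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(
    path: str | Path,
    sample_id: str | None = None,
    patient_id: str = "unknown",
    collection_day: float = 30.0,
) -> CfDNASample:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PILEUP_COLUMNS, "pileup TSV", path)
    counts = df[[f"count_{b}" for b in BASES]].to_numpy(dtype=np.int64)
    return CfDNASample(
        sample_id=sample_id or Path(path).stem,
        patient_id=patient_id,
        collection_day=collection_day,
        locus_ids=[str(x) for x in df["locus_id"]],
        counts=counts,
    )


# -- HLA typings and eplet tables ------------------------------------------

def write_typings_csv(cohort: CohortDataset, path: str | Path) -> None:
    rows = []
    for p in cohort.patients:
        for role, typing in (("donor", p.donor_typing), ("recipient", p.recipient_typing)):
            if typing is None:
                continue
            for locus, (a1, a2) in typing.alleles.items():
                rows.append((p.patient_id, role, locus, a1, a2))
    pd.DataFrame(rows, columns=TYPING_COLUMNS).to_csv(path, index=False)


def read_typings_csv(path: str | Path) -> dict[str, dict[str, HlaTyping]]:
    """patient_id → {"donor": HlaTyping, "recipient": HlaTyping}."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TYPING_COLUMNS, "typings CSV", path)
    out: dict[str, dict[str, HlaTyping]] = {}
    for (pid, role), grp in df.groupby(["patient_id", "role"], sort=False):
        if role not in ("donor", "recipient"):
            raise ValueError(f"typings CSV {path}: unknown role {role!r}")
        alleles = {r.locus: (r.allele1, r.allele2) for r in grp.itertuples()}
        out.setdefault(pid, {})[role] = HlaTyping(alleles)
    return out


def write_eplet_table_csv(table: EpletTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


# -- tacrolimus series ------------------------------------------------------

def write_series_csv(cohort: CohortDataset, path: str | Path) -> None:
    rows = []
    for p in cohort.patients:
        s = p.tacrolimus
        for d, l, dose in zip(s.days, s.levels, s.doses):
            rows.append((p.patient_id, d, l, dose))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series_csv(path: str | Path) -> dict[str, TacrolimusSeries]:
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, "series CSV", path)
    out = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        out[str(pid)] = TacrolimusSeries(
            days=grp["day"].to_numpy(dtype=float),
            levels=grp["level_ng_ml"].to_numpy(dtype=float),
            doses=grp["dose_mg"].to_numpy(dtype=float),
        )
    return out


# -- outcomes / truth -------------------------------------------------------

def write_outcomes_csv(cohort: CohortDataset, path: str | Path) -> None:
    df = cohort.truth_frame()
    df.to_csv(path, index=False)


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, OUTCOME_COLUMNS, "outcomes CSV", path)
    return df
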