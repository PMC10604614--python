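"""HLA antigen mismatches and eplet mismatch loads.

An eplet is a small patch of polymorphic amino-acid residues on an HLA
molecule that antibodies can recognise. The mismatch load of a transplant
pair is the number of eplets carried by the donor's HLA alleles that are
absent from the recipient's repertoire — computed per locus, per class, or
pooled, from an allele→eplet table (HLAMatchmaker-style).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: loci entering the antigen-level mismatch count (classic 6-locus set)
DEFAULT_ANTIGEN_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1")

CLASS_I_LOCI = ("A", "B", "C")
CLASS_II_LOCI = ("DRB1", "DRB345", "DQA1", "DQB1", "DPA1", "DPB1")


def locus_of(allele: str) -> str:
    """Locus name of an HLA allele string, e.g. ``DQB1*03:01`` → ``DQB1``."""
    return allele.split("*", 1)[0]


def antigen_of(allele: str) -> str:
    """Antigen-level (first-field) name, e.g. ``A*02:01`` → ``A*02``."""
    return allele.split(":", 1)[0]


@dataclass(frozen=True)
class HlaTyping:
    """Unordered allele pairs per HLA locus (homozygous = repeated name)."""

    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for locus, pair in self.alleles.items():
            if len(pair) != 2:
                raise ValueError(f"locus {locus}: exactly 2 alleles required")
            for a in pair:
                if locus_of(a) != locus:
                    raise ValueError(f"allele {a} does not belong to locus {locus}")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(self.alleles)

    def alleles_at(self, loci: Iterable[str]) -> list[str]:
        out: list[str] = []
        for locus in loci:
            if locus not in self.alleles:
                raise KeyError(f"locus {locus} absent from typing")
            out.extend(self.alleles[locus])
        return out

    def antigens_at(self, locus: str) -> set[str]:
        if locus not in self.alleles:
            raise KeyError(f"locus {locus} absent from typing")
        return {antigen_of(a) for a in self.alleles[locus]}


@dataclass
class EpletTable:
    """Allele → eplet-repertoire mapping with per-eplet class annotation."""

    repertoires: dict[str, frozenset[str]]
    eplet_class: dict[str, str]  # eplet id → "I" | "II"

    def __post_init__(self) -> None:
        bad = set(self.eplet_class.values()) - {"I", "II"}
        if bad:
            raise ValueError(f"unknown eplet class labels: {sorted(bad)}")

    def eplets_of(self, allele: str) -> frozenset[str]:
        try:
            return self.repertoires[allele]
        except KeyError:
            raise KeyError(f"allele {allele!r} missing from eplet table") from None

    def union_over(self, alleles: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for a in alleles:
            out |= self.eplets_of(a)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (allele, eplet, self.eplet_class.get(eplet, ""))
            for allele, eps in sorted(self.repertoires.items())
            for eplet in sorted(eps)
        ]
        return pd.DataFrame(rows, columns=["allele", "eplet", "class"])


def load_eplet_table(path: str | Path) -> EpletTable:
    """Read an allele→eplet CSV with columns ``allele,eplet,class``.

    Duplicate (allele, eplet) rows collapse to set semantics.
    """
    df = pd.read_csv(path, dtype=str)
    return eplet_table_from_frame(df)


def eplet_table_from_frame(df: pd.DataFrame) -> EpletTable:
    missing = {"allele", "eplet", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"eplet table missing columns: {sorted(missing)}")
    if df[["allele", "eplet", "class"]].isna().any().any():
        raise ValueError("eplet table contains malformed (empty) fields")
    repertoires: dict[str, set[str]] = {}
    eplet_class: dict[str, str] = {}
    for allele, eplet, cls in df[["allele", "eplet", "class"]].itertuples(index=False):
        if cls not in ("I", "II"):
            raise ValueError(f"unknown class label {cls!r} for eplet {eplet!r}")
        prev = eplet_class.setdefault(eplet, cls)
        if prev != cls:
            raise ValueError(f"eplet {eplet!r} labelled with conflicting classes")
        repertoires.setdefault(allele, set()).add(eplet)
    return EpletTable(
        repertoires={a: frozenset(e) for a, e in repertoires.items()},
        eplet_class=eplet_class,
    )


def _resolve_scope(scope: str | Iterable[str], typing: HlaTyping) -> list[str]:
    if isinstance(scope, str):
        key = scope.lower().replace("class", "").replace("_", "").strip()
        if key == "i":
            loci = [l for l in CLASS_I_LOCI if l in typing.alleles]
        elif key == "ii":
            loci = [l for l in CLASS_II_LOCI if l in typing.alleles]
        else:
            loci = [scope]
        return loci
    return list(scope)


def eplet_mismatch_load(
    donor: HlaTyping,
    recipient: HlaTyping,
    table: EpletTable,
    scope: str | Iterable[str],
) -> int:
    """Count donor eplets absent from the recipient within ``scope``.

    ``scope`` is a locus name, an iterable of loci, or ``"classI"`` /
    ``"classII"``. The load is |E_donor \\ E_recipient| over the selected
    loci's allele repertoires; it is asymmetric in donor/recipient.
    """
    donor_loci = [l for l in _resolve_scope(scope, donor) if l in donor.alleles]
    recip_loci = [l for l in _resolve_scope(scope, recipient) if l in recipient.alleles]
    e_donor = table.union_over(donor.alleles_at(donor_loci))
    e_recip = table.union_over(recipient.alleles_at(recip_loci))
    return len(e_donor - e_recip)


def antigen_mismatch_count(
    donor: HlaTyping,
    recipient: HlaTyping,
    loci: Iterable[str] = DEFAULT_ANTIGEN_LOCI,
) -> int:
    """Antigen-level (first-field) mismatches: donor antigens absent from
    the recipient, 0-2 per locus, summed over ``loci``."""
    total = 0
    for locus in loci:
        total += len(donor.antigens_at(locus) - recipient.antigens_at(locus))
    return total


@dataclass(frozen=True)
class MismatchLoads:
    """Per-pair antigen and eplet mismatch summary."""

    antigen_mm_total: int
    classI_eplet_load: int
    classII_eplet_load: int
    drb1_eplet_load: int
    dqb1_eplet_load: int
    dqa1_eplet_load: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def compute_loads(
    donor: HlaTyping,
    recipient: HlaTyping,
    table: EpletTable,
    antigen_loci: Iterable[str] = DEFAULT_ANTIGEN_LOCI,
) -> MismatchLoads:
    """All mismatch loads for one donor/recipient pair.

    Per-locus class II loads use locus-restricted eplet sets; the class II
    total pools all class II loci and may be sub-additive when loci share
    eplets.
    """
    return MismatchLoads(
        antigen_mm_total=antigen_mismatch_count(donor, recipient, antigen_loci),
        classI_eplet_load=eplet_mismatch_load(donor, recipient, table, "classI"),
        classII_eplet_load=eplet_mismatch_load(donor, recipient, table, "classII"),
        drb1_eplet_load=eplet_mismatch_load(donor, recipient, table, "DRB1"),
        dqb1_eplet_load=eplet_mismatch_load(donor, recipient, table, "DQB1"),
        dqa1_eplet_load=eplet_mismatch_load(donor, recipient, table, "DQA1"),
    )


def cohort_loads(cohort, table: EpletTable | None = None) -> dict[str, MismatchLoads]:
    """Recompute mismatch loads for every patient of a cohort.

    ``table`` defaults to the cohort's own eplet table. Errors from a
    missing allele propagate with the allele named.
    """
    if table is None:
        table = cohort.eplet_table
    if table is None:
        raise ValueError("cohort carries no eplet table and none was given")
    out: dict[str, MismatchLoads] = {}
    for p in cohort.patients:
        if p.donor_typing is None or p.recipient_typing is None:
            raise ValueError(f"patient {p.patient_id} has no HLA typings attached")
        out[p.patient_id] = compute_loads(p.donor_typing, p.recipient_typing, table)
    return out
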