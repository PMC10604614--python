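"""SNP panel definitions for chimerism-style cfDNA assays.

A panel is an ordered set of autosomal biallelic SNPs chosen near 50%
population frequency so that a large share of donor/recipient pairs are
informative (recipient homozygous, donor carrying the other allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default panel size: one multiplexed amplicon per SNP across the 22 autosomes
DEFAULT_N_LOCI = 202


@dataclass(frozen=True)
class SNPLocus:
    """One autosomal biallelic SNP."""

    locus_id: str
    chromosome: int
    allele_ref: str
    allele_alt: str
    alt_freq: float

    def __post_init__(self) -> None:
        if self.allele_ref not in BASES or self.allele_alt not in BASES:
            raise ValueError(f"alleles must be in {BASES}")
        if self.allele_ref == self.allele_alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 < self.alt_freq < 1.0:
            raise ValueError("alt_freq must be strictly inside (0, 1)")
        if not 1 <= int(self.chromosome) <= 22:
            raise ValueError("chromosome must be an autosome (1-22)")


@dataclass
class SNPPanel:
    """Ordered collection of :class:`SNPLocus` with unique ids."""

    loci: list[SNPLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("panel must contain at least one locus")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus_ids must be unique within a panel")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def alt_freqs(self) -> np.ndarray:
        return np.array([l.alt_freq for l in self.loci])

    @property
    def ref_idx(self) -> np.ndarray:
        """Index of the reference base in A<C<G<T order, per locus."""
        return np.array([BASE_INDEX[l.allele_ref] for l in self.loci])

    @property
    def alt_idx(self) -> np.ndarray:
        return np.array([BASE_INDEX[l.allele_alt] for l in self.loci])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "chrom": [l.chromosome for l in self.loci],
                "ref": [l.allele_ref for l in self.loci],
                "alt": [l.allele_alt for l in self.loci],
                "alt_freq": self.alt_freqs,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SNPPanel":
        required = {"locus_id", "chrom", "ref", "alt", "alt_freq"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        loci = [
            SNPLocus(str(r.locus_id), int(r.chrom), str(r.ref), str(r.alt), float(r.alt_freq))
            for r in df.itertuples()
        ]
        return cls(loci)


def make_default_panel(
    n_loci: int = DEFAULT_N_LOCI,
    freq_low: float = 0.3,
    freq_high: float = 0.7,
    seed: int = 0,
) -> SNPPanel:
    """Build a synthetic autosomal SNP panel.

    Alternate-allele frequencies are drawn Uniform(freq_low, freq_high):
    chimerism panels are picked near 0.5 to maximise the informative-locus
    yield. Loci are spread round-robin over chromosomes 1-22 and ref/alt
    bases are drawn uniformly among distinct nucleotide pairs.

    Deterministic given ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0.0 < freq_low < freq_high < 1.0):
        raise ValueError("need 0 < freq_low < freq_high < 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_low, freq_high, size=n_loci)
    ref = rng.integers(0, 4, size=n_loci)
    alt = (ref + rng.integers(1, 4, size=n_loci)) % 4
    loci = [
        SNPLocus(
            locus_id=f"rs{100000 + i}",
            chromosome=(i % 22) + 1,
            allele_ref=BASES[ref[i]],
            allele_alt=BASES[alt[i]],
            alt_freq=float(freqs[i]),
        )
        for i in range(n_loci)
    ]
    return SNPPanel(loci)
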