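"""Synthetic transplant-cohort generator.

Emulates the data a 1-month post-kidney-transplant dd-cfDNA study consumes:
donor/recipient genotypes at a biallelic SNP panel (Hardy-Weinberg,
unrelated individuals), cfDNA read pileups at a chosen donor fraction with
sequencing error and optional third-genome contamination, HLA typings with
prescribed eplet mismatch loads plus the matching allele→eplet table,
tacrolimus trough series, and outcome labels with the hierarchy
AbMR ⊆ acute rejection ⊆ troubled graft.

Default calibration reflects the cohort structure the analysis is designed
around: ~1/3 troubled grafts, half of them rejections, 5/7 of rejections
antibody-mediated; right-skewed (log-normal) donor fractions with group
medians 0.50% (uneventful) to 1.64% (AbMR); class II eplet mismatch loads
centred near 46 when the true donor fraction is elevated versus 21 when it
is not; troughs around 12.5 ng/mL with ~28% intra-patient CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eplets import (
    DEFAULT_ANTIGEN_LOCI,
    EpletTable,
    HlaTyping,
    MismatchLoads,
    antigen_mismatch_count,
)
from .exposure import TacrolimusSeries
from .panel import SNPPanel, make_default_panel
from .quant import CfDNASample

RngLike = int | np.random.Generator | np.random.SeedSequence


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genotypes and pileups
# ---------------------------------------------------------------------------

@dataclass
class GenotypePairSet:
    """Donor and recipient genotypes over a panel, as alt-allele dosages."""

    panel: SNPPanel
    donor_dosage: np.ndarray      # 0/1/2 copies of the alt allele
    recipient_dosage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.panel)
        self.donor_dosage = np.asarray(self.donor_dosage, dtype=np.int8)
        self.recipient_dosage = np.asarray(self.recipient_dosage, dtype=np.int8)
        for arr in (self.donor_dosage, self.recipient_dosage):
            if arr.shape != (n,):
                raise ValueError("one dosage per panel locus required")
            if arr.min() < 0 or arr.max() > 2:
                raise ValueError("dosages must be in {0, 1, 2}")

    def genotype_bases(self, who: str, i: int) -> tuple[str, str]:
        """Unordered nucleotide pair of ``who`` ('donor'|'recipient') at locus i."""
        locus = self.panel.loci[i]
        g = self.donor_dosage[i] if who == "donor" else self.recipient_dosage[i]
        return tuple([locus.allele_ref] * (2 - g) + [locus.allele_alt] * g)  # type: ignore


def simulate_genotype_pair(panel: SNPPanel, seed: RngLike) -> GenotypePairSet:
    """Independent Hardy-Weinberg genotypes for an unrelated donor/recipient.

    Alt dosage at each locus is Binomial(2, alt_freq), drawn independently
    per individual.
    """
    rng = _as_rng(seed)
    p = panel.alt_freqs
    return GenotypePairSet(
        panel=panel,
        donor_dosage=rng.binomial(2, p),
        recipient_dosage=rng.binomial(2, p),
    )


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial per-locus depth: mean and dispersion r
    (variance = mean + mean^2 / r; larger r = more uniform)."""

    mean: float = 5000.0
    dispersion: float = 4.0

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ValueError("mean depth must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        r = self.dispersion
        return rng.negative_binomial(r, r / (r + self.mean), size=n)


def _base_probs(panel: SNPPanel, dosage: np.ndarray) -> np.ndarray:
    """(n_loci, 4) per-read base probabilities for one genome."""
    n = len(panel)
    probs = np.zeros((n, 4))
    rows = np.arange(n)
    probs[rows, panel.alt_idx] = dosage / 2.0
    probs[rows, panel.ref_idx] = 1.0 - dosage / 2.0
    return probs


def simulate_pileup(
    genotypes: GenotypePairSet,
    donor_fraction: float,
    depth_model: DepthModel | None = None,
    error_rate: float = 0.001,
    seed: RngLike = 0,
    contamination_fraction: float = 0.0,
    contaminant_dosage: np.ndarray | None = None,
    sample_id: str = "S1",
    patient_id: str = "P1",
    collection_day: float = 30.0,
) -> CfDNASample:
    """cfDNA read counts at every panel locus.

    Each read originates from the donor with probability
    ``donor_fraction``/100 (and from an optional contaminant genome with
    probability ``contamination_fraction``/100), carries a base drawn from
    the originating genotype (heterozygote → 50/50), and is substituted
    uniformly to one of the other three bases with probability
    ``error_rate``. Depths are drawn per locus from ``depth_model``.
    """
    if not 0.0 <= donor_fraction <= 100.0:
        raise ValueError("donor_fraction must be in [0, 100]")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if not 0.0 <= contamination_fraction <= 100.0 - donor_fraction:
        raise ValueError("contamination_fraction must fit in the mixture")
    rng = _as_rng(seed)
    if depth_model is None:
        depth_model = DepthModel()
    panel = genotypes.panel
    fd = donor_fraction / 100.0
    fc = contamination_fraction / 100.0

    probs = (1.0 - fd - fc) * _base_probs(panel, genotypes.recipient_dosage)
    probs += fd * _base_probs(panel, genotypes.donor_dosage)
    if fc > 0.0:
        if contaminant_dosage is None:
            raise ValueError("contaminant_dosage required when contamination > 0")
        probs += fc * _base_probs(panel, np.asarray(contaminant_dosage))
    # uniform substitution error: base b keeps prob (1-e), receives e/3 from others
    probs = probs * (1.0 - error_rate) + (1.0 - probs) * (error_rate / 3.0)

    depths = depth_model.draw(rng, len(panel))
    counts = rng.multinomial(depths, probs)
    return CfDNASample(
        sample_id=sample_id,
        patient_id=patient_id,
        collection_day=collection_day,
        locus_ids=panel.locus_ids,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# tacrolimus series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TacrolimusModel:
    """Month-1 trough-sampling model.

    Per-patient mean trough ~ Normal(level_mean, level_sd_between); troughs
    on ``sampling_days`` ~ Normal(patient mean, cv * patient mean) with the
    intra-patient CV itself drawn Normal(cv_mean, cv_sd); constant daily
    dose ~ Normal(dose_mean, dose_sd). Levels floor at 0.5 ng/mL.
    """

    sampling_days: tuple[float, ...] = (1, 3, 5, 7, 10, 14, 21, 30)
    level_mean: float = 12.5      # ng/mL, cohort median of per-patient means
    level_sd_between: float = 2.2
    cv_mean: float = 0.28         # intra-patient coefficient of variation
    cv_sd: float = 0.08
    dose_mean: float = 7.0        # mg/day at month 1
    dose_sd: float = 2.0

    def __post_init__(self) -> None:
        if len(self.sampling_days) < 2:
            raise ValueError("need at least 2 sampling days")
        if any(not 0 <= d <= 30 for d in self.sampling_days):
            raise ValueError("sampling days must lie in [0, 30]")
        if len(set(self.sampling_days)) != len(self.sampling_days):
            raise ValueError("sampling days must be unique")


def simulate_tacrolimus_series(
    model: TacrolimusModel | None = None, seed: RngLike = 0
) -> TacrolimusSeries:
    """One patient's month-1 tacrolimus trough series."""
    if model is None:
        model = TacrolimusModel()
    rng = _as_rng(seed)
    days = np.sort(np.asarray(model.sampling_days, dtype=float))
    mu = max(rng.normal(model.level_mean, model.level_sd_between), 2.0)
    cv = float(np.clip(rng.normal(model.cv_mean, model.cv_sd), 0.0, 0.8))
    levels = np.maximum(rng.normal(mu, cv * mu, size=days.size), 0.5)
    dose = max(rng.normal(model.dose_mean, model.dose_sd), 1.0)
    return TacrolimusSeries(days=days, levels=levels, doses=np.full(days.size, dose))


# ---------------------------------------------------------------------------
# outcome, donor-fraction, eplet-load and covariate models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Hierarchical 1-month outcome prevalences (AbMR ⊆ rejection ⊆ troubled)."""

    p_troubled: float = 14 / 42
    p_rejection_given_troubled: float = 7 / 14
    p_abmr_given_rejection: float = 5 / 7
    p_extra_first_year_rejection: float = 2 / 35

    def __post_init__(self) -> None:
        for name, p in self.__dict__.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")


#: outcome group → (median dd-cfDNA %, log-scale sigma) of the log-normal
#: true-donor-fraction distribution
DEFAULT_DONOR_FRACTION_MODEL: dict[str, tuple[float, float]] = {
    "non_troubled": (0.50, 0.7),
    "troubled_no_rejection": (1.00, 0.6),
    "rejection_no_abmr": (0.65, 0.5),
    "abmr": (1.64, 0.5),
}


@dataclass(frozen=True)
class EpletLoadModel:
    """Negative-binomial eplet-load means, conditional on whether the true
    donor fraction is elevated (>= cutoff).

    ``classII_other`` covers class II loci beyond DRB1/DQB1/DQA1 (DRB3/4/5
    etc.), so the pooled class II total centres near classII_other + the
    three per-locus means: ~46 elevated vs ~21 not.
    """

    means_elevated: dict[str, float] = field(
        default_factory=lambda: {
            "classI": 20.0, "drb1": 10.0, "dqb1": 9.0, "dqa1": 3.0, "classII_other": 24.0
        }
    )
    means_low: dict[str, float] = field(
        default_factory=lambda: {
            "classI": 16.0, "drb1": 9.0, "dqb1": 7.0, "dqa1": 1.0, "classII_other": 4.0
        }
    )
    dispersion: float = 5.0

    def draw(self, rng: np.random.Generator, elevated: bool) -> dict[str, int]:
        means = self.means_elevated if elevated else self.means_low
        r = self.dispersion
        return {
            k: int(rng.negative_binomial(r, r / (r + m))) if m > 0 else 0
            for k, m in means.items()
        }


@dataclass(frozen=True)
class CovariateModel:
    egfr_mean: float = 52.0
    egfr_sd: float = 16.0
    egfr_shift_elevated: float = -6.0   # lower renal function with elevated dd-cfDNA
    albuminuria_median: float = 55.0    # mg/g, log-normal
    albuminuria_sigma: float = 1.1
    mpa_median: float = 2.0             # mg/L, log-normal
    mpa_sigma: float = 0.5


@dataclass
class SimulationConfig:
    """Everything needed to draw a cohort reproducibly from one seed."""

    n_patients: int = 42
    n_loci: int = 202
    depth_model: DepthModel = field(default_factory=DepthModel)
    error_rate: float = 0.001
    contamination_fraction: float = 0.0
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    donor_fraction_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DONOR_FRACTION_MODEL)
    )
    eplet_load_model: EpletLoadModel = field(default_factory=EpletLoadModel)
    tacrolimus_model: TacrolimusModel = field(default_factory=TacrolimusModel)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    elevated_cutoff: float = 1.0        # truth threshold driving eplet/covariate shifts
    include_reads: bool = True
    include_typings: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        missing = set(DEFAULT_DONOR_FRACTION_MODEL) - set(self.donor_fraction_model)
        if missing:
            raise ValueError(f"donor_fraction_model missing groups: {sorted(missing)}")


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    true_dd_fraction: float           # simulation truth, percent
    abmr: bool
    acute_rejection: bool
    troubled_graft: bool
    first_year_rejection: bool
    egfr: float
    albuminuria: float
    mpa_trough: float
    tacrolimus: TacrolimusSeries
    true_loads: MismatchLoads
    sample: CfDNASample | None = None
    donor_typing: HlaTyping | None = None
    recipient_typing: HlaTyping | None = None
    genotypes: GenotypePairSet | None = None


@dataclass
class CohortDataset:
    patients: list[PatientRecord]
    panel: SNPPanel
    eplet_table: EpletTable | None
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.patients)

    def truth_frame(self) -> pd.DataFrame:
        """Per-patient truth and labels as a tidy table."""
        rows = []
        for p in self.patients:
            row = {
                "patient_id": p.patient_id,
                "group": p.group,
                "true_dd_fraction": p.true_dd_fraction,
                "abmr": p.abmr,
                "acute_rejection": p.acute_rejection,
                "troubled_graft": p.troubled_graft,
                "first_year_rejection": p.first_year_rejection,
                "egfr": p.egfr,
                "albuminuria": p.albuminuria,
                "mpa_trough": p.mpa_trough,
            }
            row.update({f"true_{k}": v for k, v in p.true_loads.as_dict().items()})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic HLA typings with prescribed loads
# ---------------------------------------------------------------------------

_TYPING_LOCI = (
    ("A", "I"), ("B", "I"), ("C", "I"),
    ("DRB1", "II"), ("DQB1", "II"), ("DQA1", "II"), ("DRB345", "II"),
)


def _build_typing_pair(
    pid: str,
    locus_loads: dict[str, int],
    rng: np.random.Generator,
    repertoires: dict[str, frozenset[str]],
    eplet_class: dict[str, str],
) -> tuple[HlaTyping, HlaTyping]:
    """Construct donor/recipient typings realising exact per-locus loads.

    Synthetic alleles (one family per pair and locus, NOT real HLA names):
    the recipient is typed with two allele names sharing a base eplet set;
    donor alleles carry the base set plus exactly ``load`` extra eplets, so
    the per-locus mismatch load is the prescribed integer by construction.
    """
    donor: dict[str, tuple[str, str]] = {}
    recip: dict[str, tuple[str, str]] = {}
    for locus, cls in _TYPING_LOCI:
        load = int(locus_loads[locus])
        base = frozenset(f"{locus}.{pid}.b{j}" for j in range(int(rng.integers(3, 9))))
        r1, r2 = f"{locus}*R{pid}:01", f"{locus}*R{pid}:02"
        repertoires[r1] = base
        repertoires[r2] = base
        recip[locus] = (r1, r2)
        for e in base:
            eplet_class[e] = cls
        if load == 0:
            donor[locus] = (r1, r2)
            continue
        mm = [f"{locus}.{pid}.m{j}" for j in range(load)]
        for e in mm:
            eplet_class[e] = cls
        half = load // 2
        d1 = f"{locus}*D{pid}:01"
        # second donor allele: same antigen half the time, distinct otherwise
        d2 = f"{locus}*D{pid}:02" if rng.random() < 0.5 else f"{locus}*E{pid}:01"
        repertoires[d1] = base | set(mm[:half])
        repertoires[d2] = base | set(mm[half:])
        donor[locus] = (d1, d2)
    return HlaTyping(donor), HlaTyping(recip)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _draw_labels(rng: np.random.Generator, m: OutcomeModel) -> tuple[bool, bool, bool, bool, str]:
    troubled = rng.random() < m.p_troubled
    rejection = troubled and rng.random() < m.p_rejection_given_troubled
    abmr = rejection and rng.random() < m.p_abmr_given_rejection
    fyr = rejection or rng.random() < m.p_extra_first_year_rejection
    if abmr:
        group = "abmr"
    elif rejection:
        group = "rejection_no_abmr"
    elif troubled:
        group = "troubled_no_rejection"
    else:
        group = "non_troubled"
    return abmr, rejection, troubled, fyr, group


def simulate_cohort(config: SimulationConfig | None = None) -> CohortDataset:
    """Draw a complete synthetic cohort.

    Labels respect the AbMR ⊆ rejection ⊆ troubled hierarchy; the true
    donor fraction comes from the group's log-normal; eplet loads and the
    eGFR shift are drawn conditional on whether the true fraction clears
    the elevation cutoff. Each patient consumes an independent child stream
    of the master seed, so the dataset is reproducible bit-for-bit.
    """
    if config is None:
        config = SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    panel_seq, *patient_seqs = ss.spawn(config.n_patients + 1)
    panel = make_default_panel(config.n_loci, seed=np.random.default_rng(panel_seq).integers(2**31))

    repertoires: dict[str, frozenset[str]] = {}
    eplet_class: dict[str, str] = {}
    patients: list[PatientRecord] = []
    cov = config.covariate_model

    for i, seq in enumerate(patient_seqs):
        rng = np.random.default_rng(seq)
        pid = f"P{i + 1:04d}"
        abmr, rejection, troubled, fyr, group = _draw_labels(rng, config.outcome_model)
        med, sigma = config.donor_fraction_model[group]
        true_f = float(rng.lognormal(math.log(med), sigma))
        true_f = min(true_f, 40.0)
        elevated = true_f >= config.elevated_cutoff

        draws = config.eplet_load_model.draw(rng, elevated)
        a, b, c = rng.multinomial(draws["classI"], [1 / 3] * 3)
        locus_loads = {
            "A": int(a), "B": int(b), "C": int(c),
            "DRB1": draws["drb1"], "DQB1": draws["dqb1"],
            "DQA1": draws["dqa1"], "DRB345": draws["classII_other"],
        }

        donor_t = recip_t = None
        if config.include_typings:
            donor_t, recip_t = _build_typing_pair(pid, locus_loads, rng, repertoires, eplet_class)
            antigen_mm = antigen_mismatch_count(donor_t, recip_t, DEFAULT_ANTIGEN_LOCI)
        else:
            # emergent antigen count is unavailable without typings; draw a
            # cohort-realistic stand-in (median near 7-8 of a max of 12)
            antigen_mm = int(rng.binomial(12, 0.62))
        true_loads = MismatchLoads(
            antigen_mm_total=antigen_mm,
            classI_eplet_load=draws["classI"],
            classII_eplet_load=draws["drb1"] + draws["dqb1"] + draws["dqa1"] + draws["classII_other"],
            drb1_eplet_load=draws["drb1"],
            dqb1_eplet_load=draws["dqb1"],
            dqa1_eplet_load=draws["dqa1"],
        )

        genotypes = sample = None
        if config.include_reads:
            genotypes = simulate_genotype_pair(panel, rng)
            contaminant = None
            if config.contamination_fraction > 0:
                contaminant = rng.binomial(2, panel.alt_freqs)
            sample = simulate_pileup(
                genotypes,
                donor_fraction=true_f,
                depth_model=config.depth_model,
                error_rate=config.error_rate,
                seed=rng,
                contamination_fraction=config.contamination_fraction,
                contaminant_dosage=contaminant,
                sample_id=f"S-{pid}",
                patient_id=pid,
                collection_day=30.0,
            )

        series = simulate_tacrolimus_series(config.tacrolimus_model, rng)
        egfr = float(
            np.clip(rng.normal(cov.egfr_mean + (cov.egfr_shift_elevated if elevated else 0.0),
                               cov.egfr_sd), 8.0, 130.0)
        )
        albuminuria = float(rng.lognormal(math.log(cov.albuminuria_median), cov.albuminuria_sigma))
        mpa = float(rng.lognormal(math.log(cov.mpa_median), cov.mpa_sigma))

        patients.append(
            PatientRecord(
                patient_id=pid,
                group=group,
                true_dd_fraction=true_f,
                abmr=abmr,
                acute_rejection=rejection,
                troubled_graft=troubled,
                first_year_rejection=fyr,
                egfr=egfr,
                albuminuria=albuminuria,
                mpa_trough=mpa,
                tacrolimus=series,
                true_loads=true_loads,
                sample=sample,
                donor_typing=donor_t,
                recipient_typing=recip_t,
                genotypes=genotypes,
            )
        )

    table = (
        EpletTable(repertoires=repertoires, eplet_class=eplet_class)
        if config.include_typings
        else None
    )
    return CohortDataset(patients=patients, panel=panel, eplet_table=table, config=config)
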