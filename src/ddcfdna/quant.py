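"""Genotype-free donor-fraction estimation from SNP read counts.

The donor fraction of plasma cfDNA is estimated from a single
post-transplant sample with no donor or recipient genotyping. At each panel
SNP the two most-read nucleotides define a major (recipient) and minor
(donor) base. Loci whose two-base shares fall inside the 30-70% band are
heterozygous in the recipient and discarded; the remaining homozygous loci
split into background (donor carries the same allele, minor reads are
sequencing error) and informative signal (donor contributes the minor
allele). The donor fraction is the average minor-allele share over the
signal loci, expressed in percent.

Two averaging modes are exposed. ``paper_faithful`` takes the plain mean of
the signal shares. ``bias_corrected`` additionally subtracts the estimated
background error and resolves the mixture of donor-homozygous loci (share
close to f) and donor-heterozygous loci (share close to f/2) with a two-cluster
assignment, doubling the heterozygous cluster before averaging; this removes
the systematic underestimate the plain mean suffers on outbred pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .panel import BASES


class CallStatus(str, Enum):
    CANDIDATE = "candidate"                       # homozygous, not yet split
    INFORMATIVE_SIGNAL = "informative_signal"
    BACKGROUND = "background"
    HETEROZYGOUS_EXCLUDED = "heterozygous_excluded"
    LOW_DEPTH_EXCLUDED = "low_depth_excluded"
    OUTLIER_EXCLUDED = "outlier_excluded"


@dataclass(frozen=True)
class AlleleCounts:
    """Read counts of A/C/G/T at one SNP."""

    locus_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(BASES):
            raise ValueError("counts must cover exactly A, C, G, T")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class CfDNASample:
    """One plasma cfDNA pileup: per-locus A/C/G/T counts over a panel."""

    sample_id: str
    patient_id: str
    collection_day: float
    locus_ids: list[str]
    counts: np.ndarray  # (n_loci, 4) in A<C<G<T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (n_loci, 4)")
        if self.counts.shape[0] == 0:
            raise ValueError("pileup must cover at least one locus")
        if self.counts.shape[0] != len(self.locus_ids):
            raise ValueError("one count row per locus required")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.collection_day < 0:
            raise ValueError("collection_day must be >= 0")

    def __len__(self) -> int:
        return len(self.locus_ids)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def allele_counts(self, i: int) -> AlleleCounts:
        return AlleleCounts(
            self.locus_ids[i], {b: int(self.counts[i, j]) for j, b in enumerate(BASES)}
        )


@dataclass(frozen=True)
class InformativeCall:
    locus_id: str
    major_base: str
    minor_base: str
    minor_fraction: float     # minor / (major + minor); in [0, 0.5]
    two_base_depth: int
    total_depth: int
    status: CallStatus
    #: mean share of the two lowest (pure-error) bases, relative to the
    #: two-base depth — estimates the per-base substitution rate e/3
    residual_fraction: float = 0.0


@dataclass(frozen=True)
class QCReport:
    total_reads: int
    depth_uniformity: float   # CV of per-locus depth
    n_outlier_loci: int
    contamination_flag: bool
    passed: bool
    failed_checks: tuple[str, ...] = ()


@dataclass
class QuantConfig:
    """Tunable thresholds of the donor-fraction pipeline.

    The assay vendor publishes none of these; defaults are this package's
    documented choices.
    """

    min_depth: int = 100                  # reads/locus below which a locus is dropped
    band_low: float = 0.30                # heterozygous-exclusion band on two-base shares
    band_high: float = 0.70
    k_sigma: float = 3.0                  # signal threshold: bkg + k·binomial SE
    min_total_reads: int = 100_000        # QC-report pass threshold
    hard_min_total_reads: int = 1_000     # below this the estimate is refused
    max_depth_cv: float = 1.0
    max_outlier_loci: int = 10
    outlier_k_mad: float = 5.0
    #: prior share of donor-heterozygous loci among informative loci; the
    #: Hardy-Weinberg average 2pq(p^2+q^2) / [2pq(p^2+q^2) + 2p^2q^2] over
    #: panel frequencies near 0.5 (used by the truncation calibration)
    donor_het_prior: float = 0.69
    #: cap on the background level used for the signal split, as a multiple
    #: of the per-base error estimate: the lowest-half median can slip into
    #: the donor-heterozygous cluster at high donor fractions (most
    #: homozygous loci carry signal in outbred pairs), and the cap keeps the
    #: threshold at sequencing-error scale in that case
    background_cap_factor: float = 6.0


@dataclass
class DdcfdnaResult:
    dd_fraction_percent: float
    n_informative: int
    per_locus_calls: list[InformativeCall]
    mode: str
    qc: QCReport
    background_error: float       # threshold-scale background (largest error base)
    per_base_error: float = 0.0   # per-base substitution share (~e/3)
    flags: list[str] = field(default_factory=list)

    @property
    def dd_fraction_percent_rounded(self) -> float:
        """Reporting precision: two decimals, full precision kept internally."""
        return round(self.dd_fraction_percent, 2)


class QCFailure(RuntimeError):
    """Raised when a sample fails hard QC and the estimate is refused."""


def compute_allele_fractions(
    sample: CfDNASample, min_depth: int = 100
) -> list[InformativeCall]:
    """Major/minor base and minor-allele share per locus.

    The two most-read bases define major and minor; ties break by the fixed
    base order A<C<G<T (earlier base wins the major slot). Loci with total
    depth below ``min_depth`` are marked ``low_depth_excluded``.
    """
    if len(sample) == 0:
        raise ValueError("sample pileup is empty")
    calls: list[InformativeCall] = []
    # argsort on (-count, base index): stable pick of the top two bases
    order = np.argsort(-sample.counts, axis=1, kind="stable")
    for i in range(len(sample)):
        row = sample.counts[i]
        j_major, j_minor = int(order[i, 0]), int(order[i, 1])
        c_major, c_minor = int(row[j_major]), int(row[j_minor])
        two = c_major + c_minor
        depth = int(row.sum())
        frac = c_minor / two if two > 0 else 0.0
        residual = (depth - two) / 2.0 / two if two > 0 else 0.0
        status = CallStatus.LOW_DEPTH_EXCLUDED if depth < min_depth else CallStatus.CANDIDATE
        calls.append(
            InformativeCall(
                locus_id=sample.locus_ids[i],
                major_base=BASES[j_major],
                minor_base=BASES[j_minor],
                minor_fraction=frac,
                two_base_depth=two,
                total_depth=depth,
                status=status,
                residual_fraction=residual,
            )
        )
    return calls


def classify_informative(
    calls: list[InformativeCall], band_low: float = 0.30, band_high: float = 0.70
) -> list[InformativeCall]:
    """Apply the heterozygous-exclusion band.

    A locus whose two-base shares both lie inside [band_low, band_high] is
    heterozygous in the recipient and excluded; "outside" is strict, so an
    exact 30/70 split still counts as heterozygous.
    """
    if band_low >= band_high:
        raise ValueError("band_low must be < band_high")
    out = []
    for c in calls:
        if c.status is CallStatus.CANDIDATE:
            inside = (c.minor_fraction >= band_low) and (1.0 - c.minor_fraction <= band_high)
            if inside:
                c = replace(c, status=CallStatus.HETEROZYGOUS_EXCLUDED)
        out.append(c)
    return out


def estimate_background_error(calls: list[InformativeCall], min_loci: int = 10) -> float:
    """Sample-specific background error proxy.

    Median minor-allele share over the lowest-share half of the homozygous
    candidate loci. The lowest half is dominated by loci where donor and
    recipient are identically homozygous, so only sequencing error feeds
    the minor base there.
    """
    fracs = sorted(
        c.minor_fraction for c in calls if c.status is CallStatus.CANDIDATE
    )
    if len(fracs) < min_loci:
        raise ValueError(
            f"background estimation needs >= {min_loci} homozygous loci, got {len(fracs)}"
        )
    half = fracs[: max(1, len(fracs) // 2)]
    return float(np.median(half))


def estimate_per_base_error(calls: list[InformativeCall]) -> float:
    """Per-base substitution-error share (≈ e/3 under uniform substitution).

    Averages the two lowest base counts — pure error at every locus, since
    major and minor absorb the two true alleles — over the homozygous
    candidates. This is the error level feeding a signal locus's donor base,
    and is what the bias-corrected estimator subtracts; the background proxy
    of :func:`estimate_background_error` instead tracks the *largest* of the
    three error bases (the minor slot at donor-identical loci) and is the
    right scale for the signal/background threshold.
    """
    homozygous = (CallStatus.CANDIDATE, CallStatus.INFORMATIVE_SIGNAL, CallStatus.BACKGROUND)
    resid = [c.residual_fraction for c in calls if c.status in homozygous]
    if not resid:
        return 0.0
    return float(np.mean(resid))


def split_signal_background(
    calls: list[InformativeCall], error_rate: float, k_sigma: float = 3.0
) -> list[InformativeCall]:
    """Separate informative signal from background among homozygous loci.

    A candidate is signal when its minor share exceeds the background error
    by more than ``k_sigma`` binomial standard errors at its own two-base
    depth; otherwise it is background (donor identical to recipient).
    """
    out = []
    for c in calls:
        if c.status is CallStatus.CANDIDATE:
            if c.two_base_depth > 0:
                se = math.sqrt(error_rate * (1.0 - error_rate) / c.two_base_depth)
            else:
                se = 0.0
            status = (
                CallStatus.INFORMATIVE_SIGNAL
                if c.minor_fraction > error_rate + k_sigma * se
                else CallStatus.BACKGROUND
            )
            c = replace(c, status=status)
        out.append(c)
    return out


def _two_cluster_correct(y: np.ndarray, max_iter: int = 100, init: str = "p90") -> float:
    """Mean donor fraction from signal shares mixing f and f/2 clusters.

    1-D two-component assignment: each share is attributed to the
    donor-homozygous cluster (near f) or donor-heterozygous cluster (near
    f/2), heterozygous shares are doubled, and f is re-estimated until the
    assignment is stable. The default initialisation is the upper decile,
    which sits in the homozygous cluster whenever one exists;
    ``init="median"`` starts from twice the median (the heterozygous
    cluster under Hardy-Weinberg mixing), which stays anchored to the main
    signal even when a minority of loci carry a contaminating genome.
    """
    f = float(np.percentile(y, 90)) if init == "p90" else 2.0 * float(np.median(y))
    if f <= 0:
        return float(np.mean(y))
    for _ in range(max_iter):
        het = np.abs(y - f / 2.0) < np.abs(y - f)
        f_new = float(np.mean(np.where(het, 2.0 * y, y)))
        if abs(f_new - f) < 1e-12:
            break
        f = f_new
    return f


def _npdf(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)


def _expected_hard_estimate(
    f: float,
    boundary: float,
    depths: np.ndarray,
    weights: np.ndarray,
    thresholds: np.ndarray,
    w_het: float,
    e_base: float,
) -> float:
    """Expected assign-double-average estimate when the true donor fraction
    is ``f`` (on the error-subtracted share scale).

    Normal approximation per locus: a donor-heterozygous share sits at f/2,
    a donor-homozygous share at f, each with binomial noise at the locus
    depth, left-truncated at the signal threshold, and doubled whenever it
    falls below the het/hom assignment ``boundary``. All pieces are
    closed-form partial expectations of the normal, so the curve is smooth
    in f and can be inverted to undo truncation/misassignment bias.
    """
    if f <= 0:
        return 0.0
    a = thresholds - e_base          # thresholds on the subtracted scale
    num = 0.0
    den = 0.0
    for mu, w in ((f / 2.0, w_het), (f, 1.0 - w_het)):
        var = np.maximum((mu + e_base) * (1.0 - mu - e_base), 1e-14) / depths
        s = np.sqrt(var)
        alpha = (a - mu) / s
        bb = np.maximum(a, boundary)
        beta = (bb - mu) / s
        p_ret = 1.0 - ndtr(alpha)
        e_mid = mu * (ndtr(beta) - ndtr(alpha)) - s * (_npdf(beta) - _npdf(alpha))
        e_hi = mu * (1.0 - ndtr(beta)) + s * _npdf(beta)
        num += w * float(np.sum(weights * (2.0 * e_mid + e_hi)))
        den += w * float(np.sum(weights * p_ret))
    return num / den if den > 0 else f


def _invert_truncation_bias(
    f_hard: float,
    depths: np.ndarray,
    background: float,
    k_sigma: float,
    w_het: float,
    e_base: float,
) -> float:
    """Solve E[hard estimate | f] = f_hard for f.

    At the root the expected estimate equals the observed hard estimate, so
    the estimator's converged assignment boundary is exactly 0.75 f_hard;
    the depth distribution is summarised by decile bins for speed. Where
    the clusters are well separated the expected-estimate curve is the
    identity and the result equals ``f_hard``; near the detection threshold
    it undoes the upward truncation bias.
    """
    if f_hard <= 0 or depths.size == 0:
        return f_hard
    if depths.size > 12:
        depths = np.quantile(depths, np.linspace(0.05, 0.95, 10))
    weights = np.full(depths.size, 1.0 / depths.size)
    thresholds = background + k_sigma * np.sqrt(
        background * (1.0 - background) / depths
    )
    boundary = 0.75 * f_hard

    def gap(f: float) -> float:
        return (
            _expected_hard_estimate(f, boundary, depths, weights, thresholds, w_het, e_base)
            - f_hard
        )

    lo, hi = f_hard / 3.0, min(3.0 * f_hard, 0.5)
    if lo <= 0 or hi <= lo:
        return f_hard
    try:
        g_lo, g_hi = gap(lo), gap(hi)
        if g_lo == 0.0:
            return lo
        if g_lo * g_hi > 0:
            return f_hard
        return float(brentq(gap, lo, hi, xtol=1e-8))
    except (ValueError, RuntimeError):
        return f_hard


def qc_sample(
    sample: CfDNASample,
    config: QuantConfig | None = None,
    calls: list[InformativeCall] | None = None,
) -> QCReport:
    """Sample-level quality control.

    Checks total reads, per-locus depth uniformity (CV), and contamination:
    signal loci whose minor share sits further than ``outlier_k_mad``
    median-absolute-deviations from the signal-cluster median are outliers,
    and an excess of outliers raises the contamination flag (a third genome
    scatters extra informative-looking loci at its own fraction).
    """
    if config is None:
        config = QuantConfig()
    if calls is None:
        calls = compute_allele_fractions(sample, config.min_depth)
        calls = classify_informative(calls, config.band_low, config.band_high)
        try:
            bkg = estimate_background_error(calls)
        except ValueError:
            bkg = 0.0
        bkg = min(bkg, max(config.background_cap_factor * estimate_per_base_error(calls), 1e-4))
        calls = split_signal_background(calls, bkg, config.k_sigma)

    total = sample.total_reads
    depths = sample.counts.sum(axis=1).astype(float)
    depth_cv = float(depths.std() / depths.mean()) if depths.mean() > 0 else float("inf")

    sig = np.array(
        [c.minor_fraction for c in calls if c.status is CallStatus.INFORMATIVE_SIGNAL]
    )
    n_outliers = 0
    if sig.size >= 3:
        # a clean sample concentrates its signal shares on two clusters
        # (donor-heterozygous near f/2, donor-homozygous near f), each with
        # binomial spread at the locus depth. A contaminating third genome
        # scatters loci over a lattice of extra fractions that NO two-cluster
        # fit can absorb. Fit the best two-cluster partition (exact 1-D
        # 2-means on the sorted shares) and count loci further than k noise
        # scales from their own cluster centre.
        e_base = estimate_per_base_error(calls)
        y = np.maximum(sig - e_base, 0.0)
        depths_sig = np.array(
            [c.two_base_depth for c in calls if c.status is CallStatus.INFORMATIVE_SIGNAL],
            dtype=float,
        )
        order = np.argsort(y)
        ys = y[order]
        csum = np.concatenate([[0.0], np.cumsum(ys)])
        csq = np.concatenate([[0.0], np.cumsum(ys**2)])
        n = ys.size

        def sse(i, j):  # within-cluster sum of squares of ys[i:j]
            m = j - i
            s = csum[j] - csum[i]
            return (csq[j] - csq[i]) - s * s / m if m > 0 else 0.0

        best_k = 1
        best = np.inf
        for k in range(1, n):
            v = sse(0, k) + sse(k, n)
            if v < best:
                best, best_k = v, k
        centers = np.empty(n)
        centers[:best_k] = ys[:best_k].mean()
        centers[best_k:] = ys[best_k:].mean()
        dev = np.abs(ys - centers)
        # the yardstick must be the binomial noise the model implies, not
        # the observed spread (which is exactly what contamination inflates)
        se = np.sqrt(np.maximum(centers + e_base, 1e-6) / np.maximum(depths_sig[order], 1.0))
        n_outliers = int(np.sum(dev > config.outlier_k_mad * se))

    failed = []
    if total < config.min_total_reads:
        failed.append("total_reads")
    if depth_cv > config.max_depth_cv:
        failed.append("depth_uniformity")
    contamination = n_outliers > config.max_outlier_loci
    if contamination:
        failed.append("contamination")
    return QCReport(
        total_reads=total,
        depth_uniformity=depth_cv,
        n_outlier_loci=n_outliers,
        contamination_flag=contamination,
        passed=not failed,
        failed_checks=tuple(failed),
    )


def estimate_dd_fraction(
    sample: CfDNASample,
    mode: str = "bias_corrected",
    config: QuantConfig | None = None,
) -> DdcfdnaResult:
    """Donor-derived cfDNA fraction (%) of one plasma sample.

    Runs the full pipeline: allele fractions → heterozygous exclusion →
    background-error estimate → signal/background split → averaging in the
    requested mode → QC. Samples with fewer total reads than the hard QC
    floor are refused with :class:`QCFailure`.
    """
    if mode not in ("paper_faithful", "bias_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if config is None:
        config = QuantConfig()
    if sample.total_reads < config.hard_min_total_reads:
        raise QCFailure(
            f"sample {sample.sample_id}: total reads {sample.total_reads} below "
            f"hard minimum {config.hard_min_total_reads}"
        )

    flags: list[str] = []
    calls = compute_allele_fractions(sample, config.min_depth)
    calls = classify_informative(calls, config.band_low, config.band_high)
    try:
        bkg = estimate_background_error(calls)
    except ValueError:
        bkg = 0.0
        flags.append("background_not_estimable")
    e_base = estimate_per_base_error(calls)
    bkg = min(bkg, max(config.background_cap_factor * e_base, 1e-4))
    calls = split_signal_background(calls, bkg, config.k_sigma)
    qc = qc_sample(sample, config, calls)

    sig = np.array(
        [c.minor_fraction for c in calls if c.status is CallStatus.INFORMATIVE_SIGNAL]
    )
    if sig.size == 0:
        flags.append("no_signal")
        estimate = 0.0
    elif mode == "paper_faithful":
        estimate = 100.0 * float(np.mean(sig))
    else:
        y = np.maximum(sig - e_base, 0.0)
        f_hard = _two_cluster_correct(y)
        # undo the truncation/misassignment bias of the hard assignment:
        # population = every homozygous locus that could have carried signal
        homozygous = (CallStatus.INFORMATIVE_SIGNAL, CallStatus.BACKGROUND)
        depths = np.array(
            [c.two_base_depth for c in calls if c.status in homozygous and c.two_base_depth > 0],
            dtype=float,
        )
        estimate = 100.0 * _invert_truncation_bias(
            f_hard, depths, bkg, config.k_sigma, config.donor_het_prior, e_base
        )

    estimate = float(np.clip(estimate, 0.0, 100.0))
    return DdcfdnaResult(
        dd_fraction_percent=estimate,
        n_informative=int(sig.size),
        per_locus_calls=calls,
        mode=mode,
        qc=qc,
        background_error=bkg,
        per_base_error=e_base,
        flags=flags,
    )


def classify_cutoff(result: DdcfdnaResult | float, cutoff: float = 1.0) -> str:
    """Dichotomise a dd-cfDNA%: ``elevated`` iff >= cutoff (inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    value = result if isinstance(result, (int, float)) else result.dd_fraction_percent
    return "elevated" if value >= cutoff else "not_elevated"
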