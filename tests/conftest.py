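import numpy as np
import pandas as pd
import pytest

from ddcfdna import CfDNASample, make_default_panel
from ddcfdna.eplets import EpletTable, HlaTyping


@pytest.fixture(scope="session")
def panel202():
    return make_default_panel(202, seed=1)


@pytest.fixture()
def clean_sample_builder():
    """Build a 202-locus sample of clean recipient-homozygous loci with a
    configurable set of signal loci (counts given as (minor, major))."""

    def build(signal: dict[int, tuple[int, int]], depth: int = 5000) -> CfDNASample:
        counts = np.zeros((202, 4), dtype=np.int64)
        counts[:, 2] = depth  # G homozygous background everywhere
        for i, (minor, major) in signal.items():
            counts[i] = 0
            counts[i, 0] = minor  # A
            counts[i, 2] = major  # G
        return CfDNASample(
            sample_id="S1",
            patient_id="P1",
            collection_day=30.0,
            locus_ids=[f"L{i}" for i in range(202)],
            counts=counts,
        )

    return build


@pytest.fixture()
def toy_eplet_table():
    """Three-locus toy table with hand-enumerable repertoires."""
    rep = {
        "A*01:01": frozenset({"I.a", "I.b", "I.c"}),
        "A*02:01": frozenset({"I.a"}),
        "A*03:01": frozenset({"I.d"}),
        "DQB1*01:01": frozenset({"II.x", "II.y", "II.z"}),
        "DQB1*02:01": frozenset({"II.x"}),
        "DRB1*01:01": frozenset({"II.r", "II.y"}),
        "DRB1*02:01": frozenset({"II.r"}),
    }
    cls = {e: ("I" if e.startswith("I.") else "II") for s in rep.values() for e in s}
    return EpletTable(repertoires=rep, eplet_class=cls)


@pytest.fixture()
def toy_typings():
    donor = HlaTyping(
        {"A": ("A*01:01", "A*03:01"), "DQB1": ("DQB1*01:01", "DQB1*01:01"),
         "DRB1": ("DRB1*01:01", "DRB1*02:01")}
    )
    recipient = HlaTyping(
        {"A": ("A*02:01", "A*02:01"), "DQB1": ("DQB1*02:01", "DQB1*02:01"),
         "DRB1": ("DRB1*02:01", "DRB1*02:01")}
    )
    return donor, recipient


@pytest.fixture()
def joined_cohort_frame():
    """Small per-patient frame in the shape the analysis stage consumes."""
    rng = np.random.default_rng(5)
    n = 60
    score = rng.lognormal(np.log(0.7), 0.6, n)
    abmr = rng.random(n) < np.where(score >= 1.0, 0.4, 0.05)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "dd_fraction_percent": score,
            "abmr": abmr.astype(int),
            "acute_rejection": abmr.astype(int),
            "troubled_graft": abmr.astype(int),
            "egfr": rng.normal(50, 15, n),
            "classII_eplet_load": rng.poisson(np.where(score >= 1.0, 46, 21)),
        }
    )
    return df
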