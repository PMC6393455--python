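import numpy as np
import pytest

from vitdmr.harmonize import HarmonizedInstrument
from vitdmr.sumstats import SnpAssociation, SummaryStatsSet

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


def make_sumstats_set(rng: np.random.Generator, n: int, label: str = "study") -> SummaryStatsSet:
    assocs = []
    for i in range(n):
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        assocs.append(
            SnpAssociation(
                rsid=f"rs{1000 + i}",
                effect_allele=ea,
                other_allele=oa,
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.005, 0.05)),
                eaf=float(rng.uniform(0.05, 0.95)),
                pvalue=float(rng.uniform(1e-12, 1.0)),
                n=int(rng.integers(1000, 100000)),
            )
        )
    return SummaryStatsSet.from_associations(assocs, study_label=label)


def make_instruments(rng: np.random.Generator, k: int = 7) -> list:
    out = []
    for i in range(k):
        ea, oa = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
        out.append(
            HarmonizedInstrument(
                rsid=f"rs{2000 + i}",
                effect_allele=ea,
                other_allele=oa,
                beta_exposure=float(rng.uniform(0.02, 0.3)),
                se_exposure=float(rng.uniform(0.002, 0.01)),
                beta_outcome=float(rng.normal(0.0, 0.05)),
                se_outcome=float(rng.uniform(0.02, 0.08)),
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture
def sumstats_factory():
    return make_sumstats_set


@pytest.fixture
def instruments_factory():
    return make_instruments
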