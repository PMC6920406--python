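import numpy as np
import pytest

from mrkit import harmonize, make_fixture
from mrkit.summary_data import HarmonizedInstrument, InstrumentSet


def build_instruments(bx, by, sx, sy, rsids=None) -> InstrumentSet:
    """Assemble an already-aligned instrument set directly from arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sx = np.broadcast_to(np.asarray(sx, dtype=float), bx.shape)
    sy = np.broadcast_to(np.asarray(sy, dtype=float), bx.shape)
    if rsids is None:
        rsids = [f"rs{i}" for i in range(len(bx))]
    insts = [
        HarmonizedInstrument(
            rsid=r,
            effect_allele="A",
            other_allele="G",
            beta_exposure=float(x),
            se_exposure=float(s1),
            beta_outcome=float(y),
            se_outcome=float(s2),
            eaf_exposure=0.3,
            eaf_outcome=0.3,
            palindromic=False,
            action="kept_as_is",
        )
        for r, x, y, s1, s2 in zip(rsids, bx, by, sx, sy)
    ]
    return InstrumentSet(insts)


@pytest.fixture(scope="session")
def study_like_study():
    return make_fixture("study_like")


@pytest.fixture(scope="session")
def study_like_instruments(study_like_study):
    return harmonize(study_like_study.exposure_table, study_like_study.outcome_table)


@pytest.fixture(scope="session")
def outlier_demo_study():
    return make_fixture("outlier_demo")


@pytest.fixture(scope="session")
def tiny_instruments():
    study = make_fixture("tiny")
    return harmonize(study.exposure_table, study.outcome_table)
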