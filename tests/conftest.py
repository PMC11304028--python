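import numpy as np
import pytest

from mwpffc import MWDParams, build_pffc_subsample, fit_mle
from mwpffc.censoring import CensoringScheme, PFFCSample


@pytest.fixture(scope="session")
def renal_sub():
    """The censored renal subsample (n=20, m=10, k=5)."""
    return build_pffc_subsample()


@pytest.fixture(scope="session")
def renal_sub_fit(renal_sub):
    return fit_mle(renal_sub)


@pytest.fixture(scope="session")
def toy_sample():
    """A tiny m=3 sample with an informative-prior-friendly scale."""
    scheme = CensoringScheme(n=5, m=3, k=2, R=(1, 1, 0))
    return PFFCSample(scheme=scheme, x=np.array([0.4, 0.9, 1.6]))


@pytest.fixture(scope="session")
def study_truth():
    """True parameters used throughout the Monte-Carlo experiments."""
    return MWDParams(1.0, 0.1, 2.0)
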