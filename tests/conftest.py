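import math

import pytest
from scipy.integrate import quad

from wgdretain import (
    GenomeComposition,
    HypothesisSpec,
    SeriesConfig,
    get_profile,
)


@pytest.fixture(scope="session")
def profile():
    return get_profile("konrad2011_adjusted")


@pytest.fixture(scope="session")
def series():
    return SeriesConfig()


@pytest.fixture(scope="session")
def quad_survival():
    """Independent survival oracle: adaptive quadrature of the hazard.

    S(t) = exp(-int_0^t (d + f*exp(-b*u^c)) du), computed without the series
    expansion the implementation uses.
    """

    def _oracle(params, t):
        integral, err = quad(
            lambda u: params.d + params.f * math.exp(-params.b * u**params.c),
            0.0,
            t,
            epsabs=1e-13,
            epsrel=1e-13,
            limit=200,
        )
        return math.exp(-integral)

    return _oracle


@pytest.fixture(scope="session")
def mixture_composition():
    return GenomeComposition(0.45, 0.30, 0.25)


@pytest.fixture(scope="session")
def gd():
    return HypothesisSpec("gene_duplicability")
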