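import itertools

import pytest

import shelfrsm as s

SCHEMES = ("OLPR", "SCG", "OLPR_SCG")
TEMPERATURES = ("ambient", "cold_4C")
ALL_RESPONSES = list(itertools.product(SCHEMES, TEMPERATURES))


@pytest.fixture(scope="session")
def fits():
    """One fitted design + ANOVA report per bundled response."""
    out = {}
    for scheme, temp in ALL_RESPONSES:
        design = s.load_shelf_life(scheme, temp)
        fit = s.fit_quadratic(design)
        out[(scheme, temp)] = (design, fit, s.anova_table(design, fit))
    return out


@pytest.fixture(scope="session")
def m1_ambient(fits):
    return fits[("OLPR", "ambient")]


@pytest.fixture(scope="session")
def tmc_ambient():
    return s.load_tmc("ambient")


@pytest.fixture(scope="session")
def tmc_cold():
    return s.load_tmc("cold_4C")
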