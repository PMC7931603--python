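import numpy as np
import pandas as pd
import pytest

from urateaf import (AttributableFractionModel, BinaryDesign, CohortConfig,
                     SummaryStatConfig, default_exposure_specs, dichotomize,
                     generate_cohort)


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized general-population cohort (seeded)."""
    return generate_cohort(CohortConfig(n_individuals=20_000, seed=1))


@pytest.fixture(scope="session")
def design(cohort):
    return dichotomize(cohort, default_exposure_specs())


@pytest.fixture(scope="session")
def af_results(design):
    return AttributableFractionModel(design).fit()


def make_2x2_design(a: int, b: int, c: int, d: int) -> BinaryDesign:
    """Single-exposure design from 2x2 counts: a=exposed cases,
    b=unexposed cases, c=exposed controls, d=unexposed controls."""
    y = [1] * (a + b) + [0] * (c + d)
    x = [1] * a + [0] * b + [1] * c + [0] * d
    return BinaryDesign(outcome=pd.Series(y, name="hu"),
                        exposures=pd.DataFrame({"exposure": x}))


@pytest.fixture
def toy_2x2():
    return make_2x2_design(30, 70, 10, 90)


def make_instruments(bx, sx, by, sy, pos=None):
    from urateaf.mr import InstrumentSet
    bx = np.asarray(bx, float)
    n = len(bx)
    tab = pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(n)],
        "CHR": 1,
        "POS": pos if pos is not None else (np.arange(n) + 1) * 2_000_000,
        "beta_exp": bx,
        "se_exp": np.asarray(sx, float),
        "beta_out": np.asarray(by, float),
        "se_out": np.asarray(sy, float),
        "p_exp": 1e-10,
    })
    return InstrumentSet(table=tab)
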