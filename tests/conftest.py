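import numpy as np
import pandas as pd
import pytest

from rejuvotrack import simulate as sim
from rejuvotrack.clocks import ClockSpec


@pytest.fixture(scope="session")
def toy_clock():
    return sim.make_toy_clock()


@pytest.fixture
def tiny_identity_clock():
    """5-probe identity clock, small enough for hand/brute-force checks."""
    return ClockSpec(
        name="tiny",
        intercept=0.2,
        coefficients={
            "cg000": 1.0,
            "cg001": -0.5,
            "cg002": 2.0,
            "cg003": 0.0,
            "cg004": 0.75,
        },
        transform="identity",
        adult_age=None,
    )


@pytest.fixture
def default_course(toy_clock):
    """Default reprogramming scenario: betas + sheet + generator info."""
    spec = sim.TrajectorySpec(seed=11)
    betas, sheet, info = sim.synth_beta_course(toy_clock, spec)
    return spec, betas, sheet, info


def make_sheet(days, n_reps):
    rows = [
        {"sample": f"d{d:g}_r{r}", "day": float(d), "replicate": f"r{r}"}
        for d in days
        for r in range(1, n_reps + 1)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def simple_sheet():
    return make_sheet([0, 1, 2], 1)
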