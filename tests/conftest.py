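"""Shared fixtures and strategies for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import strategies as st

from ldftopsis import CopulaSpec, LDFN, make_ldfn

# one representative parameter per family, plus extra lam values where the
# family's domain has interesting corners
FAMILY_SPECS = [
    CopulaSpec(1, 1.0),
    CopulaSpec(1, 2.5),
    CopulaSpec(2, 1.0),
    CopulaSpec(2, -0.5),
    CopulaSpec(3, 2.0),
    CopulaSpec(3, -4.0),
    CopulaSpec(4, 0.5),
    CopulaSpec(4, -1.0),
    CopulaSpec(5, 1.0),
    CopulaSpec(5, 3.0),
]

ONE_PER_FAMILY = [
    CopulaSpec(1, 2.0),
    CopulaSpec(2, 1.0),
    CopulaSpec(3, 2.0),
    CopulaSpec(4, 0.5),
    CopulaSpec(5, 2.0),
]


def sample_ldfns(rng: np.random.Generator, size: int, q: int = 1,
                 low: float = 0.0, high: float = 1.0) -> list[LDFN]:
    """Rejection-sample valid LDFNs with components in [low, high]."""
    out: list[LDFN] = []
    while len(out) < size:
        rho, sigma, mem, nonmem = rng.uniform(low, high, size=4)
        if rho**q + sigma**q <= 1.0 and mem * rho**q + nonmem * sigma**q <= 1.0:
            out.append(make_ldfn(mem, nonmem, rho, sigma, q))
    return out


@st.composite
def ldfn_values(draw, q: int = 1) -> LDFN:
    """Hypothesis strategy for valid LDFNs at exponent q."""
    unit = st.floats(0.0, 1.0, allow_nan=False)
    rho = draw(unit)
    smax = (1.0 - rho**q) ** (1.0 / q) if rho < 1.0 else 0.0
    sigma = draw(unit) * smax
    mem = draw(unit)
    slack = 1.0 - mem * rho**q
    if sigma > 0.0:
        nonmem = min(1.0, slack / sigma**q) * draw(unit)
    else:
        nonmem = draw(unit)
    # shave rounding to stay strictly inside the constraints
    return make_ldfn(mem * (1 - 1e-12), nonmem * (1 - 1e-12), rho, sigma, q)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230714)
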