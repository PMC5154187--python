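import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from perilreg import CohortCounts

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


# Published coefficient tables of the three worked cohort analyses
# (age/BMI on hypertension; age/tolbutamide on mortality; age/personality on
# CHD).  Each row: term -> (beta, ci_lower, ci_upper, printed two-sided p).
HYPERTENSION_TABLE = {
    "Intercept": (0.0446, 0.0348, 0.0545, None),
    "Age": (0.1142, 0.0815, 0.1469, None),
    "BMI": (0.0724, 0.0514, 0.0934, None),
    "Age:BMI": (0.0866, 0.0335, 0.1397, 0.0014),
}

MORTALITY_TABLE = {
    "Intercept": (0.0426, 0.0053, 0.0799, 0.0254),
    "Age": (0.1660, 0.0570, 0.2743, 0.0028),
    "Treatment": (0.0359, -0.0300, 0.1019, 0.2859),
    "Age:Treatment": (0.0098, -0.1520, 0.1716, 0.9057),
}

CHD_TABLE = {
    "Intercept": (0.0398, 0.0163, 0.0633, 0.0009),
    "Age[50-54]": (0.0486, 0.0004, 0.0967, 0.0480),
    "Personality": (0.0399, -0.0022, 0.0821, 0.0631),
}

# published transformed values exp(-beta) at 4 d.p., across all three tables
PRINTED_TRANSFORMS = [
    (0.0446, 0.9564),
    (0.1142, 0.8921),
    (0.0724, 0.9302),
    (0.0866, 0.9170),
    (0.0426, 0.9583),
    (0.1660, 0.8470),
    (0.0398, 0.9610),
    (0.0399, 0.9609),
    (0.0486, 0.9526),
]


def saturated_beta_oracle(counts: CohortCounts) -> np.ndarray:
    """Closed-form saturated 2x2 coefficients: cell log-peril contrasts."""
    tab = counts.table.set_index(["x", "z"])
    lp = {c: -math.log1p(-tab.loc[c, "cases"] / tab.loc[c, "n"]) for c in tab.index}
    return np.array(
        [
            lp[(0, 0)],
            lp[(1, 0)] - lp[(0, 0)],
            lp[(0, 1)] - lp[(0, 0)],
            lp[(1, 1)] - lp[(1, 0)] - lp[(0, 1)] + lp[(0, 0)],
        ]
    )


def random_2x2_table(rng: np.random.Generator, n_low=50, n_high=500) -> CohortCounts:
    """A random non-degenerate grouped 2x2 cohort (no empty or boundary cells)."""
    n = rng.integers(n_low, n_high, size=4)
    cases = np.array([rng.integers(1, ni) for ni in n])
    table = pd.DataFrame(
        {"x": [0, 1, 0, 1], "z": [0, 0, 1, 1], "n": n, "cases": cases}
    )
    return CohortCounts(exposures=("x", "z"), table=table)


@pytest.fixture
def rng():
    return np.random.default_rng(20161213)
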