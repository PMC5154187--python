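"""Synthetic cohort generation from the sufficient-cause model.

A simulated cohort emulates a fixed-interval, fully-followed study: exposure
cells are drawn multinomially, and cases within each cell are binomial with
the risk implied by independent completion of the applicable sufficient-cause
classes.  There is no loss to follow-up, competing death, confounding or
measurement error — exactly the setting in which the complementary log
model's coefficients have their causal peril-ratio reading.

Monte-Carlo studies of test size and power draw per-replicate generators
from spawned seed sequences, so replicate r is reproducible in isolation
and the whole study is bit-reproducible under a fixed root seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .core_model import PROFILES, SufficientCauseSpec, cell_risks_from_spec
from .fitting import (
    BoundaryCellError,
    CohortCounts,
    ModelDesign,
    fit_complementary_log,
)
from .inference import ReriResult, prism_test, reri

__all__ = [
    "SimulationDesign",
    "StudyResult",
    "simulate_cohort",
    "reri_from_counts",
    "rejection_rate_study",
    "make_fixture_table",
    "FIXTURE_NAMES",
]

_UNIFORM_CELLS = {p: 0.25 for p in PROFILES}


@dataclass(frozen=True)
class SimulationDesign:
    """Everything needed to draw one synthetic cohort (or a study of them).

    Parameters
    ----------
    spec
        Generative truth: completion risks of the nine sufficient-cause
        classes.
    cell_probs
        Joint exposure distribution over the four (x, z) cells; defaults to
        uniform (0.25 each).
    n
        Cohort size.
    n_replicates, alpha
        Study settings for :func:`rejection_rate_study`.
    seed
        Root seed; per-replicate substreams are spawned from it.
    """

    spec: SufficientCauseSpec
    n: int
    cell_probs: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(_UNIFORM_CELLS)
    )
    n_replicates: int = 1000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        probs = {p: float(self.cell_probs.get(p, 0.0)) for p in PROFILES}
        if any(v < 0 for v in probs.values()):
            raise ValueError("cell probabilities must be nonnegative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities must sum to 1; got {total}")
        object.__setattr__(self, "cell_probs", probs)
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class StudyResult:
    """Rejection tallies of a Monte-Carlo size/power study.

    Rates are per converged replicate; fit failures are counted, never
    silently dropped.
    """

    design: SimulationDesign
    rejections: dict[str, int]
    n_effective: int
    n_failures: int
    rates: dict[str, float]
    mc_se: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "tests": {
                t: {
                    "rejections": self.rejections[t],
                    "rate": self.rates[t],
                    "mc_se": self.mc_se[t],
                }
                for t in self.rejections
            },
            "n_effective": self.n_effective,
            "n_failures": self.n_failures,
            "n_replicates": self.design.n_replicates,
            "n": self.design.n,
            "alpha": self.design.alpha,
            "seed": self.seed,
        }


def simulate_cohort(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> CohortCounts:
    """Draw one grouped cohort: multinomial cells, binomial cases per cell.

    Cells that receive no subjects are omitted from the table (the grouped
    representation has no zero-at-risk rows).  Identical design and seed
    give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    probs = [design.cell_probs[p] for p in PROFILES]
    counts = rng.multinomial(design.n, probs)
    risks = cell_risks_from_spec(design.spec)
    rows = []
    for profile, n_cell in zip(PROFILES, counts):
        if n_cell == 0:
            continue
        cases = int(rng.binomial(int(n_cell), risks.risk[profile]))
        rows.append({"x": profile[0], "z": profile[1], "n": int(n_cell), "cases": cases})
    return CohortCounts(exposures=("x", "z"), table=pd.DataFrame(rows))


def simulate_individual(
    design: SimulationDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Individual-level records equivalent to :func:`simulate_cohort`."""
    return simulate_cohort(design, rng=rng).to_individual()


def reri_from_counts(
    counts: CohortCounts,
    null_threshold: float = 1.0,
    continuity: float = 0.5,
) -> ReriResult:
    """RERI from the empirical risk ratios of a 2x2 grouped cohort.

    Risk ratios are taken relative to the (0, 0) cell; the standard error
    comes from the delta method via the log-RR covariances (the three RRs
    share the reference-cell denominator).  A continuity correction is
    applied to every cell whenever any cell has zero cases.  The default
    null threshold 1 is the stringent test specific to the (1, 1)
    interaction class; 0 is the conventional additivity null.
    """
    tab = counts.table.set_index(["x", "z"]) if set(counts.exposures) == {"x", "z"} else None
    if tab is None or len(counts.table) != 4:
        raise ValueError("reri_from_counts requires a complete 2x2 (x, z) table")
    n = {p: float(tab.loc[p, "n"]) for p in PROFILES}
    y = {p: float(tab.loc[p, "cases"]) for p in PROFILES}
    if any(y[p] == 0 for p in PROFILES):
        y = {p: y[p] + continuity for p in PROFILES}
        n = {p: n[p] + 2 * continuity for p in PROFILES}
    p_hat = {c: y[c] / n[c] for c in PROFILES}
    rr = {c: p_hat[c] / p_hat[(0, 0)] for c in PROFILES}

    # log-scale delta method: var(log RR_c) and cov from the shared reference
    var_log = {
        c: (1.0 - p_hat[c]) / (n[c] * p_hat[c])
        + (1.0 - p_hat[(0, 0)]) / (n[(0, 0)] * p_hat[(0, 0)])
        for c in ((1, 0), (0, 1), (1, 1))
    }
    cov_ref = (1.0 - p_hat[(0, 0)]) / (n[(0, 0)] * p_hat[(0, 0)])
    cells = [(1, 1), (1, 0), (0, 1)]
    grad = np.array([1.0, -1.0, -1.0])  # d RERI / d RR
    cov = np.empty((3, 3))
    for i, a in enumerate(cells):
        for j, b in enumerate(cells):
            cov_log = var_log[a] if a == b else cov_ref
            cov[i, j] = rr[a] * rr[b] * cov_log
    se = math.sqrt(float(grad @ cov @ grad))
    return reri(rr[(1, 1)], rr[(1, 0)], rr[(0, 1)], se=se, null_threshold=null_threshold)


_SATURATED_2X2 = ModelDesign(
    exposures=("x", "z"), levels={"x": (0, 1), "z": (0, 1)}, interaction_order=2
)


def rejection_rate_study(
    design: SimulationDesign,
    tests: Sequence[str] = ("prism", "reri"),
    reri_null_threshold: float = 1.0,
) -> StudyResult:
    """Monte-Carlo rejection rates of the PRISM and/or RERI tests.

    Per replicate: simulate a cohort, fit the saturated 2x2 complementary
    log model, run each requested test at ``design.alpha``, and tally
    rejections.  Replicates where the fit fails (boundary cell, missing
    cell, non-convergence) are excluded from the denominator; a warning is
    issued if more than 1% fail.
    """
    tests = tuple(tests)
    unknown = set(tests) - {"prism", "reri"}
    if unknown:
        raise ValueError(f"unknown tests {sorted(unknown)}; choose from prism, reri")
    rejections = {t: 0 for t in tests}
    failures = 0
    children = np.random.SeedSequence(design.seed).spawn(design.n_replicates)
    for child in children:
        rng = np.random.default_rng(child)
        cohort = simulate_cohort(design, rng=rng)
        try:
            if len(cohort.table) < 4:
                raise ValueError("incomplete 2x2 table")
            model = fit_complementary_log(cohort, design=_SATURATED_2X2)
            if not model.converged:
                raise ValueError(f"fit did not converge: {model.message}")
            results = {}
            if "prism" in tests:
                results["prism"] = prism_test(model).p_value
            if "reri" in tests:
                results["reri"] = reri_from_counts(
                    cohort, null_threshold=reri_null_threshold
                ).p_value
        except (ValueError, BoundaryCellError, ZeroDivisionError):
            failures += 1
            continue
        for t in tests:
            if results[t] < design.alpha:
                rejections[t] += 1
    n_eff = design.n_replicates - failures
    if failures > 0.01 * design.n_replicates:
        warnings.warn(
            f"{failures}/{design.n_replicates} replicates failed to fit",
            RuntimeWarning,
            stacklevel=2,
        )
    rates = {t: (rejections[t] / n_eff if n_eff else math.nan) for t in tests}
    mc_se = {
        t: (math.sqrt(rates[t] * (1 - rates[t]) / n_eff) if n_eff else math.nan)
        for t in tests
    }
    return StudyResult(
        design=design,
        rejections=rejections,
        n_effective=n_eff,
        n_failures=failures,
        rates=rates,
        mc_se=mc_se,
        seed=design.seed,
    )


# ---------------------------------------------------------------------------
# deterministic fixtures

FIXTURE_NAMES = ("null_2x2", "interaction_2x2", "single_cell", "boundary_cell")


def make_fixture_table(name: str) -> CohortCounts:
    """Small deterministic grouped tables for unit tests and documentation.

    - ``null_2x2``: survivals exactly multiplicative, so the saturated fit
      has interaction coefficient 0 (PRISM 1) in closed form.
    - ``interaction_2x2``: super-multiplicative (1,1) cell, PRISM > 1.
    - ``single_cell``: one cell with 5 cases out of 120 at risk; the
      intercept-only fit has beta0 = -log(115/120).
    - ``boundary_cell``: a cell with all subjects as cases, which the fitter
      must refuse (infinite log peril).
    """
    if name == "null_2x2":
        # survivals 0.96, 0.90, 0.80 and 0.90*0.80/0.96 = 0.75 exactly
        table = pd.DataFrame(
            {
                "x": [0, 1, 0, 1],
                "z": [0, 0, 1, 1],
                "n": [1000, 1000, 1000, 1000],
                "cases": [40, 100, 200, 250],
            }
        )
        return CohortCounts(exposures=("x", "z"), table=table)
    if name == "interaction_2x2":
        table = pd.DataFrame(
            {
                "x": [0, 1, 0, 1],
                "z": [0, 0, 1, 1],
                "n": [1000, 1000, 1000, 1000],
                "cases": [40, 100, 200, 400],
            }
        )
        return CohortCounts(exposures=("x", "z"), table=table)
    if name == "single_cell":
        table = pd.DataFrame({"x": [0], "n": [120], "cases": [5]})
        return CohortCounts(exposures=("x",), table=table)
    if name == "boundary_cell":
        table = pd.DataFrame(
            {
                "x": [0, 1, 0, 1],
                "z": [0, 0, 1, 1],
                "n": [50, 50, 50, 20],
                "cases": [5, 10, 8, 20],
            }
        )
        return CohortCounts(exposures=("x", "z"), table=table)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
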