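"""Maximum-likelihood fitting of binomial regression with complementary log link.

The model is a binomial GLM with link g(mu) = -log(1 - mu), equivalently
inverse link mu = 1 - exp(-eta).  Unlike logit/probit/cloglog this link maps
(0, 1) onto the positive half-line, so the linear predictor must satisfy
eta > 0 at every observation; the fitter enforces this by feasible
initialisation and step-halving against the boundary.

Fisher scoring uses the working weight n * (1 - mu) / mu per grouped row.
The stored negative log-likelihood is the kernel (binomial coefficients
excluded), so grouped and individual-level representations of the same data
yield identical likelihood-ratio statistics.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortCounts",
    "ModelDesign",
    "FittedModel",
    "BoundaryCellError",
    "build_design_matrix",
    "negative_log_likelihood",
    "fit_complementary_log",
    "inverse_link",
    "predict_risk",
]


class BoundaryCellError(ValueError):
    """Raised when a cell has cases == at-risk, making its log peril infinite."""


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class CohortCounts:
    """Grouped cohort data: one row per exposure cell.

    Parameters
    ----------
    exposures
        Names of the exposure columns, in model order.
    table
        DataFrame with the exposure columns plus ``n`` (number at risk,
        positive) and ``cases`` (number of cases, 0 <= cases <= n).
        Exposure profiles must be unique across rows.
    """

    exposures: tuple[str, ...]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposures", tuple(self.exposures))
        tab = self.table.reset_index(drop=True).copy()
        missing = [c for c in (*self.exposures, "n", "cases") if c not in tab.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        tab["n"] = tab["n"].astype(np.int64)
        tab["cases"] = tab["cases"].astype(np.int64)
        if (tab["n"] <= 0).any():
            bad = tab.index[tab["n"] <= 0][0]
            raise ValueError(f"row {bad}: number at risk must be positive")
        if (tab["cases"] < 0).any() or (tab["cases"] > tab["n"]).any():
            bad = tab.index[(tab["cases"] < 0) | (tab["cases"] > tab["n"])][0]
            raise ValueError(f"row {bad}: cases must satisfy 0 <= cases <= n")
        if tab.duplicated(subset=list(self.exposures)).any():
            raise ValueError("exposure profiles must be unique across rows")
        object.__setattr__(self, "table", tab[[*self.exposures, "n", "cases"]])

    @classmethod
    def from_individual(
        cls,
        records: pd.DataFrame,
        exposures: Sequence[str],
        outcome: str = "outcome",
    ) -> "CohortCounts":
        """Aggregate individual-level records (binary ``outcome``) to cells."""
        exposures = tuple(exposures)
        missing = [c for c in (*exposures, outcome) if c not in records.columns]
        if missing:
            raise ValueError(f"individual records are missing columns: {missing}")
        y = records[outcome]
        if not y.isin([0, 1]).all():
            raise ValueError(f"outcome column {outcome!r} must be binary 0/1")
        grouped = (
            records.groupby(list(exposures), sort=False)[outcome]
            .agg(n="size", cases="sum")
            .reset_index()
        )
        return cls(exposures=exposures, table=grouped)

    def to_individual(self, outcome: str = "outcome") -> pd.DataFrame:
        """Expand to one row per subject (cases first within each cell)."""
        rows = []
        for _, row in self.table.iterrows():
            profile = {e: row[e] for e in self.exposures}
            rows.extend([{**profile, outcome: 1}] * int(row["cases"]))
            rows.extend([{**profile, outcome: 0}] * int(row["n"] - row["cases"]))
        return pd.DataFrame(rows, columns=[*self.exposures, outcome])

    @property
    def n_total(self) -> int:
        return int(self.table["n"].sum())

    @property
    def cases_total(self) -> int:
        return int(self.table["cases"].sum())

    def pooled_risk(self) -> float:
        return self.cases_total / self.n_total

    def profile_labels(self) -> list[tuple]:
        return [tuple(row) for row in self.table[list(self.exposures)].itertuples(index=False)]


@dataclass(frozen=True)
class ModelDesign:
    """Terms of a complementary log regression: intercept, dummy-coded main
    effects, and interaction products up to a given order.

    Categorical exposures are dummy-coded against their reference level
    (first declared level); continuous exposures enter as a single column.
    """

    exposures: tuple[str, ...]
    levels: Mapping[str, tuple]
    continuous: frozenset[str] = frozenset()
    interaction_order: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposures", tuple(self.exposures))
        object.__setattr__(self, "continuous", frozenset(self.continuous))
        levels = {e: tuple(v) for e, v in dict(self.levels).items()}
        for e in self.exposures:
            if e in self.continuous:
                levels.setdefault(e, ())
            elif e not in levels or len(levels[e]) < 2:
                raise ValueError(f"categorical exposure {e!r} needs >= 2 declared levels")
        object.__setattr__(self, "levels", levels)
        if not 1 <= self.interaction_order <= max(1, len(self.exposures)):
            raise ValueError("interaction_order must be in [1, number of exposures]")

    @classmethod
    def from_data(
        cls,
        data: CohortCounts,
        interaction_order: int | None = None,
        continuous: Iterable[str] = (),
        levels: Mapping[str, Sequence] | None = None,
    ) -> "ModelDesign":
        """Infer levels from the data.  Numeric levels are sorted ascending
        (so 0 is the reference for 0/1 coding); other levels keep order of
        first appearance.  Default interaction order is the full order.
        """
        continuous = frozenset(continuous)
        inferred: dict[str, tuple] = {}
        for e in data.exposures:
            if e in continuous:
                continue
            if levels and e in levels:
                inferred[e] = tuple(levels[e])
                continue
            observed = list(dict.fromkeys(data.table[e]))
            if all(isinstance(v, (int, float, np.integer, np.floating)) for v in observed):
                observed = sorted(observed)
            inferred[e] = tuple(observed)
        if interaction_order is None:
            interaction_order = max(1, len(data.exposures))
        return cls(
            exposures=data.exposures,
            levels=inferred,
            continuous=continuous,
            interaction_order=interaction_order,
        )

    @classmethod
    def intercept_only(cls) -> "ModelDesign":
        """One-parameter design: beta0 = -log(1 - pooled risk) in closed form."""
        return cls(exposures=(), levels={}, interaction_order=1)

    def reference_level(self, exposure: str):
        if exposure in self.continuous:
            return 0.0
        return self.levels[exposure][0]

    def main_effect_terms(self) -> list[tuple[str, object]]:
        """(exposure, level) pairs for each main-effect column; level is None
        for a continuous exposure."""
        terms: list[tuple[str, object]] = []
        for e in self.exposures:
            if e in self.continuous:
                terms.append((e, None))
            else:
                terms.extend((e, lev) for lev in self.levels[e][1:])
        return terms

    def term_labels(self) -> list[str]:
        labels = ["Intercept"]
        for e, lev in self.main_effect_terms():
            labels.append(self._label(e, lev))
        for order in range(2, self.interaction_order + 1):
            for combo in itertools.combinations(self.exposures, order):
                for parts in itertools.product(
                    *[self._exposure_parts(e) for e in combo]
                ):
                    labels.append(":".join(self._label(e, lev) for e, lev in parts))
        return labels

    def interaction_labels(self, order: int | None = None) -> list[str]:
        """Labels of interaction terms (all orders >= 2, or one given order)."""
        out = []
        for lab in self.term_labels():
            k = lab.count(":") + 1
            if k >= 2 and (order is None or k == order):
                out.append(lab)
        return out

    def _exposure_parts(self, e: str) -> list[tuple[str, object]]:
        if e in self.continuous:
            return [(e, None)]
        return [(e, lev) for lev in self.levels[e][1:]]

    def _label(self, e: str, lev) -> str:
        if lev is None or len(self.levels.get(e, ())) == 2:
            return e
        return f"{e}[{lev}]"

    def _columns(self) -> list[list[tuple[str, object]]]:
        """Each column as a list of (exposure, level) factors to multiply."""
        cols: list[list[tuple[str, object]]] = [[]]  # intercept
        for term in self.main_effect_terms():
            cols.append([term])
        for order in range(2, self.interaction_order + 1):
            for combo in itertools.combinations(self.exposures, order):
                for parts in itertools.product(
                    *[self._exposure_parts(e) for e in combo]
                ):
                    cols.append(list(parts))
        return cols


def build_design_matrix(
    data: CohortCounts | pd.DataFrame,
    design: ModelDesign,
    outcome: str = "outcome",
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Design matrix for grouped or individual data.

    Returns
    -------
    X : (rows, terms) float array
    labels : term labels in column order
    n : number at risk per row (all ones for individual data)
    y : cases per row
    """
    if isinstance(data, CohortCounts):
        frame = data.table
        n = frame["n"].to_numpy(dtype=float)
        y = frame["cases"].to_numpy(dtype=float)
    else:
        frame = data
        if outcome not in frame.columns:
            raise ValueError(f"individual data needs an {outcome!r} column")
        n = np.ones(len(frame))
        y = frame[outcome].to_numpy(dtype=float)

    # validate observed levels
    for e in design.exposures:
        if e in design.continuous:
            continue
        observed = set(frame[e])
        declared = set(design.levels[e])
        unseen = observed - declared
        if unseen:
            raise ValueError(
                f"exposure {e!r} has levels {sorted(unseen, key=repr)} not declared "
                f"in the design (declared: {list(design.levels[e])})"
            )

    cols = design._columns()
    X = np.empty((len(frame), len(cols)))
    for j, factors in enumerate(cols):
        col = np.ones(len(frame))
        for e, lev in factors:
            if lev is None and e in design.continuous:
                col = col * frame[e].to_numpy(dtype=float)
            else:
                col = col * (frame[e].to_numpy() == lev).astype(float)
        X[:, j] = col
    return X, design.term_labels(), n, y


# ---------------------------------------------------------------------------
# likelihood


def negative_log_likelihood(
    beta: np.ndarray, X: np.ndarray, n: np.ndarray, y: np.ndarray
) -> float:
    """Negative binomial log-likelihood kernel at beta.

    mu = 1 - exp(-X beta).  Binomial coefficients are excluded so the value
    is representation-invariant (grouped vs individual).  Any row with
    eta <= 0 makes the value +inf (used by step-halving), never an exception.
    """
    eta = X @ np.asarray(beta, dtype=float)
    if np.any(eta <= 0.0) or np.any(~np.isfinite(eta)):
        return math.inf
    mu = -np.expm1(-eta)
    # 0*log(0) := 0 at y == 0 or y == n
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(mu), 0.0)
        term2 = np.where(n - y > 0, (n - y) * (-eta), 0.0)  # log(1-mu) = -eta
    ll = float(np.sum(term1) + np.sum(term2))
    return -ll


def _saturated_nll(n: np.ndarray, y: np.ndarray) -> float:
    p = y / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(p), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
    return -float(np.sum(t1) + np.sum(t2))


def _nll_gradient(
    beta: np.ndarray, X: np.ndarray, n: np.ndarray, y: np.ndarray
) -> np.ndarray:
    eta = X @ beta
    mu = -np.expm1(-eta)
    mu = np.clip(mu, 1e-300, None)
    # dll/deta = y(1-mu)/mu - (n-y)
    score = y * (1.0 - mu) / mu - (n - y)
    return -(X.T @ score)


# ---------------------------------------------------------------------------
# fitted model


@dataclass(frozen=True)
class FittedModel:
    """Result of a complementary log regression fit.

    ``nll`` is the negative log-likelihood kernel, so a likelihood-ratio
    statistic is 2 * (nll_reduced - nll_full).  ``cov`` is the inverse
    expected information at the estimate.
    """

    params: pd.Series
    cov: pd.DataFrame
    nll: float
    deviance: float
    n_iter: int
    converged: bool
    design: ModelDesign
    n_total: int
    cases_total: int
    message: str = ""

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def se(self, term: str) -> float:
        return math.sqrt(self.cov.loc[term, term])

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def predict_risk(self, profile: Mapping, clamp: bool = True) -> float:
        return predict_risk(self, profile, clamp=clamp)


# ---------------------------------------------------------------------------
# fitting


def _initial_beta(X: np.ndarray, n: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feasible start: empirical log perils with a continuity correction,
    projected onto the design by least squares; fall back to the pooled
    intercept-only start (always feasible because eta = beta0 > 0)."""
    p = (y + 0.5) / (n + 1.0)
    lp = -np.log1p(-p)
    beta, *_ = np.linalg.lstsq(X, lp, rcond=None)
    if np.all(X @ beta > 0.0):
        return beta
    pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta = np.zeros(X.shape[1])
    beta[0] = -math.log1p(-pooled)
    return beta


def fit_complementary_log(
    data: CohortCounts | pd.DataFrame,
    design: ModelDesign | None = None,
    *,
    exposures: Sequence[str] | None = None,
    interaction_order: int | None = None,
    outcome: str = "outcome",
    max_iter: int = 100,
    tol: float = 1e-8,
    dev_tol: float = 1e-10,
    max_halvings: int = 50,
    allow_boundary: bool = False,
) -> FittedModel:
    """Fit the binomial GLM with link g(mu) = -log(1 - mu) by Fisher scoring.

    Parameters
    ----------
    data
        Grouped :class:`CohortCounts`, or an individual-level DataFrame with
        exposure columns and a binary ``outcome`` column (``exposures`` must
        then be given).
    design
        Model terms; default is the saturated design inferred from the data
        (all interactions), or up to ``interaction_order`` if given.
    allow_boundary
        If False (default), any cell with cases == n raises
        :class:`BoundaryCellError` because its log peril is infinite.

    Returns
    -------
    FittedModel
        With ``converged`` False (never an exception) if the iteration limit
        is reached; inspect ``message``.
    """
    if isinstance(data, pd.DataFrame) and not isinstance(data, CohortCounts):
        if exposures is None:
            raise ValueError("individual-level data requires `exposures`")
        data = CohortCounts.from_individual(data, exposures, outcome=outcome)
    if design is None:
        design = ModelDesign.from_data(data, interaction_order=interaction_order)

    if not allow_boundary:
        boundary = data.table["cases"] == data.table["n"]
        if boundary.any():
            cell = tuple(data.table.loc[boundary.idxmax(), list(data.exposures)])
            raise BoundaryCellError(
                f"cell {cell} has all {int(data.table.loc[boundary.idxmax(), 'n'])} "
                "subjects as cases: its log peril is infinite and the maximum "
                "likelihood estimate does not exist on this design"
            )

    X, labels, n, y = build_design_matrix(data, design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix is rank-deficient ({np.linalg.matrix_rank(X)} < "
            f"{X.shape[1]}): collinear specification"
        )

    beta = _initial_beta(X, n, y)
    nll = negative_log_likelihood(beta, X, n, y)
    converged = False
    message = ""
    info = None
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = -np.expm1(-eta)
        mu = np.clip(mu, 1e-12, None)
        w = n * (1.0 - mu) / mu
        z = eta + (y / n - mu) / (1.0 - mu)
        WX = X * w[:, None]
        info = X.T @ WX
        rhs = X.T @ (w * z)
        try:
            proposal = np.linalg.solve(info, rhs)
        except np.linalg.LinAlgError as exc:
            message = f"singular information matrix at iteration {it}: {exc}"
            break
        delta = proposal - beta
        step = 1.0
        accepted = False
        for _ in range(max_halvings + 1):
            cand = beta + step * delta
            nll_cand = negative_log_likelihood(cand, X, n, y)
            if nll_cand <= nll + 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            message = f"step-halving failed to improve at iteration {it}"
            break
        change = float(np.max(np.abs(cand - beta)))
        rel_dev = abs(nll - nll_cand) / (abs(nll_cand) + 1.0)
        beta, nll = cand, nll_cand
        if change < tol and rel_dev < dev_tol:
            converged = True
            break

    grad = _nll_gradient(beta, X, n, y)
    if not converged and float(np.max(np.abs(grad))) < 1e-6:
        converged = True  # stalled within numerical resolution of the optimum
    if not converged and not message:
        message = f"no convergence after {max_iter} iterations"

    # expected information at the final estimate
    eta = X @ beta
    mu = np.clip(-np.expm1(-eta), 1e-12, None)
    w = n * (1.0 - mu) / mu
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)

    deviance = 2.0 * (nll - _saturated_nll(n, y))
    return FittedModel(
        params=pd.Series(beta, index=labels),
        cov=pd.DataFrame(cov, index=labels, columns=labels),
        nll=nll,
        deviance=deviance,
        n_iter=it,
        converged=converged,
        design=design,
        n_total=data.n_total,
        cases_total=data.cases_total,
        message=message,
    )


# ---------------------------------------------------------------------------
# prediction


def inverse_link(eta: float, clamp: bool = False) -> float:
    """Risk from the linear predictor: 1 - exp(-eta).

    Unclamped the value can be negative (the link does not map the real line
    into [0, 1]); with ``clamp`` the predictor is floored at 0 first, so the
    result is guaranteed in [0, 1).
    """
    if clamp and eta < 0.0:
        logger.info("linear predictor %.6g clamped to 0 for risk prediction", eta)
        eta = 0.0
    return -math.expm1(-eta)


def predict_risk(model: FittedModel, profile: Mapping, clamp: bool = True) -> float:
    """Predicted risk for a new subject with the given exposure profile.

    By default the linear predictor is clamped at zero, guaranteeing a
    prediction in [0, 1) even for profiles outside the convex hull of the
    fitted data; ``clamp=False`` returns the raw 1 - exp(-eta).
    """
    design = model.design
    row = pd.DataFrame([dict(profile)])
    for e in design.exposures:
        if e not in row.columns:
            raise ValueError(f"profile is missing exposure {e!r}")
    x, _, _, _ = build_design_matrix(
        CohortCounts(
            exposures=design.exposures,
            table=row.assign(n=1, cases=0),
        ),
        design,
    )
    eta = float(x[0] @ model.params.to_numpy())
    return inverse_link(eta, clamp=clamp)
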