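"""Wald and likelihood-ratio inference for complementary log regression.

Estimands follow the peril-ratio reading of the model: for a main-effect
term, exp(-beta) is the inverse (adjusted) peril ratio, i.e. a ratio of
survival probabilities; for the cross-product term of two binary exposures,
exp(beta) is PRISM — the peril ratio index of synergy based on
multiplicativity — and testing beta = 0 is a test for sufficient-cause
(mechanistic) interaction.  In the rare-disease limit the model is linear in
the odds, giving the gamma = beta_i / beta_0 excess-odds-ratio mapping and
the RERI index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fitting import FittedModel

__all__ = [
    "EffectEstimate",
    "PrismResult",
    "ReriResult",
    "GammaResult",
    "LrtResult",
    "wald_test",
    "confint_transformed",
    "prism_test",
    "likelihood_ratio_test",
    "reri",
    "gamma_from_beta",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A coefficient with its Wald CI on both scales.

    ``transformed`` is exp(-beta), the survival-ratio (inverse peril-ratio)
    scale; its CI endpoints are swapped relative to the coefficient CI.
    """

    term: str
    beta: float
    se: float
    level: float
    ci_lower: float
    ci_upper: float
    transformed: float
    transformed_ci_lower: float
    transformed_ci_upper: float
    z: float
    p_value: float


@dataclass(frozen=True)
class PrismResult:
    """PRISM test for sufficient-cause interaction.

    Single interaction term: PRISM = exp(beta3) with a Wald z test.
    Several terms of common order (multi-level exposures): a joint Wald
    chi-square on the coefficient subvector; rejection asserts presence of
    at least one interaction class.
    """

    terms: tuple[str, ...]
    prism: float | None
    inverse_prism: float | None
    ci_lower: float | None
    ci_upper: float | None
    inverse_ci_lower: float | None
    inverse_ci_upper: float | None
    statistic: float
    df: int
    p_value: float
    per_term: tuple[EffectEstimate, ...] = ()


@dataclass(frozen=True)
class ReriResult:
    """Relative excess risk due to interaction: v11 - v10 - v01 + 1 on a
    ratio scale (risk ratios, or odds ratios for rare diseases)."""

    reri: float
    se: float | None
    null_threshold: float
    z: float | None
    p_value: float | None  # one-sided, H1: RERI > threshold


@dataclass(frozen=True)
class GammaResult:
    """Rare-disease linear-odds coefficients gamma_i = beta_i / beta_0.

    Each gamma of a main-effect term approximates the excess odds ratio
    (OR - 1); for the 2x2 cross-product term gamma equals
    OR11 - OR10 - OR01 + 1, the (odds-ratio) RERI index.
    """

    gamma: dict[str, float]
    beta0: float


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    df: int
    p_value: float


def _z_quantile(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2.0))


def wald_test(model: FittedModel, term: str) -> tuple[float, float]:
    """Wald z statistic and two-sided p for a single coefficient."""
    if term not in model.params.index:
        raise KeyError(f"term {term!r} not in model (terms: {model.terms})")
    se = model.se(term)
    if se <= 0.0 or not math.isfinite(se):
        raise ValueError(f"degenerate information: SE of {term!r} is {se}")
    z = float(model.params[term]) / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def confint_transformed(
    model: FittedModel, term: str, level: float = 0.95
) -> EffectEstimate:
    """Coefficient CI and its exp(-beta) transform with endpoint swap.

    The transformed lower bound is exp(-upper coefficient bound) and vice
    versa, since exp(-x) is decreasing.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1); got {level}")
    z_stat, p = wald_test(model, term)
    beta = float(model.params[term])
    se = model.se(term)
    q = _z_quantile(level)
    lo, hi = beta - q * se, beta + q * se
    return EffectEstimate(
        term=term,
        beta=beta,
        se=se,
        level=level,
        ci_lower=lo,
        ci_upper=hi,
        transformed=math.exp(-beta),
        transformed_ci_lower=math.exp(-hi),
        transformed_ci_upper=math.exp(-lo),
        z=z_stat,
        p_value=p,
    )


def prism_test(
    model: FittedModel,
    interaction_terms: Sequence[str] | None = None,
    level: float = 0.95,
) -> PrismResult:
    """Test for sufficient-cause interaction via the interaction coefficients.

    With a single term this is the Wald test of beta3 = 0 and reports
    PRISM = exp(beta3) with its CI; with several terms (multi-level
    exposures) it is a joint Wald chi-square with df = number of terms.
    """
    if interaction_terms is None:
        interaction_terms = model.design.interaction_labels()
    terms = tuple(interaction_terms)
    if not terms:
        raise ValueError("no interaction terms to test")
    for t in terms:
        if t not in model.params.index:
            raise KeyError(f"term {t!r} not in model (terms: {model.terms})")

    per_term = tuple(confint_transformed(model, t, level=level) for t in terms)

    if len(terms) == 1:
        est = per_term[0]
        return PrismResult(
            terms=terms,
            prism=math.exp(est.beta),
            inverse_prism=est.transformed,
            ci_lower=math.exp(est.ci_lower),
            ci_upper=math.exp(est.ci_upper),
            inverse_ci_lower=est.transformed_ci_lower,
            inverse_ci_upper=est.transformed_ci_upper,
            statistic=est.z,
            df=1,
            p_value=est.p_value,
            per_term=per_term,
        )

    b = model.params[list(terms)].to_numpy()
    V = model.cov.loc[list(terms), list(terms)].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance of interaction subvector: {exc}") from exc
    df = len(terms)
    p = float(stats.chi2.sf(stat, df))
    return PrismResult(
        terms=terms,
        prism=None,
        inverse_prism=None,
        ci_lower=None,
        ci_upper=None,
        inverse_ci_lower=None,
        inverse_ci_upper=None,
        statistic=stat,
        df=df,
        p_value=p,
        per_term=per_term,
    )


def likelihood_ratio_test(full: FittedModel, reduced: FittedModel) -> LrtResult:
    """LRT of nested complementary log models on the same data.

    statistic = 2 * (nll_reduced - nll_full), chi-square with df equal to
    the difference in parameter counts.
    """
    full_terms = set(full.terms)
    red_terms = set(reduced.terms)
    if not red_terms <= full_terms:
        raise ValueError(
            "reduced model is not nested in the full model: extra terms "
            f"{sorted(red_terms - full_terms)}"
        )
    if (full.n_total, full.cases_total) != (reduced.n_total, reduced.cases_total):
        raise ValueError("models were fit on different data")
    df = len(full_terms) - len(red_terms)
    stat = 2.0 * (reduced.nll - full.nll)
    if stat < -1e-8:
        raise ValueError(
            f"negative LRT statistic {stat}: models are not nested or fits "
            "did not converge"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return LrtResult(statistic=stat, df=df, p_value=p)


def reri(
    v11: float,
    v10: float,
    v01: float,
    se: float | None = None,
    null_threshold: float = 0.0,
    alpha: float = 0.05,
) -> ReriResult:
    """RERI = v11 - v10 - v01 + 1 from ratio-scale effects (RRs or ORs).

    If ``se`` is given, a one-sided test of H0: RERI <= ``null_threshold``
    against H1: RERI > threshold is performed.  The conventional additivity
    null is 0; a threshold of 1 gives the more stringent test of the
    (1,1) interaction class specifically.
    """
    for name, v in (("v11", v11), ("v10", v10), ("v01", v01)):
        if v <= 0.0:
            raise ValueError(f"{name} must be a positive ratio; got {v}")
    value = v11 - v10 - v01 + 1.0
    z = p = None
    if se is not None:
        if se <= 0.0:
            raise ValueError(f"se must be positive; got {se}")
        z = (value - null_threshold) / se
        p = float(stats.norm.sf(z))
    return ReriResult(reri=value, se=se, null_threshold=null_threshold, z=z, p_value=p)


def gamma_from_beta(model: FittedModel) -> GammaResult:
    """Rare-disease mapping gamma_i = beta_i / beta_0 (excess odds ratios).

    Requires beta0 > 0; a non-positive fitted intercept means the baseline
    log peril is not a valid (rare) risk and the odds approximation fails.
    """
    beta0 = float(model.params.iloc[0])
    if model.params.index[0] != "Intercept":
        raise ValueError("model has no leading intercept term")
    if beta0 <= 0.0:
        raise ValueError(
            f"intercept {beta0:.6g} <= 0: rare-disease odds approximation "
            "requires a positive baseline log peril"
        )
    gamma = {
        term: float(model.params[term]) / beta0
        for term in model.params.index[1:]
    }
    return GammaResult(gamma=gamma, beta0=beta0)
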