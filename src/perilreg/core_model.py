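"""Peril transforms and the sufficient-cause algebra for two binary exposures.

The sufficient-component cause ("causal pie") model for two binary exposures
X and Z admits nine classes of sufficient causes: one all-unknown class (U1),
two X-only classes (U2 requires X=1, U3 requires X=0), two Z-only classes
(U4 requires Z=1, U5 requires Z=0), and four interaction classes requiring a
specific joint state of both exposures (U6 = (1,1), U7 = (1,0), U8 = (0,1),
U9 = (0,0)).

Each class i carries a *completion risk* r_i — the probability that its
unknown complement is completed during follow-up — and a *completion peril*
Q_i = 1/(1 - r_i) >= 1.  Under the no-redundancy assumption (operationalised
here as mutually independent class completions) the log disease peril of an
exposure cell is the sum of the log completion perils of the four classes
applicable to that cell, which is exactly a linear model on the
complementary-log scale g(mu) = -log(1 - mu).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CLASS_IDS",
    "PROFILES",
    "ExposureProfile",
    "SufficientCauseSpec",
    "CellRiskSet",
    "TrueBetas",
    "risk_to_peril",
    "peril_to_risk",
    "log_peril",
    "risk_from_log_peril",
    "applicable_classes",
    "cell_risks_from_spec",
    "true_betas_from_spec",
    "prism_from_perils",
]

#: The nine sufficient-cause classes for two binary exposures.
CLASS_IDS: tuple[str, ...] = ("U1", "U2", "U3", "U4", "U5", "U6", "U7", "U8", "U9")

#: The four exposure cells (x, z) of the 2x2 design, in reference-first order.
PROFILES: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))

#: Class applicability: a class contributes to a cell iff its exposure
#: requirements are met there.  U1 needs nothing; U2/U3 key on X, U4/U5 on Z;
#: U6-U9 each require one specific joint state.
_APPLICABILITY: dict[tuple[int, int], frozenset[str]] = {
    (0, 0): frozenset({"U1", "U3", "U5", "U9"}),
    (1, 0): frozenset({"U1", "U2", "U5", "U7"}),
    (0, 1): frozenset({"U1", "U3", "U4", "U8"}),
    (1, 1): frozenset({"U1", "U2", "U4", "U6"}),
}

#: Risks at or above this bound are clipped (with a warning) before the
#: complementary-log transform to keep log perils finite.
_RISK_CLIP = 1.0 - 1e-12

ExposureProfile = tuple[int, int]


def _validate_risk(risk: float, *, name: str = "risk") -> float:
    risk = float(risk)
    if not (0.0 <= risk < 1.0) or math.isnan(risk):
        raise ValueError(
            f"{name} must lie in [0, 1); got {risk!r}"
        )
    return risk


def risk_to_peril(risk: float) -> float:
    """Peril of a risk: (1 - risk)^-1, from 1 (no peril) up to infinity.

    Raises
    ------
    ValueError
        If ``risk`` is outside [0, 1).
    """
    risk = _validate_risk(risk)
    return 1.0 / (1.0 - risk)


def peril_to_risk(peril: float) -> float:
    """Inverse of :func:`risk_to_peril`: risk = 1 - 1/peril."""
    peril = float(peril)
    if peril < 1.0 or math.isnan(peril):
        raise ValueError(f"peril must be >= 1; got {peril!r}")
    return 1.0 - 1.0 / peril

def log_peril(risk: float) -> float:
    """Complementary log of a risk, -log(1 - risk) = log(peril). Nonnegative."""
    risk = _validate_risk(risk)
    return -math.log1p(-risk)


def risk_from_log_peril(lp: float) -> float:
    """Inverse complementary log: risk = 1 - exp(-lp), for lp >= 0."""
    lp = float(lp)
    if lp < 0.0 or math.isnan(lp):
        raise ValueError(f"log peril must be >= 0; got {lp!r}")
    return -math.expm1(-lp)


def applicable_classes(profile: ExposureProfile) -> frozenset[str]:
    """The four sufficient-cause classes that can complete in a given cell.

    Parameters
    ----------
    profile
        Pair ``(x, z)`` with each coordinate in {0, 1}.

    Returns
    -------
    frozenset of str
        Exactly four class ids: U1, the matching X-only and Z-only classes,
        and the single interaction class keyed to this joint state.
    """
    try:
        x, z = profile
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"expected a two-binary-exposure profile (x, z); got {profile!r}"
        ) from exc
    if x not in (0, 1) or z not in (0, 1):
        raise ValueError(
            "class enumeration only supports two binary exposures; "
            f"got profile {profile!r} (multi-level designs are handled at "
            "the model-design level)"
        )
    return _APPLICABILITY[(int(x), int(z))]


@dataclass(frozen=True)
class SufficientCauseSpec:
    """Generative truth: completion risks for the nine classes U1-U9.

    Absent classes have completion risk 0 (completion peril exactly 1).

    Parameters
    ----------
    completion_risk
        Mapping from class id ("U1" ... "U9") to completion risk in [0, 1).
        Omitted classes default to 0.
    """

    completion_risk: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        risks: dict[str, float] = {}
        for cid, r in dict(self.completion_risk).items():
            if cid not in CLASS_IDS:
                raise ValueError(
                    f"unknown sufficient-cause class {cid!r}; expected one of {CLASS_IDS}"
                )
            risks[cid] = _validate_risk(r, name=f"completion risk of {cid}")
        full = {cid: risks.get(cid, 0.0) for cid in CLASS_IDS}
        object.__setattr__(self, "completion_risk", full)

    def completion_peril(self, class_id: str) -> float:
        """Completion peril Q_i = 1/(1 - r_i); exactly 1 for an absent class."""
        return risk_to_peril(self.completion_risk[class_id])

    @property
    def present_classes(self) -> frozenset[str]:
        return frozenset(c for c, r in self.completion_risk.items() if r > 0.0)

    def cell_risks(self) -> "CellRiskSet":
        return cell_risks_from_spec(self)

    def true_betas(self) -> "TrueBetas":
        return true_betas_from_spec(self)


@dataclass(frozen=True)
class CellRiskSet:
    """Disease risk per exposure cell of the 2x2 design.

    Perils and log perils are derived views; the identity
    log Peril = -log(1 - Risk) holds to numerical precision by construction.
    """

    risk: Mapping[ExposureProfile, float]

    def __post_init__(self) -> None:
        risks: dict[ExposureProfile, float] = {}
        for profile in PROFILES:
            if profile not in self.risk:
                raise ValueError(f"missing risk for cell {profile}")
            r = float(self.risk[profile])
            if not 0.0 <= r <= 1.0 or math.isnan(r):
                raise ValueError(f"risk of cell {profile} must lie in [0, 1]; got {r!r}")
            if r >= _RISK_CLIP:
                warnings.warn(
                    f"risk {r} of cell {profile} clipped to {_RISK_CLIP} before "
                    "the complementary-log transform",
                    RuntimeWarning,
                    stacklevel=3,
                )
                r = _RISK_CLIP
            risks[profile] = r
        object.__setattr__(self, "risk", risks)

    def peril(self, profile: ExposureProfile) -> float:
        return risk_to_peril(self.risk[tuple(profile)])

    def log_peril(self, profile: ExposureProfile) -> float:
        return log_peril(self.risk[tuple(profile)])

    def prism(self) -> float:
        return prism_from_perils(self)

    def true_betas(self) -> "TrueBetas":
        lp = {p: self.log_peril(p) for p in PROFILES}
        return TrueBetas(
            beta0=lp[(0, 0)],
            beta1=lp[(1, 0)] - lp[(0, 0)],
            beta2=lp[(0, 1)] - lp[(0, 0)],
            beta3=lp[(1, 1)] - lp[(1, 0)] - lp[(0, 1)] + lp[(0, 0)],
        )


@dataclass(frozen=True)
class TrueBetas:
    """Coefficients of the saturated complementary log model on the 2x2 cells.

    beta0 is the log peril of the reference cell (so exp(-beta0) is the
    reference group's survival probability); beta1 and beta2 are log peril
    ratios for X and Z; beta3 is log PRISM, the cross-ratio of perils.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    @property
    def prism(self) -> float:
        return math.exp(self.beta3)


def cell_risks_from_spec(spec: SufficientCauseSpec) -> CellRiskSet:
    """Cell risks induced by independent completion of the applicable classes.

    For each cell the survival probability is the product of (1 - r_i) over
    the four applicable classes — equivalently the log peril is the sum of
    the four log completion perils.
    """
    risks: dict[ExposureProfile, float] = {}
    for profile in PROFILES:
        survival = 1.0
        for cid in applicable_classes(profile):
            survival *= 1.0 - spec.completion_risk[cid]
        risks[profile] = 1.0 - survival
    return CellRiskSet(risk=risks)


def true_betas_from_spec(spec: SufficientCauseSpec) -> TrueBetas:
    """Saturated-model coefficients implied by a generative spec.

    Computed directly from the log completion perils, so absent classes
    contribute exactly 0: beta3 = log Q6 + log Q9 - log Q7 - log Q8 depends
    only on the interaction classes and is exactly 0 when they are absent.
    Agrees with the cell-contrast route ``cell_risks_from_spec(spec)
    .true_betas()`` to numerical precision.
    """
    q = {cid: log_peril(spec.completion_risk[cid]) for cid in CLASS_IDS}
    return TrueBetas(
        beta0=q["U1"] + q["U3"] + q["U5"] + q["U9"],
        beta1=q["U2"] + q["U7"] - q["U3"] - q["U9"],
        beta2=q["U4"] + q["U8"] - q["U5"] - q["U9"],
        beta3=q["U6"] + q["U9"] - q["U7"] - q["U8"],
    )


def prism_from_perils(cells: CellRiskSet) -> float:
    """Peril Ratio Index of Synergy based on Multiplicativity.

    PRISM = Peril(1,1) * Peril(0,0) / (Peril(1,0) * Peril(0,1)).  A value
    different from 1 implies at least one interaction class U6-U9 is present.
    """
    for profile in PROFILES:
        if cells.risk[profile] >= 1.0:
            raise ValueError(f"cell {profile} has risk 1: infinite peril, PRISM undefined")
    return (
        cells.peril((1, 1))
        * cells.peril((0, 0))
        / (cells.peril((1, 0)) * cells.peril((0, 1)))
    )
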