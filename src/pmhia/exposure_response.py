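"""Non-linear exposure-response functions for long-term PM2.5 mortality.

Two families are supported:

* **GEMM** (Global Exposure Mortality Model) — log-linear hazard in
  ``log(1 + z/alpha)`` with a logistic weight::

      RR(z) = exp( theta * log(1 + z/alpha) * w(z) ),
      w(z)  = 1 / (1 + exp(-(z - mu)/nu)),
      z     = max(0, C - zcf)

  where ``C`` is the annual-mean PM2.5 concentration (ug m-3) and ``zcf``
  the counterfactual concentration below which no excess risk is
  attributed (2.4 ug m-3, the lowest observed cohort concentration in the
  GEMM cohort pool; configurable per parameter row).

* **IER** (Integrated Exposure-Response, as used by the Global Burden of
  Disease) — a saturating form::

      RR(z) = 1 + a * (1 - exp(-g * z**d))

  whose shape constants ``(a, g, d)`` are stored in the ``(alpha, mu, nu)``
  parameter slots with family-specific interpretation.

The 95% confidence interval is propagated through the log-hazard slope only:
low/high use ``theta -/+ 1.96 * theta_se``.  Shape parameters carry no
sampled uncertainty, matching how the GEMM literature reports 95% CIs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import AGE_BANDS, ALL_AGES
from .errors import CoverageError, ValidationError
from .grid_io import read_table

Z_CRIT = 1.96  # two-sided 95% normal quantile


class Family(str, enum.Enum):
    GEMM = "GEMM"
    IER = "IER"


class Endpoint(str, enum.Enum):
    """Cause-of-death categories with exposure-response parameters.

    ``NCD_LRI`` is the non-accidental envelope (all non-communicable
    diseases plus lower respiratory infections); the five specific causes
    are subtracted from it to derive "other NCD" downstream.
    """

    NCD_LRI = "NCD_LRI"
    IHD = "IHD"
    CEV = "CEV"
    COPD = "COPD"
    LC = "LC"
    LRI = "LRI"


#: the five specific causes subtracted from NCD_LRI to get other-NCD
SPECIFIC_CAUSES: tuple[Endpoint, ...] = (
    Endpoint.IHD,
    Endpoint.CEV,
    Endpoint.COPD,
    Endpoint.LC,
    Endpoint.LRI,
)


@dataclass(frozen=True)
class RRParams:
    """One exposure-response parameter row.

    For ``family == IER`` the slots (alpha, mu, nu) carry the IER shape
    constants (a, gamma, delta).
    """

    family: Family
    endpoint: Endpoint
    age_group: str
    theta: float
    theta_se: float
    alpha: float
    mu: float
    nu: float
    zcf: float

    def __post_init__(self) -> None:
        if self.family == Family.GEMM and self.alpha <= 0:
            raise ValidationError("GEMM alpha must be positive")
        if self.family == Family.GEMM and self.nu <= 0:
            raise ValidationError("GEMM nu must be positive")
        if self.theta_se < 0:
            raise ValidationError("theta_se must be non-negative")
        if self.zcf < 0:
            raise ValidationError("zcf must be non-negative")
        if self.age_group != ALL_AGES and self.age_group not in AGE_BANDS:
            raise ValidationError(f"unknown age group {self.age_group!r}")


@dataclass(frozen=True)
class RRValue:
    """Central estimate and 95% CI bounds of a risk ratio.

    Components may be scalars or arrays (evaluated over a concentration
    field); the ordering low <= central <= high holds elementwise.
    """

    central: np.ndarray | float
    low: np.ndarray | float
    high: np.ndarray | float

    def __post_init__(self) -> None:
        c, lo, hi = (np.asarray(x, dtype=float) for x in (self.central, self.low, self.high))
        if np.any(lo > c + 1e-15) or np.any(c > hi + 1e-15):
            raise ValidationError("RR confidence bounds are not ordered low <= central <= high")
        if np.any(lo < 0):
            raise ValidationError("RR components must be non-negative")

    def triple(self) -> tuple[np.ndarray | float, np.ndarray | float, np.ndarray | float]:
        return self.central, self.low, self.high


def _excess_exposure(concentration, zcf: float) -> np.ndarray:
    c = np.asarray(concentration, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValidationError("concentration must be finite")
    if np.any(c < 0):
        raise ValidationError("concentration must be non-negative")
    return np.maximum(0.0, c - zcf)


def _gemm_core(z: np.ndarray, theta: float, alpha: float, mu: float, nu: float) -> np.ndarray:
    # log(1 + z/alpha) is exactly 0 at z = 0, so RR(zcf) == 1 identically
    omega = 1.0 / (1.0 + np.exp(-(z - mu) / nu))
    return np.exp(theta * np.log1p(z / alpha) * omega)


def gemm_rr(concentration, params: RRParams, reject_protective: bool = True) -> RRValue:
    """Evaluate the GEMM risk ratio at one or many concentrations.

    Central uses ``theta``; low/high use ``theta -/+ 1.96 * theta_se``.
    Returns exactly 1 (all three components) at or below the counterfactual.
    With ``reject_protective`` (default) a central RR below 1 — impossible
    for theta > 0 — raises :class:`ValidationError`.
    """
    if params.family != Family.GEMM:
        raise ValidationError("gemm_rr requires GEMM-family parameters")
    z = _excess_exposure(concentration, params.zcf)
    central = _gemm_core(z, params.theta, params.alpha, params.mu, params.nu)
    low = _gemm_core(z, params.theta - Z_CRIT * params.theta_se, params.alpha, params.mu, params.nu)
    high = _gemm_core(z, params.theta + Z_CRIT * params.theta_se, params.alpha, params.mu, params.nu)
    if reject_protective and np.any(np.asarray(central) < 1.0):
        raise ValidationError("central GEMM RR fell below 1; check theta sign")
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return RRValue(float(central), float(low), float(high))
    return RRValue(central, low, high)


def ier_rr(concentration, params: RRParams) -> RRValue:
    """Evaluate the IER risk ratio; shape constants live in (alpha, mu, nu).

    The stored table carries no CI columns for the shape constants, so the
    central estimate is replicated into the bounds.
    """
    if params.family != Family.IER:
        raise ValidationError("ier_rr requires IER-family parameters")
    a, gamma, delta = params.alpha, params.mu, params.nu
    z = _excess_exposure(concentration, params.zcf)
    with np.errstate(invalid="ignore"):
        central = 1.0 + a * (1.0 - np.exp(-gamma * np.power(z, delta)))
    central = np.where(z == 0.0, 1.0, central)
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        c = float(central)
        return RRValue(c, c, c)
    return RRValue(central, central.copy(), central.copy())


def attributable_fraction(rr: RRValue, allow_protective: bool = False):
    """Population attributable fraction ``AF = (RR - 1) / RR`` per component.

    AF lies in [0, 1) for RR >= 1 and is strictly increasing in RR.  RR
    components below 1 (protective) are rejected unless explicitly allowed,
    in which case the AF is negative.
    """
    out = []
    for comp in rr.triple():
        arr = np.asarray(comp, dtype=float)
        if np.any(arr == 0):
            raise ValidationError("RR component of 0 has no attributable fraction")
        if not allow_protective and np.any(arr < 1.0):
            raise ValidationError("RR component below 1; pass allow_protective=True to accept")
        af = (arr - 1.0) / arr
        out.append(float(af) if arr.ndim == 0 else af)
    return tuple(out)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

#: endpoints whose RR must be age-resolved (hazard declines with log age)
AGE_SPECIFIC_REQUIRED: tuple[Endpoint, ...] = (Endpoint.IHD, Endpoint.CEV)


class ParamSet:
    """Parameter rows for one family, keyed by (endpoint, age_group).

    ``lookup(endpoint, age)`` falls back to the ALL_AGES row when no
    band-specific row exists, so age-constant endpoints (COPD, LC, LRI) are
    served by a single row.
    """

    def __init__(self, rows: list[RRParams]):
        self.family = rows[0].family if rows else None
        self._rows: dict[tuple[Endpoint, str], RRParams] = {}
        for row in rows:
            key = (row.endpoint, row.age_group)
            if key in self._rows:
                raise ValidationError(f"duplicated parameter row {key}")
            if row.family != self.family:
                raise ValidationError("mixed families in one parameter set")
            self._rows[key] = row
        self._check_complete()

    def _check_complete(self) -> None:
        for endpoint in Endpoint:
            has_all = (endpoint, ALL_AGES) in self._rows
            bands = [b for b in AGE_BANDS if (endpoint, b) in self._rows]
            if not has_all and len(bands) != len(AGE_BANDS):
                raise CoverageError(
                    f"endpoint {endpoint.value} covered by neither ALL_AGES "
                    f"nor a full 5-year-band set"
                )
            if endpoint in AGE_SPECIFIC_REQUIRED and len(bands) != len(AGE_BANDS):
                raise CoverageError(
                    f"endpoint {endpoint.value} requires age-specific rows"
                )

    def lookup(self, endpoint: Endpoint | str, age_group: str) -> RRParams:
        endpoint = Endpoint(endpoint)
        row = self._rows.get((endpoint, age_group))
        if row is None:
            row = self._rows.get((endpoint, ALL_AGES))
        if row is None:
            raise CoverageError(f"no parameters for ({endpoint.value}, {age_group})")
        return row

    def rows(self) -> list[RRParams]:
        return list(self._rows.values())

    def evaluate(self, concentration, endpoint: Endpoint | str, age_group: str) -> RRValue:
        """Dispatch to the family's RR function."""
        p = self.lookup(endpoint, age_group)
        if p.family == Family.GEMM:
            return gemm_rr(concentration, p)
        return ier_rr(concentration, p)


def load_rr_params(family: Family | str = Family.GEMM, source: str | Path | None = None) -> ParamSet:
    """Load a risk-function parameter table and check endpoint/age coverage.

    ``source=None`` loads the packaged default table for the family (GEMM
    constants ship with the package).
    """
    family = Family(family)
    if source is None:
        if family != Family.GEMM:
            raise CoverageError("only the GEMM family ships a packaged default table")
        source = resources.files("pmhia.data") / "gemm_params.csv"
    df = read_table(source, "rr_params")
    rows = [
        RRParams(
            family=Family(r.family),
            endpoint=Endpoint(r.endpoint),
            age_group=str(r.age_group),
            theta=float(r.theta),
            theta_se=float(r.theta_se),
            alpha=float(r.alpha),
            mu=float(r.mu),
            nu=float(r.nu),
            zcf=float(r.zcf),
        )
        for r in df.itertuples(index=False)
        if Family(r.family) == family
    ]
    if not rows:
        raise CoverageError(f"no {family.value} rows in {source}")
    return ParamSet(rows)
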