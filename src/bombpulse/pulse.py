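"""The parametric bomb-pulse curve relating percent modern carbon to year.

The mid/late-1950s atmospheric nuclear tests produced a sharp rise ("bomb
pulse") in radiocarbon that entered North Atlantic surface waters around
1958 and, through diet, the growth layers of marine mammals.  The five-
parameter curve used here is a logistic rise modulated by a slow exponential
decay:

    pMC(year) = a + b * exp((c - year)/d2) / (1 + exp((c - year)/d1))

with baseline ``a`` (pre-pulse pMC), amplitude scale ``b``, half-rise year
``c``, rise timescale ``d1`` and decay timescale ``d2 >> d1``.  Dropping the
decay term gives the four-parameter sigmoid

    pMC(year) = a + (b - a) / (1 + exp((c - year)/d1))

where ``b`` is the post-pulse asymptote (so the increment is ``b - a``).

For the five-parameter curve the maximum has closed form: it occurs in year
``c + d1*ln(d2/d1 - 1)`` with value ``a + b*(d1/d2)*(d2/d1 - 1)**(1 - d1/d2)``.
Only the fast rising limb (pre-peak) gives nearly unambiguous dates; the
falling limb decays far more slowly than typical measurement error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "FIVE_PARAM",
    "FOUR_PARAM",
    "PulseParams",
    "PeakPoint",
    "pmc_at",
    "peak_point",
    "inverse_rising",
    "inverse_falling",
    "ALL_SPECIES_PARAMS",
    "NARWHAL_PARAMS",
]

FIVE_PARAM = "five_param"
FOUR_PARAM = "four_param"


@dataclass(frozen=True)
class PulseParams:
    """Parameters of the bomb-pulse curve.

    ``variant`` selects the algebra: ``"five_param"`` (rise + slow decay,
    needs ``d2``) or ``"four_param"`` (pure sigmoid, ``d2`` unused and ``b``
    is the upper asymptote).
    """

    a: float
    b: float
    c: float
    d1: float
    d2: float | None = None
    variant: str = FIVE_PARAM

    def __post_init__(self) -> None:
        if self.variant not in (FIVE_PARAM, FOUR_PARAM):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (self.d1 > 0):
            raise ValueError(f"d1 must be > 0, got {self.d1}")
        if self.variant == FIVE_PARAM:
            if self.d2 is None:
                raise ValueError("five_param variant requires d2")
            if not (self.d2 > self.d1):
                raise ValueError(
                    f"five_param requires d2 > d1 (timescale separation); "
                    f"got d1={self.d1}, d2={self.d2}"
                )
            if not (self.b > 0):
                raise ValueError(f"five_param requires amplitude b > 0, got {self.b}")
        else:
            if not (self.b > self.a):
                raise ValueError(
                    f"four_param requires asymptote b > baseline a; "
                    f"got a={self.a}, b={self.b}"
                )

    @classmethod
    def five(cls, a: float, b: float, c: float, d1: float, d2: float) -> "PulseParams":
        return cls(a=a, b=b, c=c, d1=d1, d2=d2, variant=FIVE_PARAM)

    @classmethod
    def four(cls, a: float, b: float, c: float, d1: float) -> "PulseParams":
        return cls(a=a, b=b, c=c, d1=d1, d2=None, variant=FOUR_PARAM)

    @property
    def free_names(self) -> tuple[str, ...]:
        return ("a", "b", "c", "d1", "d2")[: self.n_free]

    @property
    def n_free(self) -> int:
        return 5 if self.variant == FIVE_PARAM else 4

    def to_array(self) -> np.ndarray:
        vals = [self.a, self.b, self.c, self.d1]
        if self.variant == FIVE_PARAM:
            vals.append(self.d2)
        return np.asarray(vals, dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray, variant: str) -> "PulseParams":
        theta = np.asarray(theta, dtype=float)
        if variant == FIVE_PARAM:
            return cls.five(*theta[:5])
        return cls.four(*theta[:4])

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {"variant": self.variant, "a": self.a, "b": self.b, "c": self.c,
                   "d1": self.d1, "d2": self.d2}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "PulseParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(a=d["a"], b=d["b"], c=d["c"], d1=d["d1"], d2=d.get("d2"),
                   variant=d["variant"])


@dataclass(frozen=True)
class PeakPoint:
    """Year and value of the curve maximum (five-parameter variant)."""

    year: float
    pmc: float


def pmc_at(params: PulseParams, year) -> np.ndarray | float:
    """Evaluate the pulse curve at one or many calendar years.

    Numerically stable for years far before ``c``: the logistic factor is
    evaluated through ``expit``/``logaddexp`` so the exponentials never
    overflow.
    """
    yr = np.asarray(year, dtype=float)
    u = (params.c - yr) / params.d1
    if params.variant == FOUR_PARAM:
        out = params.a + (params.b - params.a) * expit(-u)
    else:
        # b*exp(v/d2)/(1+exp(v/d1)) in log space: log b + v/d2 - log(1+e^u)
        v = params.c - yr
        log_term = math.log(params.b) + v / params.d2 - np.logaddexp(0.0, u)
        out = params.a + np.exp(log_term)
    if np.isscalar(year):
        return float(out)
    return out


def peak_point(params: PulseParams) -> PeakPoint:
    """Closed-form maximum of the five-parameter curve.

    year* = c + d1*ln(d2/d1 - 1);  pMC* = a + b*(d1/d2)*(d2/d1 - 1)**(1 - d1/d2).
    Requires d2/d1 > 1 for the logarithm (guaranteed by the parameter
    invariant d2 > d1; d2/d1 = 2 puts the peak exactly at c).
    """
    if params.variant != FIVE_PARAM:
        raise ValueError("peak_point is defined for the five-parameter variant only")
    ratio = params.d2 / params.d1
    if ratio <= 1.0:
        raise ValueError(f"peak formula requires d2/d1 > 1, got {ratio:.3g}")
    year = params.c + params.d1 * math.log(ratio - 1.0)
    pmc = params.a + params.b * (1.0 / ratio) * (ratio - 1.0) ** (1.0 - 1.0 / ratio)
    return PeakPoint(year=year, pmc=pmc)


def _rising_bracket(params: PulseParams) -> tuple[float, float]:
    lo = params.c - 60.0 * params.d1
    if params.variant == FIVE_PARAM:
        hi = peak_point(params).year
    else:
        hi = params.c + 60.0 * params.d1
    return lo, hi


def inverse_rising(params: PulseParams, pmc: float, tol: float = 1e-8) -> float:
    """Year on the rising limb at which the curve attains ``pmc``.

    The rising limb is monotone, so the root is unique; bracketed bisection
    (Brent) is used to ``tol`` years.  Raises ValueError when ``pmc`` lies
    outside the open interval attainable on the limb (at or below the
    pre-pulse plateau, or at/above the peak / asymptote).
    """
    lo, hi = _rising_bracket(params)
    f_lo, f_hi = pmc_at(params, lo), pmc_at(params, hi)
    if not (f_lo < pmc < f_hi):
        raise ValueError(
            f"pMC {pmc:.3f} not datable on the rising limb; attainable open "
            f"interval is ({f_lo:.3f}, {f_hi:.3f})"
        )
    return float(brentq(lambda y: pmc_at(params, y) - pmc, lo, hi, xtol=tol))


def inverse_falling(params: PulseParams, pmc: float, tol: float = 1e-8) -> float:
    """Year on the falling (post-peak) limb at which the curve attains ``pmc``.

    Ambiguous-limb counterpart of :func:`inverse_rising`: post-peak decay is
    slow relative to measurement error, so falling-limb dates carry large
    uncertainty and are not used by default.
    """
    if params.variant != FIVE_PARAM:
        raise ValueError("the four-parameter sigmoid has no falling limb")
    pk = peak_point(params)
    lo, hi = pk.year, pk.year + 20.0 * params.d2
    f_lo, f_hi = pmc_at(params, lo), pmc_at(params, hi)
    if not (f_hi < pmc < f_lo):
        raise ValueError(
            f"pMC {pmc:.3f} not datable on the falling limb; attainable open "
            f"interval is ({f_hi:.3f}, {f_lo:.3f})"
        )
    return float(brentq(lambda y: pmc_at(params, y) - pmc, lo, hi, xtol=tol))


#: Published point estimates for the all-species five-parameter fit
#: (narwhal + beluga + humpback + fin whale), used as the default truth of
#: the synthetic-data generator.
ALL_SPECIES_PARAMS = PulseParams.five(a=92.2, b=12.9, c=1965.0, d1=6.4, d2=218.2)

#: Published four-parameter (no-decay sigmoid) point estimates for the
#: narwhal-only fit, where the five-parameter model does not converge.
NARWHAL_PARAMS = PulseParams.four(a=92.6, b=103.3, c=1960.0, d1=4.5)
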