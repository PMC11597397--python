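"""Growth-layer chronologies, bomb-onset classification, ages and dating.

Under annual GLG deposition a layer series is a linear calendar: anchoring
one layer to one calendar year dates every other layer.  Tooth chronologies
anchor the prenatal tip (layer 0) at the birth year; tusk chronologies with
broken tips anchor the first preserved GLG at its inferred deposition year.

The 95 pMC threshold separates dentine formed before the bomb pulse reached
North Atlantic surface waters (1958) from dentine formed after; values
straddling the threshold within measurement uncertainty mark layers laid
down around the onset itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .core import Specimen
from .fitting import FitResult
from .pulse import FIVE_PARAM, inverse_falling, inverse_rising, peak_point

__all__ = [
    "BOMB_THRESHOLD_PMC",
    "BOMB_ONSET_YEAR",
    "BombLabel",
    "BombClass",
    "Chronology",
    "AgeEstimate",
    "DatingResult",
    "classify_bomb",
    "build_chronology",
    "estimate_age",
    "date_sample",
]

#: pMC threshold separating pre- from post-bomb-pulse dentine.
BOMB_THRESHOLD_PMC = 95.0
#: First year the pulse was registered in North Atlantic chronologies.
BOMB_ONSET_YEAR = 1958


class BombLabel(str, Enum):
    PRE_BOMB = "pre_bomb"
    AT_THRESHOLD = "at_threshold"
    POST_ONSET = "post_onset"


@dataclass(frozen=True)
class BombClass:
    label: BombLabel
    threshold: float = BOMB_THRESHOLD_PMC


def classify_bomb(
    pmc: float,
    pmc_sd: float,
    threshold: float = BOMB_THRESHOLD_PMC,
    uncertainty_aware: bool = True,
) -> BombClass:
    """Classify a measurement against the bomb-onset threshold.

    With ``uncertainty_aware`` (default) a 2-sigma buffer is applied:
    pre-bomb only if pmc + 2 sd < threshold, post-onset only if
    pmc - 2 sd > threshold, otherwise at-threshold (deposited around the
    pulse onset).  ``uncertainty_aware=False`` applies the bare cut, with
    exact equality mapped to at-threshold.
    """
    if not (pmc > 0 and pmc_sd > 0):
        raise ValueError("pmc and pmc_sd must be positive")
    if uncertainty_aware:
        if pmc + 2.0 * pmc_sd < threshold:
            label = BombLabel.PRE_BOMB
        elif pmc - 2.0 * pmc_sd > threshold:
            label = BombLabel.POST_ONSET
        else:
            label = BombLabel.AT_THRESHOLD
    else:
        if pmc < threshold:
            label = BombLabel.PRE_BOMB
        elif pmc > threshold:
            label = BombLabel.POST_ONSET
        else:
            label = BombLabel.AT_THRESHOLD
    return BombClass(label=label, threshold=threshold)


@dataclass(frozen=True)
class Chronology:
    """Linear layer-to-year mapping: year(layer) = anchor_year + (layer - anchor_layer)."""

    specimen_id: str
    anchor_layer: int
    anchor_year: float

    def year_of(self, layer_index: int) -> float:
        return self.anchor_year + (layer_index - self.anchor_layer)

    def layer_of(self, year: float) -> float:
        return self.anchor_layer + (year - self.anchor_year)


def build_chronology(
    specimen: Specimen, anchor_layer: int, anchor_year: float
) -> Chronology:
    """Anchor one layer of a specimen to a calendar year.

    The anchor must be consistent with the specimen: the year of the last
    sampled layer under the mapping may not fall after the year of death.
    """
    chron = Chronology(specimen.specimen_id, anchor_layer, anchor_year)
    if specimen.year_of_death is not None and specimen.samples:
        last = max(s.layer_index for s in specimen.samples)
        if chron.year_of(last) > specimen.year_of_death:
            raise ValueError(
                f"anchor ({anchor_layer} -> {anchor_year}) puts layer {last} at "
                f"{chron.year_of(last):.0f}, after death in {specimen.year_of_death:.0f}"
            )
    return chron


@dataclass(frozen=True)
class AgeEstimate:
    """Birth-year and age-at-death intervals for a specimen."""

    specimen_id: str
    birth_year: tuple[float, float]  # (earliest, latest)
    age_at_death: tuple[float, float]  # (lo, hi)
    basis: str = "radiocarbon_anchor"

    @property
    def max_age(self) -> float:
        return self.age_at_death[1]

    @property
    def min_age(self) -> float:
        return self.age_at_death[0]


def estimate_age(
    year_of_death: float,
    first_layer_year: float,
    layers_missing: tuple[int, int] = (0, 0),
    specimen_id: str = "",
    basis: str = "radiocarbon_anchor",
) -> AgeEstimate:
    """Age at death from a dated first preserved layer plus missing-tip GLGs.

    The first preserved layer was laid down at age ``layers_missing`` (one
    lost GLG = one year of life before the preserved record), so

        age = (year_of_death - first_layer_year) + [lo, hi]
        birth = first_layer_year - [hi, lo]

    A complete tooth with its prenatal tip present has ``layers_missing =
    (0, 0)`` and the first layer year *is* the birth year.
    """
    lo, hi = layers_missing
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid layers_missing interval [{lo}, {hi}]")
    if first_layer_year > year_of_death:
        raise ValueError("first_layer_year is after year_of_death")
    span = year_of_death - first_layer_year
    return AgeEstimate(
        specimen_id=specimen_id,
        birth_year=(first_layer_year - hi, first_layer_year - lo),
        age_at_death=(span + lo, span + hi),
        basis=basis,
    )


@dataclass(frozen=True)
class DatingResult:
    """Candidate deposition year(s) for a pMC value under a fitted curve."""

    pmc: float
    pmc_sd: float
    limb: str
    year: Optional[float]  # point estimate on the requested limb
    year_interval: Optional[tuple[float, float]]
    candidates: tuple[float, ...] = ()
    status: str = "ok"  # "ok" | "undatable_pre_bomb"
    ambiguous: bool = False


def _invert_interval(params, pmc, sd, limb: str) -> tuple[float, float]:
    """Propagate pmc +/- 2 sd through the chosen inverse branch, clipping
    the endpoints into the attainable range of the limb."""
    inv = inverse_rising if limb == "rising" else inverse_falling
    vals = []
    for p in (pmc - 2.0 * sd, pmc, pmc + 2.0 * sd):
        try:
            vals.append(inv(params, p))
        except ValueError:
            pass  # endpoint beyond plateau or peak: interval is open there
    if not vals:
        raise ValueError("no branch value attainable")
    return min(vals), max(vals)


def date_sample(
    pmc: float,
    pmc_sd: float,
    fit: FitResult,
    limb: str = "rising",
) -> DatingResult:
    """Date a radiocarbon measurement by inverting the fitted pulse curve.

    Only the rising limb gives (nearly) unambiguous calendar dates; with
    ``limb="both"`` the falling-limb candidate is also returned and the
    result flagged ambiguous.  Year uncertainty combines the measurement
    interval pmc +/- 2 sd propagated through the inverse with the spread of
    the bootstrap parameter draws (when the fit carries them).

    Values at or below the pre-bomb baseline plateau are undatable (any
    pre-1958 year is consistent); values above the fitted maximum admit no
    solution and raise ValueError.
    """
    if limb not in ("rising", "falling", "both"):
        raise ValueError(f"limb must be rising/falling/both, got {limb!r}")
    if not fit.converged:
        raise ValueError("date_sample requires a converged fit")
    params = fit.params
    if params.variant == FIVE_PARAM:
        top = peak_point(params).pmc
    else:
        top = params.b
    if pmc >= top:
        raise ValueError(
            f"pMC {pmc} is at or above the fitted maximum {top:.2f}; no year "
            f"on the curve attains it"
        )
    if pmc <= params.a:  # indistinguishable from the pre-pulse plateau
        return DatingResult(pmc=pmc, pmc_sd=pmc_sd, limb=limb, year=None,
                            year_interval=None, status="undatable_pre_bomb")

    primary_limb = "falling" if limb == "falling" else "rising"
    inv = inverse_rising if primary_limb == "rising" else inverse_falling
    year = inv(params, pmc)
    lo, hi = _invert_interval(params, pmc, pmc_sd, primary_limb)

    # widen with bootstrap parameter uncertainty when available
    if fit.boot_params is not None and len(fit.boot_params):
        from .fitting import _to_params

        boot_years = []
        for theta in fit.boot_params:
            try:
                boot_years.append(inv(_to_params(theta, fit.variant), pmc))
            except ValueError:
                continue
        if boot_years:
            b_lo, b_hi = np.quantile(boot_years, [0.025, 0.975])
            lo, hi = min(lo, float(b_lo)), max(hi, float(b_hi))

    candidates = [year]
    ambiguous = False
    if limb == "both" and params.variant == FIVE_PARAM:
        try:
            candidates.append(inverse_falling(params, pmc))
            ambiguous = True
        except ValueError:
            pass
    return DatingResult(
        pmc=pmc,
        pmc_sd=pmc_sd,
        limb=limb,
        year=year,
        year_interval=(lo, hi),
        candidates=tuple(candidates),
        status="ok",
        ambiguous=ambiguous or limb == "falling",
    )
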