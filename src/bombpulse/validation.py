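"""Leave-one-out validation of the dating model.

One individual (all of its layer samples) is held out at a time; the pulse
curve is refitted to everyone else; each of the held-out individual's
*eligible* measurements — pMC strictly between the 95 pMC bomb-onset
threshold and the maximum of the refitted curve, i.e. values that sit on
the informative rising limb — is inverted to a predicted deposition year
and converted to a birth-year estimate through its layer index (annual
deposition); the per-measurement estimates are aggregated per individual
and compared with the known birth year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chronology import BOMB_THRESHOLD_PMC
from .core import Dataset, Specimen
from .fitting import DEFAULT_SEED, FitResult, fit_pulse
from .pulse import FIVE_PARAM, FOUR_PARAM, inverse_rising, peak_point

__all__ = ["LooRecord", "LooResult", "loo_validate", "true_birth_year"]


def true_birth_year(sp: Specimen) -> Optional[float]:
    """Birth year implied by the specimen's own chronology (annual layers).

    Every dated layer k was deposited in year birth + k, so birth is
    year - layer_index; the minimum over samples guards against rounding.
    """
    vals = [s.year - s.layer_index for s in sp.samples if s.year is not None]
    return min(vals) if vals else None


@dataclass(frozen=True)
class LooRecord:
    specimen_id: str
    true_birth_year: Optional[float]
    predicted_birth_year: Optional[float]
    error: Optional[float]  # predicted - true, years (signed)
    n_eligible: int
    eligible: bool
    note: str = ""


@dataclass(frozen=True)
class LooResult:
    """Per-individual predictions and signed-error summary.

    ``summary`` holds mean/median of the signed errors, their standard
    deviation (``sd_error``), the standard error of the mean and the number
    of eligible individuals.  Individuals with no eligible measurement are
    listed with ``eligible=False`` and excluded from the summary.
    """

    records: tuple[LooRecord, ...]
    summary: dict
    variant: str
    eligibility: str = (
        f"at least one pMC value strictly between {BOMB_THRESHOLD_PMC} and "
        f"the maximum of the refitted curve"
    )

    @property
    def errors(self) -> np.ndarray:
        return np.array([r.error for r in self.records if r.eligible])


def _fitted_max(fit: FitResult) -> float:
    if fit.variant == FIVE_PARAM:
        return peak_point(fit.params).pmc
    return fit.params.b


def loo_validate(
    ds: Dataset,
    variant: str = FIVE_PARAM,
    seed: int = DEFAULT_SEED,
    aggregate: str = "mean",
    threshold: float = BOMB_THRESHOLD_PMC,
    n_starts: int = 10,
) -> LooResult:
    """Leave-one-individual-out age-prediction validation.

    Parameters
    ----------
    ds : Dataset
        Individuals with dated layer series (true birth years are implied
        by their own chronologies).
    variant : {"five_param", "four_param"}
        Curve variant for the refits.  A five-parameter refit whose decay
        timescale is not identified falls back to the four-parameter
        sigmoid, mirroring the treatment of rise-only data.
    aggregate : {"mean", "inverse_variance"}
        How per-measurement birth-year estimates are combined within an
        individual (unweighted mean by default; 1/sd^2 weights optional).
    seed : int
        Passed to the multi-start of every refit; the whole procedure is
        deterministic given the seed.

    Folds are independent: each refit sees exactly the other individuals'
    samples, so removing one individual never changes another's prediction.
    """
    if len(ds) < 3:
        raise ValueError("leave-one-out needs at least 3 individuals")
    if aggregate not in ("mean", "inverse_variance"):
        raise ValueError(f"unknown aggregate {aggregate!r}")

    records = []
    for held in ds:
        rest = [
            (s.year, s.pmc, s.pmc_sd)
            for sp in ds
            if sp.specimen_id != held.specimen_id
            for s in sp.samples
            if s.year is not None
        ]
        fit = fit_pulse(rest, variant=variant, seed=seed, n_starts=n_starts)
        note = ""
        if not fit.converged and variant == FIVE_PARAM:
            fit = fit_pulse(rest, variant=FOUR_PARAM, seed=seed, n_starts=n_starts)
            note = "five-parameter refit not identified; used four-parameter sigmoid"
        top = _fitted_max(fit)
        truth = true_birth_year(held)

        births, weights = [], []
        for s in held.samples:
            if not (threshold < s.pmc < top):
                continue
            try:
                year_pred = inverse_rising(fit.params, s.pmc)
            except ValueError:
                continue
            births.append(year_pred - s.layer_index)
            weights.append(1.0 / s.pmc_sd**2)
        if births and truth is not None:
            if aggregate == "mean":
                pred = float(np.mean(births))
            else:
                pred = float(np.average(births, weights=weights))
            records.append(
                LooRecord(held.specimen_id, truth, pred, pred - truth,
                          len(births), True, note)
            )
        else:
            why = note or (
                "no measurement between threshold and fitted maximum"
                if truth is not None else "no dated layers"
            )
            records.append(
                LooRecord(held.specimen_id, truth, None, None, 0, False, why)
            )

    errors = np.array([r.error for r in records if r.eligible])
    if len(errors):
        summary = {
            "mean_error": float(np.mean(errors)),
            "median_error": float(np.median(errors)),
            "sd_error": float(np.std(errors, ddof=1)) if len(errors) > 1 else 0.0,
            "se_mean": (float(np.std(errors, ddof=1) / np.sqrt(len(errors)))
                        if len(errors) > 1 else 0.0),
            "mean_abs_error": float(np.mean(np.abs(errors))),
            "n_eligible": int(len(errors)),
        }
    else:
        summary = {"mean_error": None, "median_error": None, "sd_error": None,
                   "se_mean": None, "mean_abs_error": None, "n_eligible": 0}
    return LooResult(records=tuple(records), summary=summary, variant=variant)
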