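"""Weighted nonlinear least-squares estimation of the pulse curve.

Measurements (year_i, pmc_i, sd_i) are fitted by minimising the
inverse-variance weighted residual sum of squares

    RSS_w(theta) = sum_i w_i * (pmc_i - pMC(year_i; theta))^2,   w_i = 1/sd_i^2.

The five-parameter curve is mildly ill-conditioned — the decay timescale d2
is weakly identified whenever the post-peak decline is shallow — so the
optimiser is run from a data-driven initial guess plus a Latin-hypercube
multi-start, and the timescale separation d2 > d1 is enforced structurally
by optimising s = d2 - d1 > 0.  Data that carry no information about the
decay (the narwhal-only series) drive s to its upper bound; such fits are
reported with ``converged=False`` and the caller is expected to fall back to
the four-parameter sigmoid.

Uncertainty is quantified by a residual bootstrap: recentred residuals are
resampled with replacement and added to the fitted curve to form
pseudo-responses, which are refitted (raw residuals by default; a
standardized-weighted flavour is available for data whose reported s.d.
genuinely tracks the error variance).  Percentile intervals over the refits give
per-parameter and pointwise-curve 95% confidence bands.  An 80% prediction
band for a *new* measurement is built by simulation: bootstrap parameter
draws plus Gaussian observation noise, with pointwise 10%/90% quantiles.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core import Dataset
from .pulse import FIVE_PARAM, FOUR_PARAM, PulseParams, pmc_at

__all__ = ["FitResult", "fit_pulse", "bootstrap_ci", "prediction_interval",
           "DEFAULT_SEED"]

DEFAULT_SEED = 20240350

# Non-convergence thresholds: relative objective change and iteration budget.
_FTOL = 1e-10
_MAX_NFEV = 500


def _model(theta: np.ndarray, years: np.ndarray, variant: str) -> np.ndarray:
    """Raw curve evaluation on the internal parameter vector (fast path).

    Internal five-parameter vector is (a, b, c, d1, s) with d2 = d1 + s so
    the separation d2 > d1 holds throughout optimisation.
    """
    a, b, c, d1 = theta[:4]
    u = (c - years) / d1
    if variant == FOUR_PARAM:
        return a + (b - a) / (1.0 + np.exp(np.minimum(u, 500.0)))
    d2 = d1 + theta[4]
    log_term = np.log(b) + (c - years) / d2 - np.logaddexp(0.0, u)
    return a + np.exp(log_term)


def _to_params(theta: np.ndarray, variant: str) -> PulseParams:
    if variant == FIVE_PARAM:
        a, b, c, d1, s = theta[:5]
        return PulseParams.five(a, b, c, d1, d1 + s)
    return PulseParams.four(*theta[:4])


def _from_params(params: PulseParams) -> np.ndarray:
    if params.variant == FIVE_PARAM:
        return np.array([params.a, params.b, params.c, params.d1,
                         params.d2 - params.d1])
    return np.array([params.a, params.b, params.c, params.d1])


_S_HI = 5000.0  # upper bound on d2 - d1; hitting it flags non-identifiability


def _bounds(variant: str) -> tuple[np.ndarray, np.ndarray]:
    if variant == FIVE_PARAM:
        lo = np.array([10.0, 1e-3, 1850.0, 0.05, 1e-3])
        hi = np.array([150.0, 200.0, 2100.0, 200.0, _S_HI])
    else:
        lo = np.array([10.0, 10.0, 1850.0, 0.05])
        hi = np.array([150.0, 250.0, 2100.0, 200.0])
    return lo, hi


@dataclass
class FitResult:
    """Point fit plus (after the bootstrap/simulation steps) interval bands.

    ``param_ci`` maps parameter name to a (lower, upper) 95% interval;
    ``curve_ci`` / ``curve_pi`` are pointwise (lower, upper) arrays over
    ``grid``.  ``sigma`` is the weighted residual standard deviation
    sqrt(RSS_w / (n - p)) — the unitless scale of the standardized residuals.
    """

    params: PulseParams
    converged: bool
    n_obs: int
    objective: float
    sigma: float
    residuals: list[tuple[float, float, float]]  # (year, raw residual, weight)
    grid: np.ndarray
    curve: np.ndarray
    message: str = ""
    param_ci: Optional[dict[str, tuple[float, float]]] = None
    curve_ci: Optional[tuple[np.ndarray, np.ndarray]] = None
    curve_pi: Optional[tuple[np.ndarray, np.ndarray]] = None
    boot_params: Optional[np.ndarray] = None
    boot_n_failed: int = 0
    # observed data, kept so resampling stages need no second data pass
    years: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    pmc: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    pmc_sd: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def variant(self) -> str:
        return self.params.variant

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.pmc_sd**2

    def fitted(self) -> np.ndarray:
        return pmc_at(self.params, self.years)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        import json

        payload = {
            "params": json.loads(self.params.to_json()),
            "converged": self.converged,
            "n_obs": self.n_obs,
            "objective": self.objective,
            "sigma": self.sigma,
            "message": self.message,
            "param_ci": self.param_ci,
            "grid": self.grid.tolist(),
            "curve": self.curve.tolist(),
            "curve_ci": None if self.curve_ci is None
            else [self.curve_ci[0].tolist(), self.curve_ci[1].tolist()],
            "curve_pi": None if self.curve_pi is None
            else [self.curve_pi[0].tolist(), self.curve_pi[1].tolist()],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def band_to_csv(self, path: Union[str, Path], which: str = "ci") -> None:
        """Export a band as CSV columns (year, lower, fit, upper)."""
        band = self.curve_ci if which == "ci" else self.curve_pi
        if band is None:
            raise ValueError(f"{which} band not computed yet")
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["year", "lower", "fit", "upper"])
            for yr, lo, f, hi in zip(self.grid, band[0], self.curve, band[1]):
                w.writerow([yr, lo, f, hi])


def _extract_points(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(samples, Dataset):
        pts = samples.radiocarbon_points()
    else:
        pts = [tuple(p) for p in samples]
    if not pts:
        raise ValueError("no (year, pmc, sd) points with known year")
    arr = np.asarray(sorted(pts), dtype=float)
    years, pmc, sd = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(sd <= 0):
        raise ValueError("all pmc_sd must be > 0")
    return years, pmc, sd


def _initial_guess(years, pmc, variant: str) -> np.ndarray:
    a0 = float(pmc.min())
    top = float(pmc.max())
    mid = 0.5 * (a0 + top)
    order = np.argsort(years)
    above = years[order][pmc[order] > mid]
    c0 = float(above[0]) if len(above) else float(np.median(years))
    if variant == FIVE_PARAM:
        return np.array([a0, top - a0, c0, 5.0, 95.0])
    return np.array([a0, top, c0, 5.0])


def _multistart_inits(theta0, lo, hi, n_starts: int, rng) -> list[np.ndarray]:
    """Heuristic guess plus Latin-hypercube perturbations around it."""
    inits = [theta0]
    if n_starts <= 1:
        return inits
    k = len(theta0)
    sampler = qmc.LatinHypercube(d=k, seed=rng)
    unit = sampler.random(n=n_starts - 1)
    # per-parameter exploration ranges around the heuristic
    span_lo = np.array(theta0, dtype=float)
    span_hi = np.array(theta0, dtype=float)
    span_lo[0] -= 3.0
    span_hi[0] += 3.0  # a
    span_lo[1] = max(lo[1], theta0[1] * 0.3)
    span_hi[1] = min(hi[1], theta0[1] * 1.5 + 5.0)  # b
    span_lo[2] -= 15.0
    span_hi[2] += 15.0  # c
    span_lo[3], span_hi[3] = 1.0, 25.0  # d1
    if k == 5:
        span_lo[4], span_hi[4] = 5.0, 1500.0  # s = d2 - d1
    pts = span_lo + unit * (span_hi - span_lo)
    pts = np.clip(pts, lo + 1e-9, hi - 1e-9)
    inits.extend(list(pts))
    return inits


def fit_pulse(
    samples,
    variant: str = FIVE_PARAM,
    init: Optional[PulseParams] = None,
    seed: int = DEFAULT_SEED,
    n_starts: int = 20,
    grid: Optional[np.ndarray] = None,
) -> FitResult:
    """Fit the pulse curve to (year, pmc, pmc_sd) points by weighted NLS.

    Parameters
    ----------
    samples : Dataset or sequence of (year, pmc, pmc_sd)
        Observations; points without a known year are ignored.
    variant : {"five_param", "four_param"}
    init : PulseParams, optional
        Explicit starting point; when given, the multi-start is still run
        and the best local optimum kept.
    seed : int
        Seed for the Latin-hypercube multi-start (fit is deterministic).
    n_starts : int
        Number of optimiser starts (heuristic guess + LHS draws).
    grid : ndarray, optional
        Year grid for the fitted-curve and band exports; defaults to one-year
        steps spanning the data with a 10-year margin.

    Notes
    -----
    Points are sorted internally, so the result is invariant to row order.
    ``converged`` is False when the optimiser fails, when the objective
    decrease stalls without meeting the relative tolerance, or when the
    decay separation s = d2 - d1 escapes to its upper bound (the flat
    direction of the non-identifiable five-parameter fit).
    """
    years, pmc, sd = _extract_points(samples)
    n_params = 5 if variant == FIVE_PARAM else 4
    if len(years) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} observations for the {variant} fit, "
            f"got {len(years)}"
        )
    w = 1.0 / sd**2
    sqw = np.sqrt(w)

    def resid(theta):
        return sqw * (pmc - _model(theta, years, variant))

    lo, hi = _bounds(variant)
    theta0 = _initial_guess(years, pmc, variant)
    rng = np.random.default_rng(seed)
    inits = _multistart_inits(theta0, lo, hi, n_starts, rng)
    if init is not None:
        if init.variant != variant:
            raise ValueError("init variant does not match requested variant")
        inits.insert(0, np.clip(_from_params(init), lo + 1e-9, hi - 1e-9))

    best = None
    for x0 in inits:
        try:
            res = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                ftol=_FTOL, xtol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV,
            )
        except Exception:  # singular step, overflow in a bad corner, ...
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimiser starts failed")

    theta = best.x
    converged = bool(best.success) and best.status != 0
    message = best.message
    if variant == FIVE_PARAM and theta[4] > 0.98 * _S_HI:
        converged = False
        message = (
            "decay timescale d2 is not identified (s = d2 - d1 at its upper "
            "bound); the data carry no post-peak decline — fall back to the "
            "four-parameter sigmoid"
        )

    objective = float(2.0 * best.cost)
    dof = max(len(years) - n_params, 1)
    sigma = float(np.sqrt(objective / dof))
    params = _to_params(theta, variant)
    raw_resid = pmc - _model(theta, years, variant)
    if grid is None:
        grid = np.arange(np.floor(years.min()) - 10.0, years.max() + 11.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    return FitResult(
        params=params,
        converged=converged,
        n_obs=len(years),
        objective=objective,
        sigma=sigma,
        residuals=list(zip(years.tolist(), raw_resid.tolist(), w.tolist())),
        grid=grid,
        curve=pmc_at(params, grid),
        message=message,
        years=years,
        pmc=pmc,
        pmc_sd=sd,
    )


def _refit(fit: FitResult, response: np.ndarray) -> Optional[np.ndarray]:
    """Warm-started single refit against a pseudo-response vector."""
    variant = fit.variant
    sqw = np.sqrt(fit.weights)
    years = fit.years

    def resid(theta):
        return sqw * (response - _model(theta, years, variant))

    lo, hi = _bounds(variant)
    x0 = np.clip(_from_params(fit.params), lo + 1e-9, hi - 1e-9)
    try:
        res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            ftol=1e-9, xtol=1e-10, max_nfev=200)
    except Exception:
        return None
    if not res.success:
        return None
    return res.x


def bootstrap_ci(
    fit: FitResult,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = DEFAULT_SEED,
    residual_type: str = "raw",
) -> FitResult:
    """Residual-bootstrap confidence intervals for parameters and the curve.

    Recentred residuals are resampled with replacement, added to the fitted
    curve to form pseudo-responses, and the model is refitted; percentile
    intervals at ``level`` are attached per parameter and pointwise over the
    year grid.  Deterministic given ``seed``.  Refits that fail are dropped;
    if more than 10% fail a warning is issued (count in ``boot_n_failed``).

    ``residual_type="raw"`` (default) resamples raw residuals, treating the
    measurement errors as exchangeable.  ``"standardized"`` resamples
    weighted residuals r*sqrt(w) and rescales by 1/sqrt(w) at the
    destination point, which is preferable only when the reported
    measurement s.d. genuinely tracks the error variance; when the
    residual scatter dwarfs the reported s.d. (sigma >> 1, as in the real
    tusk series) the raw flavour is the robust choice.
    """
    if not fit.converged:
        raise ValueError("bootstrap_ci requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if residual_type not in ("raw", "standardized"):
        raise ValueError(f"unknown residual_type {residual_type!r}")
    rng = np.random.default_rng(seed)
    yhat = fit.fitted()
    sqw = np.sqrt(fit.weights)
    if residual_type == "standardized":
        pool = (fit.pmc - yhat) * sqw
        scale = 1.0 / sqw
    else:
        pool = fit.pmc - yhat
        scale = np.ones_like(sqw)
    pool = pool - pool.mean()
    n = fit.n_obs

    thetas = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        response = yhat + pool[idx] * scale
        theta = _refit(fit, response)
        if theta is None:
            n_failed += 1
        else:
            thetas.append(theta)
    if n_failed > 0.1 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits failed; intervals use the "
            f"remaining {len(thetas)}",
            RuntimeWarning,
        )
    if not thetas:
        raise RuntimeError("every bootstrap refit failed")
    thetas = np.asarray(thetas)
    alpha = (1.0 - level) / 2.0
    qs = np.quantile(thetas, [alpha, 1.0 - alpha], axis=0)

    names = list(fit.params.free_names)
    boot_nat = thetas.copy()
    ci_nat = qs.copy()
    if fit.variant == FIVE_PARAM:  # report d2 = d1 + s, not the internal s
        boot_nat[:, 4] = boot_nat[:, 3] + boot_nat[:, 4]
        d2q = np.quantile(boot_nat[:, 4], [alpha, 1.0 - alpha])
        ci_nat[:, 4] = d2q
    param_ci = {nm: (float(ci_nat[0, j]), float(ci_nat[1, j]))
                for j, nm in enumerate(names)}

    curves = np.array([_model(t, fit.grid, fit.variant) for t in thetas])
    c_lo, c_hi = np.quantile(curves, [alpha, 1.0 - alpha], axis=0)
    return dataclasses.replace(
        fit,
        param_ci=param_ci,
        curve_ci=(c_lo, c_hi),
        boot_params=thetas,
        boot_n_failed=n_failed,
    )


def prediction_interval(
    fit: FitResult,
    years: Optional[np.ndarray] = None,
    level: float = 0.80,
    n_sim: int = 1000,
    seed: int = DEFAULT_SEED,
    noise_sd: Optional[float] = None,
) -> FitResult:
    """Simulation-based pointwise prediction band for a new measurement.

    At every grid year, ``n_sim`` responses are simulated from the fitted
    model — a bootstrap parameter draw (curve uncertainty) plus Gaussian
    observation noise — and the band is the pointwise (alpha/2, 1 - alpha/2)
    quantiles, i.e. the 10% and 90% quantiles at the default 80% level.

    ``noise_sd`` defaults to sigma * median(pmc_sd): under inverse-variance
    weights, sigma is the dimensionless scale of the standardized residuals,
    so this is the implied observation s.d. of a typical new measurement.
    Set ``noise_sd=0`` to see the band collapse onto the curve-uncertainty
    envelope (and onto the curve itself when no bootstrap draws are held).

    Returns the FitResult with the band attached as ``curve_pi`` when
    ``years`` is None; with an explicit ``years`` grid, returns the band as
    a (years, lower, upper) tuple instead.
    """
    if not fit.converged:
        raise ValueError("prediction_interval requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    grid = fit.grid if years is None else np.asarray(years, dtype=float)
    if noise_sd is None:
        noise_sd = fit.sigma * float(np.median(fit.pmc_sd))

    if fit.boot_params is not None and len(fit.boot_params):
        idx = rng.integers(0, len(fit.boot_params), size=n_sim)
        curves = np.array(
            [_model(fit.boot_params[j], grid, fit.variant) for j in idx]
        )
    else:
        curves = np.tile(pmc_at(fit.params, grid), (n_sim, 1))
    sims = curves + rng.normal(0.0, 1.0, size=curves.shape) * noise_sd
    alpha = (1.0 - level) / 2.0
    p_lo, p_hi = np.quantile(sims, [alpha, 1.0 - alpha], axis=0)
    if years is not None:
        return grid, p_lo, p_hi
    return dataclasses.replace(fit, curve_pi=(p_lo, p_hi))
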