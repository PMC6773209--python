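"""The simplified macro-index scaling method.

Province-average unit costs (outpatient visit cost, inpatient bed-day cost)
are regressed on a macro-index x — per-capita GDP, HDI, or another province
attribute — with a three-parameter exponential law

    cost(x) = A * exp(B * x) + C,

fitted by unweighted least squares on the natural cost scale.  Costs for a
target province are then obtained from the base province's reference costs
via the transfer multiplier

    lambda = (A * exp(B * x_target) + C) / (A * exp(B * x_base) + C),

with separate fits (and hence separate multipliers) for outpatient and
inpatient costs.  Combined predictors generalise the exponent to a linear
form, cost(x) = A * exp(sum_k B_k x_k) + C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import Bundle
from .types import CostTable, Province, SETTINGS, ValidationError

log = logging.getLogger(__name__)

MIN_POINTS = 4


@dataclass
class ExponentialFit:
    """A fitted unit-cost-vs-index curve with residual diagnostics.

    ``B`` has one entry per predictor; for the usual single-predictor fit it
    is a length-1 array and ``slope`` gives the scalar.
    """

    predictor_names: tuple[str, ...]
    setting: str
    A: float
    B: np.ndarray
    C: float
    x: np.ndarray          # (n, k) fitted predictor values
    residuals: np.ndarray  # y - fitted, length n
    rmse: float

    @property
    def slope(self) -> float:
        if len(self.B) != 1:
            raise ValueError("slope is defined for single-predictor fits only")
        return float(self.B[0])

    def predict(self, x: float | np.ndarray) -> np.ndarray | float:
        """Fitted curve value(s) at predictor value(s) ``x``."""
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[-1] != len(self.B) and len(self.B) == 1:
            arr = arr.reshape(-1, 1)
        out = self.A * np.exp(arr @ self.B) + self.C
        return float(out[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else out

    def diagnostics(self) -> pd.DataFrame:
        """Residual-plot companion data (observed index, fitted, residual)."""
        frame = pd.DataFrame(self.x, columns=list(self.predictor_names))
        frame["fitted"] = self.A * np.exp(self.x @ self.B) + self.C
        frame["residual"] = self.residuals
        return frame


def _initial_parameters(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """C0 = 0.9 * min(y); (A0, B0) from a linear fit of log(y - C0) on x."""
    c0 = 0.9 * float(np.min(y))
    z = np.log(np.clip(y - c0, 1e-12, None))
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    a0 = float(np.exp(coef[0]))
    return np.concatenate([[a0], coef[1:], [c0]])


def fit_exponential(
    x: np.ndarray,
    y: np.ndarray,
    predictor_names: tuple[str, ...] | str = ("index",),
    setting: str = "outpatient",
    max_restarts: int = 5,
    restart_seed: int = 20180101,
) -> ExponentialFit:
    """Least-squares fit of ``y = A * exp(x @ B) + C``.

    ``x`` may be a length-n vector (single predictor) or an (n, k) matrix
    (combined predictors).  On non-convergence the initial point is jittered
    up to ``max_restarts`` times with a fixed-seed generator, so fits are
    reproducible.
    """
    if isinstance(predictor_names, str):
        predictor_names = (predictor_names,)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if len(predictor_names) != k:
        raise ValidationError(
            f"{k} predictor column(s) but {len(predictor_names)} name(s)",
            rule="predictor-names")
    if n != len(y):
        raise ValidationError("x and y lengths differ", rule="xy-length")
    if n < MIN_POINTS:
        raise ValidationError(
            f"need at least {MIN_POINTS} points for an exponential fit, got {n}",
            rule="min-points")
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValidationError("a predictor column is constant (degenerate x)",
                              rule="degenerate-x")

    # rescale predictors to O(1) so one step-size policy works for GDP
    # (1e4 scale) and HDI (1e-1 scale) alike; B is mapped back afterwards
    scale = np.ptp(x, axis=0)
    xs = x / scale

    def residual(params: np.ndarray) -> np.ndarray:
        a, b, c = params[0], params[1:1 + k], params[1 + k]
        return a * np.exp(xs @ b) + c - y

    p0 = _initial_parameters(xs, y)
    rng = np.random.default_rng(restart_seed)
    best = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * (1 + 0.1 * rng.standard_normal(p0.shape))
        try:
            sol = least_squares(residual, start, method="lm", max_nfev=20000)
        except Exception:  # singular Jacobian etc.; retry from jittered start
            continue
        if np.all(np.isfinite(sol.x)) and np.isfinite(sol.cost):
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.success and sol.cost <= best.cost + 1e-12:
                break
    if best is None:
        raise ValidationError(
            f"exponential fit failed to converge after {max_restarts} restarts",
            rule="fit-convergence")

    a, b, c = best.x[0], best.x[1:1 + k] / scale, best.x[1 + k]
    resid = y - (a * np.exp(x @ b) + c)
    fit = ExponentialFit(
        predictor_names=tuple(predictor_names), setting=setting,
        A=float(a), B=np.asarray(b, dtype=float), C=float(c),
        x=x, residuals=resid, rmse=float(np.sqrt(np.mean(resid ** 2))))
    log.info("fit %s/%s: A=%.4g B=%s C=%.4g rmse=%.4g",
             "+".join(predictor_names), setting, fit.A,
             np.array2string(fit.B, precision=4), fit.C, fit.rmse)
    return fit


def fit_unit_costs(
    provinces: list[Province],
    predictors: tuple[str, ...] | str,
    setting: str,
    **kwargs,
) -> ExponentialFit:
    """Fit the unit-cost law for one setting over a province list."""
    if isinstance(predictors, str):
        predictors = (predictors,)
    x = np.array([[p.index_value(name) for name in predictors] for p in provinces])
    y = np.array([p.unit_cost(setting) for p in provinces])
    return fit_exponential(x, y, predictors, setting, **kwargs)


def scaling_multiplier(fit: ExponentialFit, x_target, x_base) -> float:
    """Transfer multiplier lambda = fitted(x_target) / fitted(x_base)."""
    denom = float(np.atleast_1d(fit.predict(np.asarray(x_base, dtype=float)))[0])
    if not denom > 0:
        raise ValidationError(
            f"fitted base-province cost must be > 0, got {denom}",
            rule="lambda-denominator")
    num = float(np.atleast_1d(fit.predict(np.asarray(x_target, dtype=float)))[0])
    lam = num / denom
    lo, hi = np.min(fit.x, axis=0), np.max(fit.x, axis=0)
    tgt = np.atleast_1d(np.asarray(x_target, dtype=float))
    if np.any(tgt < lo) or np.any(tgt > hi):
        log.warning("extrapolating beyond the fitted index range: %s", tgt)
    return lam


def scale_costs_simplified(
    base_costs: dict[str, float],
    procedure_settings: dict[str, str],
    fits: dict[str, ExponentialFit],
    provinces: list[Province],
    base_province: str,
) -> CostTable:
    """Transfer the base province's per-procedure reference costs to every
    province via the fitted multipliers (overall provincial costs only)."""
    for setting in set(procedure_settings.values()):
        if setting not in fits:
            raise ValidationError(f"no fit supplied for setting {setting!r}",
                                  rule="fit-per-setting")
    base = next((p for p in provinces if p.name == base_province), None)
    if base is None:
        raise ValidationError(f"base province {base_province!r} not present",
                              rule="base-province-present")

    rows = []
    for prov in provinces:
        for pid, cost in base_costs.items():
            fit = fits[procedure_settings[pid]]
            x_t = np.array([prov.index_value(n) for n in fit.predictor_names])
            x_b = np.array([base.index_value(n) for n in fit.predictor_names])
            lam = scaling_multiplier(fit, x_t, x_b)
            rows.append({"scope": "province", "scope_id": prov.name,
                         "procedure_id": pid, "overall": cost * lam,
                         "urban": np.nan, "rural": np.nan})
    return CostTable(pd.DataFrame(rows))


def run_simplified_pipeline(
    bundle: Bundle,
    reference: CostTable,
    predictors: tuple[str, ...] | str,
    **fit_kwargs,
) -> tuple[CostTable, dict[str, ExponentialFit]]:
    """Fit both settings' unit-cost laws on a bundle's provinces and scale
    the base province's reference costs (taken from ``reference``) to all
    provinces."""
    fits = {s: fit_unit_costs(bundle.provinces, predictors, s, **fit_kwargs)
            for s in SETTINGS}
    base_costs = {
        pid: reference.value("province", bundle.base_province, pid)
        for pid in bundle.procedures
    }
    settings = {pid: proc.setting for pid, proc in bundle.procedures.items()}
    table = scale_costs_simplified(base_costs, settings, fits,
                                   bundle.provinces, bundle.base_province)
    return table, fits
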