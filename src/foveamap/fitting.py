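"""Parameter estimation for the retino-cortical map family.

Follows the statsmodels convention: a model object is built from data,
``fit()`` returns a results object carrying estimates, residual
diagnostics and a ``summary()`` table.

Two observation models are supported:

positions
    sparse retinotopy samples (E, theta, area -> cortical x, y); the
    objective is the summed squared cortical-position residual in mm.
magnification curve
    samples of the areal magnification function M(E) per area; the
    objective is least squares in log M, since magnification spans
    orders of magnitude across eccentricity and relative error is the
    physically meaningful scale.

By default only the cortical scale ``k`` is free and the structural
parameters stay at the canonical values (a = 1.05 deg, b = 90 deg,
lam = 0.4), which fit most individual subjects; freeing more parameters
is opt-in via ``free``.  Optimization is bounded local least squares
from a small deterministic multi-start grid, since the objective is
smooth but can be locally flat in ``b`` when only central data are
present.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import DEFAULT_BOUNDS, FITTABLE, ModelParams, validate_free
from .wedge import AreaLabel, VisualAreaMap

__all__ = ["RetinotopyFit", "MagnificationCurveFit", "FitResult",
           "fit_positions", "fit_magnification_curve"]


@dataclass
class FitResult:
    """Estimates, uncertainty proxies and diagnostics of one fit."""

    params: ModelParams
    free: tuple[str, ...]
    success: bool
    rms_mm: float                      # root-mean-square residual
    cost: float
    n_obs: int
    n_free: int
    message: str = ""
    underdetermined: bool = False
    stderr: Mapping[str, float] = field(default_factory=dict)
    n_starts: int = 1

    @property
    def estimates(self) -> dict[str, float]:
        return {name: getattr(self.params, name) for name in self.free}

    def summary(self) -> str:
        lines = [
            "Retinotopic map fit",
            "=" * 46,
            f"variant: {self.params.variant:>20s}   n_obs: {self.n_obs}",
            f"free parameters: {', '.join(self.free) or '(none)'}",
            f"converged: {self.success}   starts: {self.n_starts}",
            f"residual RMS: {self.rms_mm:.4g}",
            "-" * 46,
            f"{'param':>6s} {'estimate':>12s} {'std.err':>10s} {'status':>8s}",
        ]
        for name in FITTABLE:
            est = getattr(self.params, name)
            se = self.stderr.get(name)
            se_s = f"{se:10.3g}" if se is not None else " " * 10
            status = "free" if name in self.free else "fixed"
            lines.append(f"{name:>6s} {est:12.5g} {se_s} {status:>8s}")
        if self.underdetermined:
            lines.append("WARNING: under-determined fit (too few points)")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


def _build_params(base: ModelParams, free, values) -> ModelParams:
    return base.with_(**dict(zip(free, values)))


def _starts(init: np.ndarray, lb: np.ndarray, ub: np.ndarray,
            per_param: int = 3) -> list[np.ndarray]:
    """Deterministic multi-start grid: the init plus, for every free
    parameter, `per_param` one-at-a-time sweeps across its bounds."""
    starts = [init.copy()]
    fracs = np.linspace(0.15, 0.85, per_param)
    for i in range(len(init)):
        for f in fracs:
            s = init.copy()
            s[i] = lb[i] + f * (ub[i] - lb[i])
            starts.append(s)
    return starts


def _run_multistart(residual_fn, init, lb, ub, max_full: int = 3):
    """Rank the start grid by objective value, polish the best few."""
    starts = _starts(init, lb, ub)
    scored = sorted(
        starts, key=lambda s: float(np.sum(residual_fn(s) ** 2)))
    best = None
    for s in scored[:max_full]:
        sol = least_squares(residual_fn, s, bounds=(lb, ub),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    return best, len(starts)


def _stderr_from_jac(sol, free) -> dict[str, float]:
    """Gauss-Newton standard errors from the final Jacobian."""
    m, n = sol.jac.shape
    if m <= n:
        return {}
    dof = m - n
    s2 = 2.0 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return {}
    return {name: float(np.sqrt(max(cov[i, i], 0.0)))
            for i, name in enumerate(free)}


class RetinotopyFit:
    """Least-squares fit of the map family to retinotopy positions.

    Parameters
    ----------
    samples
        DataFrame with columns ``ecc_deg, polar_rad, x_mm, y_mm, area``.
    variant
        Map variant to fit (default: the sheared dipole).
    banded
        Include the lam banding stage.
    free
        Names of the parameters to estimate, subset of (k, a, b, lam).
    init
        Starting ModelParams (defaults to the canonical set).
    bounds
        Mapping name -> (lo, hi) overriding the default bounds.
    """

    def __init__(self, samples: pd.DataFrame, variant: str = "sheared_dipole",
                 banded: bool = True, free: Sequence[str] = ("k",),
                 init: ModelParams | None = None,
                 bounds: Mapping[str, tuple[float, float]] | None = None):
        req = {"ecc_deg", "polar_rad", "x_mm", "y_mm", "area"}
        missing = req - set(samples.columns)
        if missing:
            raise ValueError(f"samples missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(samples[["ecc_deg", "polar_rad",
                                           "x_mm", "y_mm"]].to_numpy())):
            raise ValueError("samples contain non-finite values")
        # canonical ordering makes the fit exactly invariant to the
        # order in which samples arrive
        self.samples = samples.sort_values(
            ["area", "ecc_deg", "polar_rad", "x_mm", "y_mm"]
        ).reset_index(drop=True)
        self.free = validate_free(free)
        self.banded = banded
        base = (init if init is not None else ModelParams())
        self.init = base.with_(variant=variant)
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        for name in self.free:
            lo, hi = self.bounds[name]
            v = getattr(self.init, name)
            if not lo <= v <= hi:
                raise ValueError(f"init {name}={v} outside bounds {lo, hi}")
        # pre-group observations by area for vectorized residuals
        self._groups = [
            (AreaLabel(lbl), g["ecc_deg"].to_numpy(),
             g["polar_rad"].to_numpy(),
             (g["x_mm"] + 1j * g["y_mm"]).to_numpy())
            for lbl, g in self.samples.groupby("area", sort=True)
        ]

    def _residuals(self, values) -> np.ndarray:
        params = _build_params(self.init, self.free, values)
        out = []
        for area, E, th, w_obs in self._groups:
            model = VisualAreaMap(params, banded=self.banded)
            w = model.project(E, th, area)
            d = w - w_obs
            d = np.where(np.isfinite(d), d, 1e3)
            out.append(d.real)
            out.append(d.imag)
        return np.concatenate(out)

    def fit(self) -> FitResult:
        n_obs = 2 * len(self.samples)
        n_free = len(self.free)
        if len(self.samples) < n_free:
            return FitResult(
                params=self.init, free=self.free, success=False,
                rms_mm=np.nan, cost=np.nan, n_obs=n_obs, n_free=n_free,
                underdetermined=True,
                message="fewer samples than free parameters")
        init = np.array([getattr(self.init, n) for n in self.free])
        lb = np.array([self.bounds[n][0] for n in self.free])
        ub = np.array([self.bounds[n][1] for n in self.free])
        if n_free == 0:
            r = self._residuals(init)
            return FitResult(params=self.init, free=self.free, success=True,
                             rms_mm=float(np.sqrt(np.mean(r ** 2))),
                             cost=0.5 * float(r @ r), n_obs=n_obs, n_free=0)
        sol, n_starts = _run_multistart(self._residuals, init, lb, ub)
        params = _build_params(self.init, self.free, sol.x)
        rms = float(np.sqrt(np.mean(sol.fun ** 2)))
        return FitResult(
            params=params, free=self.free, success=bool(sol.success),
            rms_mm=rms, cost=float(sol.cost), n_obs=n_obs, n_free=n_free,
            message="" if sol.success else f"optimizer: {sol.message}",
            stderr=_stderr_from_jac(sol, self.free), n_starts=n_starts)


class MagnificationCurveFit:
    """Least squares in log M(E) against the model's magnification curve.

    ``curve`` needs columns ``ecc_deg, M_mm_per_deg`` and optionally
    ``area`` (default V1).  Requires at least 3 points per free
    parameter, otherwise the result is flagged under-determined.
    """

    def __init__(self, curve: pd.DataFrame, variant: str = "sheared_dipole",
                 banded: bool = True, free: Sequence[str] = ("lam",),
                 init: ModelParams | None = None,
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 n_polar: int = 31):
        req = {"ecc_deg", "M_mm_per_deg"}
        if req - set(curve.columns):
            raise ValueError(f"curve needs columns {sorted(req)}")
        self.curve = curve.reset_index(drop=True)
        if "area" not in self.curve.columns:
            self.curve["area"] = "V1"
        self.free = validate_free(free)
        self.banded = banded
        self.init = (init if init is not None else ModelParams()).with_(
            variant=variant)
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)
        self.n_polar = n_polar

    def _residuals(self, values) -> np.ndarray:
        from .cartography import areal_magnification_curve
        params = _build_params(self.init, self.free, values)
        model = VisualAreaMap(params, banded=self.banded)
        out = []
        for area, g in self.curve.groupby("area", sort=True):
            pred = areal_magnification_curve(
                model, area, g["ecc_deg"].to_numpy(), n_polar=self.n_polar)
            r = np.log(pred["M_mm_per_deg"].to_numpy()) - np.log(
                g["M_mm_per_deg"].to_numpy())
            out.append(np.where(np.isfinite(r), r, 1e3))
        return np.concatenate(out)

    def fit(self) -> FitResult:
        n_obs = len(self.curve)
        n_free = len(self.free)
        if n_obs < 3 * max(n_free, 1):
            return FitResult(
                params=self.init, free=self.free, success=False,
                rms_mm=np.nan, cost=np.nan, n_obs=n_obs, n_free=n_free,
                underdetermined=True,
                message="need >= 3 curve points per free parameter")
        init = np.array([getattr(self.init, n) for n in self.free])
        lb = np.array([self.bounds[n][0] for n in self.free])
        ub = np.array([self.bounds[n][1] for n in self.free])
        sol, n_starts = _run_multistart(self._residuals, init, lb, ub,
                                        max_full=2)
        params = _build_params(self.init, self.free, sol.x)
        return FitResult(
            params=params, free=self.free, success=bool(sol.success),
            rms_mm=float(np.sqrt(np.mean(sol.fun ** 2))),
            cost=float(sol.cost), n_obs=n_obs, n_free=n_free,
            message="residuals are in log M" + (
                "" if sol.success else f"; optimizer: {sol.message}"),
            stderr=_stderr_from_jac(sol, self.free), n_starts=n_starts)


def fit_positions(samples: pd.DataFrame, variant: str = "sheared_dipole",
                  free: Sequence[str] = ("k",), init: ModelParams | None = None,
                  bounds=None, banded: bool = True) -> FitResult:
    """Functional wrapper over :class:`RetinotopyFit`."""
    return RetinotopyFit(samples, variant=variant, banded=banded, free=free,
                         init=init, bounds=bounds).fit()


def fit_magnification_curve(curve: pd.DataFrame,
                            variant: str = "sheared_dipole",
                            free: Sequence[str] = ("lam",),
                            init: ModelParams | None = None,
                            bounds=None, banded: bool = True) -> FitResult:
    """Functional wrapper over :class:`MagnificationCurveFit`."""
    return MagnificationCurveFit(curve, variant=variant, banded=banded,
                                 free=free, init=init, bounds=bounds).fit()
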