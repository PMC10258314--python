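"""Tumor-growth ODE models and per-patient fitting.

The central quantity is the pretreatment growth-rate constant ``alpha``
(units: per day) of the exponential model

    dV/dt = alpha * V,

fitted to the cumulative metastatic tumor volume at two imaging timepoints:
the last pretreatment scan (TP-1, at a negative day offset) and the treatment
baseline (TP0, day 0). With exactly two observations the least-squares
solution has the closed form ``alpha = ln(V0 / V-1) / dt``.

Six alternative growth laws are registered for comparison, with the forms of
Murphy, Jaafari & Dobrovolny, *BMC Cancer* 16:163 (2016):

====================  ==========================================
name                  dV/dt
====================  ==========================================
exponential           a * V
mendelsohn            a * V**b
logistic              a * V * (1 - V/b)
linear                a * V / (V + b)
surface               a * V / (V + b)**(1/3)
gompertz              a * V * ln(b / V)
bertalanffy           a * V**(2/3) - b * V
====================  ==========================================

Only the exponential rate is identifiable from two timepoints; fits of
multi-parameter models to two observations are flagged ``underdetermined``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Volumes are clipped to this floor (cc) before log/ODE evaluation so that
#: log-based right-hand sides stay finite on the fitting domain.
VOLUME_FLOOR = 1e-3


class InvalidInputError(ValueError):
    """An input violates a precondition (non-positive volume, bad interval...)."""


class IntegrationError(RuntimeError):
    """The ODE solver produced a non-finite state."""

    def __init__(self, model: str, params: Sequence[float], detail: str = ""):
        self.model = model
        self.params = tuple(params)
        super().__init__(
            f"ODE integration failed for model {model!r} with params {self.params}"
            + (f": {detail}" if detail else "")
        )


@dataclass(frozen=True)
class VolumeObservation:
    """One cumulative-volume measurement: day offset relative to TP0, volume in cc."""

    t: float
    v: float
    imputed: bool = False

    def __post_init__(self) -> None:
        if not (self.v > 0):
            raise InvalidInputError(f"volume must be > 0, got v={self.v}")


@dataclass(frozen=True)
class GrowthModelSpec:
    """A growth law: name, ordered parameters, RHS, and data-driven bounds/inits.

    ``bounds`` and ``default_init`` take the observed volumes so that
    capacity-like parameters can be bounded relative to the data
    (capacity must exceed the largest observed volume).
    """

    name: str
    param_names: tuple[str, ...]
    rhs: Callable[[float, np.ndarray], float]
    bounds: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]
    default_init: Callable[[np.ndarray], np.ndarray]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _clip(v: float) -> float:
    return v if v > VOLUME_FLOOR else VOLUME_FLOOR


def _rhs_exponential(v, p):
    return p[0] * v


def _rhs_mendelsohn(v, p):
    return p[0] * _clip(v) ** p[1]


def _rhs_logistic(v, p):
    return p[0] * v * (1.0 - v / p[1])


def _rhs_linear(v, p):
    return p[0] * v / (v + p[1])


def _rhs_surface(v, p):
    return p[0] * v / (v + p[1]) ** (1.0 / 3.0)


def _rhs_gompertz(v, p):
    return p[0] * v * math.log(p[1] / _clip(v))


def _rhs_bertalanffy(v, p):
    return p[0] * _clip(v) ** (2.0 / 3.0) - p[1] * v


def _capacity_bounds(vmax: float) -> tuple[float, float]:
    # capacity strictly above the largest observed volume, capped at 1e6 cc
    return vmax * (1.0 + 1e-9), 1e6


def _make_registry() -> dict[str, GrowthModelSpec]:
    def exp_bounds(v):
        return np.array([-1.0]), np.array([1.0])

    def two_param_rate_capacity_bounds(v):
        lo, hi = _capacity_bounds(float(np.max(v)))
        return np.array([-1.0, lo]), np.array([1.0, hi])

    def rate_capacity_init(v):
        return np.array([0.01, 10.0 * float(np.max(v))])

    def mendelsohn_bounds(v):
        return np.array([-10.0, 0.0]), np.array([10.0, 3.0])

    def linear_bounds(v):
        return np.array([-1e4, 1e-6]), np.array([1e4, 1e6])

    def bertalanffy_bounds(v):
        return np.array([-1e2, -1.0]), np.array([1e2, 1.0])

    vmax = lambda v: float(np.max(v))  # noqa: E731

    return {
        "exponential": GrowthModelSpec(
            "exponential", ("alpha",), _rhs_exponential,
            exp_bounds, lambda v: np.array([0.01]),
        ),
        "mendelsohn": GrowthModelSpec(
            "mendelsohn", ("a", "b"), _rhs_mendelsohn,
            mendelsohn_bounds, lambda v: np.array([0.01, 1.0]),
        ),
        "logistic": GrowthModelSpec(
            "logistic", ("a", "b"), _rhs_logistic,
            two_param_rate_capacity_bounds, rate_capacity_init,
        ),
        "linear": GrowthModelSpec(
            "linear", ("a", "b"), _rhs_linear,
            linear_bounds, lambda v: np.array([0.01 * vmax(v), vmax(v)]),
        ),
        "surface": GrowthModelSpec(
            "surface", ("a", "b"), _rhs_surface,
            linear_bounds, lambda v: np.array([0.01 * vmax(v) ** (1 / 3), vmax(v)]),
        ),
        "gompertz": GrowthModelSpec(
            "gompertz", ("a", "b"), _rhs_gompertz,
            two_param_rate_capacity_bounds, rate_capacity_init,
        ),
        "bertalanffy": GrowthModelSpec(
            "bertalanffy", ("a", "b"), _rhs_bertalanffy,
            bertalanffy_bounds, lambda v: np.array([0.01 * vmax(v) ** (1 / 3), 1e-3]),
        ),
    }


#: Registry of growth laws, addressable by name (config / ``--model``).
MODELS: dict[str, GrowthModelSpec] = _make_registry()


def get_model(name: str) -> GrowthModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {name!r}; available: {sorted(MODELS)}"
        ) from None


@dataclass(frozen=True)
class GrowthFit:
    """Result of fitting one growth law to one patient's volume series.

    ``params`` is ordered as in the model spec, growth-rate parameter first;
    for the exponential model ``params[0]`` is alpha (d^-1). ``rss`` is the
    residual sum of squares on the fitting scale. ``underdetermined`` marks
    fits with fewer free residuals than parameters (e.g. a two-parameter law
    fitted to two timepoints), where parameters are not jointly identifiable.
    """

    model: str
    params: tuple[float, ...]
    rss: float
    converged: bool
    n_obs: int
    underdetermined: bool = False

    @property
    def alpha(self) -> float:
        return self.params[0]

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def fit_exponential_two_point(v_pre: float, v_base: float, dt: float) -> GrowthFit:
    """Closed-form exponential growth rate from two cumulative volumes.

    Parameters
    ----------
    v_pre : float
        Cumulative volume (cc) at the pretreatment scan TP-1. Must be > 0
        (imputed as 0.1 cc for de-novo metastatic patients).
    v_base : float
        Cumulative volume (cc) at baseline TP0. Must be > 0.
    dt : float
        Elapsed days from TP-1 to TP0 (positive).

    Returns
    -------
    GrowthFit
        With ``alpha = ln(v_base / v_pre) / dt`` exactly; negative alpha is
        admissible (shrinking disease between scans).
    """
    if not (v_pre > 0):
        raise InvalidInputError(f"v_pre must be > 0, got {v_pre}")
    if not (v_base > 0):
        raise InvalidInputError(f"v_base must be > 0, got {v_base}")
    if not (dt > 0):
        raise InvalidInputError(f"dt must be > 0, got {dt}")
    alpha = math.log(v_base / v_pre) / dt
    return GrowthFit(
        model="exponential", params=(alpha,), rss=0.0, converged=True,
        n_obs=2, underdetermined=False,
    )


def solve_growth_ode(
    model: GrowthModelSpec | str,
    params: Sequence[float],
    v0: float,
    t_grid: Sequence[float],
) -> np.ndarray:
    """Solve dV/dt = f(V; params) forward over ``t_grid``, V(t_grid[0]) = v0.

    The exponential law uses its closed-form solution; other laws are
    integrated numerically (LSODA, rtol 1e-9).
    """
    if isinstance(model, str):
        model = get_model(model)
    params = np.asarray(params, dtype=float)
    if not (v0 > 0):
        raise InvalidInputError(f"v0 must be > 0, got {v0}")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("t_grid must be strictly ascending")

    if model.name == "exponential":
        return v0 * np.exp(params[0] * (t - t[0]))

    if t.size == 1:
        return np.array([v0])

    sol = solve_ivp(
        lambda tt, y: [model.rhs(max(y[0], VOLUME_FLOOR), params)],
        (t[0], t[-1]), [v0], t_eval=t, method="LSODA",
        rtol=1e-9, atol=1e-12,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(model.name, params, sol.message)
    return sol.y[0]


def fit_growth_model(
    model: GrowthModelSpec | str,
    obs: Sequence[VolumeObservation] | Sequence[tuple[float, float]],
    init: Sequence[float] | None = None,
    log_scale: bool = False,
) -> GrowthFit:
    """Bounded nonlinear least squares of the integrated trajectory.

    The trajectory is anchored at the first observation (V(t_1) = v_1) and the
    model parameters are fitted to the remaining points. With two observations
    and the exponential law this reproduces the closed form of
    :func:`fit_exponential_two_point` (the single residual is driven to zero).

    Parameters
    ----------
    obs : sequence
        ``VolumeObservation`` or ``(t, v)`` pairs with strictly increasing t.
    init : sequence of float, optional
        Starting parameters; data-driven defaults otherwise.
    log_scale : bool
        Fit residuals on log-volume instead of raw volume (cc).

    Returns
    -------
    GrowthFit
        ``converged`` is False (never an exception) on optimizer failure,
        carrying the best-found parameters.
    """
    if isinstance(model, str):
        model = get_model(model)
    pts = [
        (o.t, o.v) if isinstance(o, VolumeObservation) else (float(o[0]), float(o[1]))
        for o in obs
    ]
    if len(pts) < 2:
        raise InvalidInputError(
            f"at least 2 observations required to fit a growth model, got {len(pts)}"
        )
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.any(v <= 0):
        raise InvalidInputError("all observed volumes must be > 0")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("observation times must be strictly increasing")

    lo, hi = model.bounds(v)
    x0 = np.asarray(init, dtype=float) if init is not None else model.default_init(v)
    x0 = np.clip(x0, lo, hi)
    v0 = v[0]

    def residuals(p: np.ndarray) -> np.ndarray:
        try:
            pred = solve_growth_ode(model, p, v0, t)
        except IntegrationError:
            return np.full(v.size, 1e6)
        if not np.all(np.isfinite(pred)):
            return np.full(v.size, 1e6)
        if log_scale:
            return np.log(np.maximum(pred, VOLUME_FLOOR)) - np.log(v)
        return pred - v

    result = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
    )
    params = tuple(float(x) for x in result.x)
    rss = float(np.sum(result.fun**2))
    converged = bool(result.success and np.all(np.isfinite(result.x)))
    underdetermined = (len(pts) - 1) < model.n_params
    if underdetermined:
        logger.debug(
            "fit of %s to %d points is underdetermined (%d params)",
            model.name, len(pts), model.n_params,
        )
    return GrowthFit(
        model=model.name, params=params, rss=rss, converged=converged,
        n_obs=len(pts), underdetermined=underdetermined,
    )
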