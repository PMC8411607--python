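"""Least-squares estimation of model parameters from gas-exchange curves.

The forward model is the full coupled simulation (both limitations, gm
coupling), so a fitted curve may span the PEPC-limited initial slope, the
Vpr/Rubisco plateau and electron-transport-limited regions.  Identifiable
parameter subsets depend on the sampled design: low-Ci-only data conflate
``gm25`` and ``Vpmax25`` (a near-singular curvature matrix triggers
:class:`~c4photo.errors.WeakIdentifiabilityWarning`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import GasExchangeCurve
from .errors import DomainError, WeakIdentifiabilityWarning
from .leaf import Environment, net_assimilation
from .parameters import ParameterSet

FREE_PARAMETERS = ("Vpmax25", "Vcmax25", "Vpr", "Jmax25", "gm25")

#: Default box bounds for each fittable parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Vpmax25": (1.0, 1000.0),
    "Vcmax25": (1.0, 500.0),
    "Vpr": (1.0, 500.0),
    "Jmax25": (5.0, 1500.0),
    "gm25": (0.01, 50.0),
}

#: Condition number of the normalized (correlation-like) curvature matrix
#: above which the design is flagged as weakly identified.  For two
#: parameters the condition number is (1+|r|)/(1-|r|); the limit of 10
#: corresponds to a parameter-estimate correlation of ~0.82, the usual
#: collinearity concern level.  Well-spread A-Ci designs sit near 1-2;
#: initial-slope-only designs for (gm, Vpmax) sit above 30.
CONDITION_LIMIT = 10.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded nonlinear least-squares fit."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    weakly_identified: bool
    condition_number: float
    message: str
    n_obs: int


def _rebuild(base: ParameterSet, updates: dict[str, float]) -> ParameterSet:
    kwargs = base.as_dict()
    if base.rd25_tied_to_vcmax:
        kwargs["Rd25"] = None  # keep Rd tracking Vcmax25 while it moves
    kwargs.update(updates)
    return ParameterSet(**kwargs)


def fit(
    curve: GasExchangeCurve,
    free: tuple[str, ...] | list[str],
    base_params: ParameterSet | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    start: dict[str, float] | None = None,
    gm_mode: str = "finite",
) -> FitResult:
    """Fit a parameter subset to observed assimilation rates.

    Parameters
    ----------
    curve : GasExchangeCurve
        Observations; needs ``Ci_ubar``, ``A_umol_m2_s`` and (optionally)
        ``I_umol_m2_s``, ``T_C``, ``Om_mbar`` columns.
    free : sequence of str
        Names from ``("Vpmax25", "Vcmax25", "Vpr", "Jmax25", "gm25")``.
    base_params : ParameterSet, optional
        Fixed values for everything not in ``free`` (defaults used if
        omitted).
    bounds, start : dict, optional
        Per-parameter box bounds and start values; defaults to
        :data:`DEFAULT_BOUNDS` and the ``base_params`` values.

    Notes
    -----
    Minimizes ``Σ (A_obs - A_model)²`` with the trust-region reflective
    algorithm; deterministic given the start point.  Approximate standard
    errors come from the Gauss–Newton curvature at the solution.
    Non-convergence is reported through ``converged``/``message``, never
    silently.
    """
    free = tuple(free)
    unknown = set(free) - set(FREE_PARAMETERS)
    if unknown:
        raise DomainError(f"not fittable: {sorted(unknown)}; choose from {FREE_PARAMETERS}")
    if not free:
        raise DomainError("free parameter set must be non-empty")

    data = curve.data
    for col in ("Ci_ubar", "A_umol_m2_s"):
        if col not in data.columns:
            raise DomainError(f"curve lacks required column {col!r}")
    n_obs = len(data)
    if n_obs < 2 * len(free):
        raise DomainError(
            f"need at least {2 * len(free)} rows to fit {len(free)} parameters, have {n_obs}"
        )

    base = base_params if base_params is not None else ParameterSet()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    start = dict(start or {})
    x0 = np.array([start.get(name, getattr(base, name)) for name in free], dtype=float)
    lower = np.array([bounds[name][0] for name in free])
    upper = np.array([bounds[name][1] for name in free])
    x0 = np.clip(x0, lower, upper)

    ci = data["Ci_ubar"].to_numpy(dtype=float)
    a_obs = data["A_umol_m2_s"].to_numpy(dtype=float)
    irr = (
        data["I_umol_m2_s"].to_numpy(dtype=float)
        if "I_umol_m2_s" in data.columns
        else np.full(n_obs, 2000.0)
    )
    temp = data["T_C"].to_numpy(dtype=float) if "T_C" in data.columns else np.full(n_obs, 25.0)
    om = data["Om_mbar"].to_numpy(dtype=float) if "Om_mbar" in data.columns else np.full(n_obs, 200.0)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _rebuild(base, dict(zip(free, x)))
        model = np.empty(n_obs)
        for i in range(n_obs):
            env = Environment(Ci=ci[i], Om=om[i], I=irr[i], T=temp[i])
            model[i] = net_assimilation(env, params, gm_mode=gm_mode).A
        return model - a_obs

    result = least_squares(
        residuals, x0, bounds=(lower, upper), method="trf", x_scale=np.abs(x0)
    )

    jac = result.jac
    # Normalize columns so the condition number measures collinearity, not scale.
    norms = np.linalg.norm(jac, axis=0)
    norms[norms == 0] = np.inf
    curvature = (jac / norms).T @ (jac / norms)
    condition = float(np.linalg.cond(curvature))
    weakly_identified = condition > CONDITION_LIMIT or np.any(norms == np.inf)
    if weakly_identified:
        warnings.warn(
            f"free parameters {free} are weakly identified by this design "
            f"(curvature condition number {condition:.3g})",
            WeakIdentifiabilityWarning,
            stacklevel=2,
        )

    rss = float(2.0 * result.cost)
    dof = max(n_obs - len(free), 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(jac.T @ jac)
        stderr = {name: float(np.sqrt(cov[i, i])) for i, name in enumerate(free)}
    except np.linalg.LinAlgError:
        stderr = {name: float("nan") for name in free}

    return FitResult(
        estimates={name: float(v) for name, v in zip(free, result.x)},
        stderr=stderr,
        rss=rss,
        converged=bool(result.success),
        weakly_identified=bool(weakly_identified),
        condition_number=condition,
        message=str(result.message),
        n_obs=n_obs,
    )
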