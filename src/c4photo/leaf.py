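"""Whole-leaf facade: temperature scaling, both limitations, gm coupling.

``net_assimilation`` is the single entry point for simulating one
gas-exchange observation: it temperature-adjusts the parameters, resolves
irradiance into electron transport, computes the enzyme-limited and
electron-transport-limited rates at the mesophyll CO2 pressure, applies
the minimum rule ``A = min(Ac, Aj)``, and (when mesophyll conductance is
finite) solves the diffusion coupling ``A = gm (Ci - Cm)`` for ``Cm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from . import electron_transport as et
from . import enzyme
from .errors import DegenerateInputError, DomainError, SolverError
from .parameters import AdjustedParameters, ParameterSet, adjust_to_temperature

LIMIT_ENZYME = "enzyme"
LIMIT_ELECTRON = "electron_transport"
LIMIT_COLIMITED = "co-limited"

#: |Ac - Aj| below which the limitation flag reads "co-limited".
COLIMITATION_TOL = 1e-3

#: Cm convergence tolerance for the gm coupling, µbar.
_CM_XTOL = 1e-8

GM_FINITE = "finite"
GM_INFINITE = "infinite"


@dataclass(frozen=True)
class Environment:
    """Environmental drivers for one simulation point.

    ``Ci`` is the intercellular CO2 partial pressure (µbar); with
    ``gm_mode="infinite"`` it is used directly as the mesophyll pressure
    ``Cm``.  ``Om`` is the O2 partial pressure (mbar; default 200, the
    common measurement condition), ``I`` the incident irradiance
    (µmol quanta m⁻² s⁻¹) and ``T`` the leaf temperature (°C).
    """

    Ci: float
    Om: float = 200.0
    I: float = 2000.0
    T: float = 25.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.Ci) or self.Ci < 0:
            raise DomainError(f"Ci must be non-negative, got {self.Ci}")
        if not math.isfinite(self.Om) or self.Om <= 0:
            raise DomainError(f"Om must be positive, got {self.Om}")
        if not math.isfinite(self.I) or self.I < 0:
            raise DomainError(f"I must be non-negative, got {self.I}")
        if not math.isfinite(self.T) or self.T <= -273.0:
            raise DomainError(f"T must exceed -273 °C, got {self.T}")


@dataclass(frozen=True)
class AssimilationState:
    """Net assimilation and diagnostics for one simulated point.

    ``phi`` (leakiness, L/Vp) and ``overcycling`` (L/A) are reported from
    the active limitation's internal state and are ``None`` when undefined
    (non-positive assimilation or zero PEP carboxylation).
    """

    A: float
    Ac: float
    Aj: float
    limitation: str
    Cm: float
    Cs: float
    Os: float
    Vp: float
    Vc: float
    Vo: float
    L: float
    phi: float | None
    overcycling: float | None
    J: float
    z: float
    rho: float


def _min_rule(
    Cm: float, Om: float, J: float, adj: AdjustedParameters
) -> tuple[enzyme.EnzymeLimitedState, et.LightLimitedState, float]:
    ec = enzyme.enzyme_limited_assimilation(Cm, Om, adj)
    lc = et.light_limited_assimilation(Cm, Om, J, adj)
    return ec, lc, min(ec.Ac, lc.Aj)


def net_assimilation(
    env: Environment, params: ParameterSet, gm_mode: str = GM_FINITE
) -> AssimilationState:
    """Simulate one observation.

    With ``gm_mode="infinite"`` the mesophyll CO2 equals ``Ci``; with
    ``"finite"`` the coupled system ``A(Cm) = gm (Ci - Cm)`` is solved
    numerically (the closed-form route leads to a cubic), bracketing ``Cm``
    in ``[0, Ci]`` and extending above ``Ci`` below the compensation point,
    where respiratory efflux makes ``Cm > Ci``.
    """
    if gm_mode not in (GM_FINITE, GM_INFINITE):
        raise DomainError(f"gm_mode must be 'finite' or 'infinite', got {gm_mode!r}")
    adj = adjust_to_temperature(params, env.T)
    light = et.light_reactions(env.I, adj)
    J = light.J

    if gm_mode == GM_INFINITE:
        Cm = env.Ci
    else:
        def mismatch(cm: float) -> float:
            _, _, A = _min_rule(cm, env.Om, J, adj)
            return A - adj.gm * (env.Ci - cm)

        lo, hi = 0.0, max(env.Ci, 1e-9)
        try:
            f_hi = mismatch(hi)
            if f_hi < 0.0:
                # Below compensation: net efflux, Cm exceeds Ci.
                hi = env.Ci + (adj.Rd + adj.Rm + 1.0) / adj.gm
                f_hi = mismatch(hi)
            f_lo = mismatch(lo)
            if f_lo == 0.0:
                Cm = lo
            elif f_hi == 0.0:
                Cm = hi
            elif f_lo * f_hi > 0.0:
                raise SolverError(
                    f"gm coupling not bracketed on Cm ∈ [{lo:.3g}, {hi:.3g}] "
                    f"(f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g})"
                )
            else:
                Cm = brentq(mismatch, lo, hi, xtol=_CM_XTOL)
        except DegenerateInputError as exc:
            raise SolverError(f"gm coupling failed: {exc}") from exc

    ec, lc, A = _min_rule(Cm, env.Om, J, adj)
    diff = ec.Ac - lc.Aj
    if abs(diff) < COLIMITATION_TOL:
        limitation = LIMIT_COLIMITED
        winner: enzyme.EnzymeLimitedState | et.LightLimitedState = ec
    elif diff < 0:
        limitation = LIMIT_ENZYME
        winner = ec
    else:
        limitation = LIMIT_ELECTRON
        winner = lc

    Vp = winner.Vp
    L = winner.L
    phi = L / Vp if (A > 0 and Vp > 0) else None
    over = L / A if A != 0 else None
    return AssimilationState(
        A=A, Ac=ec.Ac, Aj=lc.Aj, limitation=limitation, Cm=Cm,
        Cs=winner.Cs, Os=winner.Os, Vp=Vp, Vc=winner.Vc, Vo=winner.Vo, L=L,
        phi=phi, overcycling=over, J=J, z=adj.z, rho=adj.rho,
    )


def initial_slope(gm: float, Vpmax: float, Kp: float) -> float:
    """Initial slope of the A–Ci curve, ``dA/dCi = gm·Vpmax/(gm·Kp + Vpmax)``
    (mol m⁻² s⁻¹ bar⁻¹).

    The finite mesophyll conductance flattens the slope below the
    PEPC-only value ``Vpmax/Kp``; reading the flattened slope as if gm were
    infinite underestimates the apparent ``Vpmax``.
    """
    if gm <= 0 or Vpmax <= 0 or Kp <= 0:
        raise DomainError("gm, Vpmax and Kp must be positive")
    return gm * Vpmax / (gm * Kp + Vpmax)


def lowco2_assimilation_with_gm(Ci: float, adj: AdjustedParameters) -> float:
    """Initial-slope approximation with gm coupling, valid at low ``Ci``.

    Combines the PEPC Michaelis–Menten supply (without the ``gbs·Cm`` term
    or the ``Vpr`` cap) with ``A = gm (Ci - Cm)``, giving a quadratic

        ``A² - A (gm [Ci + Kp] + Vpmax - Rm) + gm (Vpmax·Ci - Rm [Ci + Kp]) = 0``

    whose smaller root is the physical branch (its derivative at Ci = 0
    equals :func:`initial_slope`).
    """
    if Ci < 0:
        raise DomainError(f"Ci must be non-negative, got {Ci}")
    S = adj.gm * (Ci + adj.Kp) + adj.Vpmax - adj.Rm
    c = adj.gm * (adj.Vpmax * Ci - adj.Rm * (Ci + adj.Kp))
    disc = S * S - 4.0 * c
    if disc < 0:
        raise DegenerateInputError(
            f"low-CO2 quadratic: negative discriminant at Ci={Ci}"
        )
    return (S - math.sqrt(disc)) / 2.0
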