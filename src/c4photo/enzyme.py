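"""Enzyme-limited (high-irradiance) CO2 assimilation.

At saturating light the C4 assimilation rate is set by the co-operation of
three processes: PEP carboxylase supply of C4 acids in the mesophyll,
RuBP-saturated Rubisco carboxylation/oxygenation in the bundle sheath, and
diffusive CO2 leak back across the bundle-sheath wall.  Balancing the
mesophyll flux equation (A = Vp - L - Rm) against the bundle-sheath demand
equation (A = Vc - 0.5 Vo - Rd), with the leak tied to the bundle-sheath
CO2 pressure and O2 build-up tied to bundle-sheath PSII activity, yields a
quadratic in the net rate ``Ac``.

Unit conventions follow :mod:`c4photo.parameters`: CO2 pressures in µbar,
O2 pressures in mbar at the interfaces.  All γ*·O products are formed after
converting O2 to µbar, so the photorespiratory compensation pressure
Γ* = γ*·Os emerges in µbar (≈76 µbar at 200 mbar O2 with defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateInputError, DomainError, InfeasibleError
from .parameters import AdjustedParameters

#: Conversion factor between mbar (O2 interfaces) and µbar (internal algebra).
UBAR_PER_MBAR = 1000.0

#: Coefficient magnitude below which the quadratic falls back to linear.
_LINEAR_EPS = 1e-12

VP_CARBOXYLATION = "carboxylation"
VP_REGENERATION = "regeneration"


def solve_printed_quadratic(a: float, b: float, c: float, context: str) -> float:
    """Root of ``a x² + b x + c = 0`` in the ``(-b + sqrt(disc)) / (2a)`` form.

    Falls back to the linear root ``-c/b`` when ``|a|`` is negligible, and
    raises :class:`DegenerateInputError` on a negative discriminant.
    """
    if abs(a) < _LINEAR_EPS:
        if abs(b) < _LINEAR_EPS:
            raise DegenerateInputError(f"{context}: degenerate quadratic (a≈0, b≈0)")
        return -c / b
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        # A double root (exact co-limitation) can land a rounding error
        # below zero; only a genuinely negative discriminant is an error.
        scale = max(b * b, abs(4.0 * a * c), 1.0)
        if disc > -1e-12 * scale:
            disc = 0.0
        else:
            raise DegenerateInputError(
                f"{context}: negative discriminant ({disc:.6g}) "
                f"for a={a:.6g}, b={b:.6g}, c={c:.6g}"
            )
    return (-b + math.sqrt(disc)) / (2.0 * a)


@dataclass(frozen=True)
class EnzymeLimitedState:
    """Co-solved fluxes and pressures of the enzyme-limited branch."""

    Ac: float   # net assimilation, µmol m⁻² s⁻¹
    Vp: float   # PEP carboxylation, µmol m⁻² s⁻¹
    Vc: float   # Rubisco carboxylation, µmol m⁻² s⁻¹
    Vo: float   # Rubisco oxygenation, µmol m⁻² s⁻¹
    Cs: float   # bundle-sheath CO2, µbar
    Os: float   # bundle-sheath O2, mbar
    L: float    # leak rate, µmol m⁻² s⁻¹
    vp_limited_by: str  # "carboxylation" | "regeneration"


def pep_carboxylation_rate(
    Cm: float, Vpmax: float, Kp: float, Vpr: float
) -> tuple[float, str]:
    """PEP carboxylation rate: min of Michaelis–Menten supply and ``Vpr``.

    Returns ``(Vp, flag)`` where the flag names the active branch; ties
    resolve to ``"regeneration"`` for deterministic labelling.
    """
    if Cm < 0:
        raise DomainError(f"Cm must be non-negative, got {Cm}")
    if Vpmax <= 0 or Kp <= 0 or Vpr <= 0:
        raise DomainError("Vpmax, Kp and Vpr must be positive")
    mm = Cm * Vpmax / (Cm + Kp) if Cm > 0 else 0.0
    if mm < Vpr:
        return mm, VP_CARBOXYLATION
    return Vpr, VP_REGENERATION


def bundle_sheath_o2(
    A: float, alpha: float, ao: float, gbs: float, Om: float
) -> float:
    """Bundle-sheath O2 partial pressure (mbar).

    O2 evolved by bundle-sheath PSII (a fraction ``alpha`` of net
    assimilation) must leak out through the O2 conductance ``ao * gbs``,
    raising the internal pressure above the mesophyll value ``Om``.
    """
    if ao <= 0 or gbs <= 0:
        raise DomainError("ao and gbs must be positive")
    return alpha * A / (ao * gbs) / UBAR_PER_MBAR + Om


def leak_rate(gbs: float, Cs: float, Cm: float) -> float:
    """CO2 leak out of the bundle sheath, ``gbs * (Cs - Cm)``.

    Negative values indicate inward diffusion (Cs < Cm).
    """
    if gbs <= 0:
        raise DomainError(f"gbs must be positive, got {gbs}")
    return gbs * (Cs - Cm)


def enzyme_limited_assimilation(
    Cm: float, Om: float, adj: AdjustedParameters
) -> EnzymeLimitedState:
    """Solve the enzyme-limited quadratic for the net assimilation rate.

    The returned state satisfies the mesophyll and bundle-sheath flux
    balances simultaneously: ``Ac = Vp - L - Rm`` and
    ``Ac = Vc - 0.5 Vo - Rd``, with ``Cs`` from the leak balance and ``Os``
    from the bundle-sheath O2 balance.  ``Ac`` may be negative below the
    compensation point.
    """
    if Cm < 0:
        raise DomainError(f"Cm must be non-negative, got {Cm}")
    if Om <= 0:
        raise DomainError(f"Om must be positive, got {Om}")

    Vp, flag = pep_carboxylation_rate(Cm, adj.Vpmax, adj.Kp, adj.Vpr)

    Om_ub = Om * UBAR_PER_MBAR
    Ko_ub = adj.Ko * UBAR_PER_MBAR
    P = Vp - adj.Rm + adj.gbs * Cm
    K = adj.gbs * adj.Kc * (1.0 + Om_ub / Ko_ub)
    beta = adj.alpha * adj.Kc / (adj.ao * Ko_ub)

    a = beta - 1.0
    b = (
        P
        + K
        + (adj.Vcmax - adj.Rd)
        + beta * adj.Rd
        + adj.gamma_star * adj.alpha * adj.Vcmax / adj.ao
    )
    c = adj.Rd * (P + K) - adj.Vcmax * (P - adj.gamma_star * adj.gbs * Om_ub)

    Ac = solve_printed_quadratic(a, b, c, "enzyme-limited assimilation")

    Os = bundle_sheath_o2(Ac, adj.alpha, adj.ao, adj.gbs, Om)
    Cs = Cm + (Vp - Ac - adj.Rm) / adj.gbs
    Os_ub = Os * UBAR_PER_MBAR
    if Cs > 0:
        # 0.5 Vo / Vc; the back-calculation of Vc remains valid above 1
        # (below the compensation point both numerator and denominator flip).
        photoresp_ratio = adj.gamma_star * Os_ub / Cs
        if photoresp_ratio == 1.0:
            Vc = float("inf")
        else:
            Vc = (Ac + adj.Rd) / (1.0 - photoresp_ratio)
        Vo = 2.0 * photoresp_ratio * Vc
    else:
        Vc = 0.0
        Vo = 0.0
    L = leak_rate(adj.gbs, Cs, Cm)
    return EnzymeLimitedState(Ac=Ac, Vp=Vp, Vc=Vc, Vo=Vo, Cs=Cs, Os=Os, L=L, vp_limited_by=flag)


def enzyme_limited_lowco2_approx(Cm: float, adj: AdjustedParameters) -> float:
    """Low-CO2 approximation: PEPC Michaelis–Menten supply minus mesophyll
    respiration plus the (small) inward bundle-sheath diffusion ``gbs*Cm``."""
    if Cm < 0:
        raise DomainError(f"Cm must be non-negative, got {Cm}")
    return Cm * adj.Vpmax / (Cm + adj.Kp) - adj.Rm + adj.gbs * Cm


def bundle_sheath_co2_from_rubisco(
    A: float, Os: float, adj: AdjustedParameters
) -> float:
    """Invert the Rubisco rate equation for the bundle-sheath CO2 pressure.

    Given a net assimilation rate ``A`` and bundle-sheath O2 ``Os`` (mbar),
    returns the ``Cs`` (µbar) at which RuBP-saturated Rubisco would produce
    exactly ``A``:

        ``Cs = (γ*·Os + Kc (1 + Os/Ko) r) / (1 - r)``,  r = (A + Rd)/Vcmax.

    Raises :class:`InfeasibleError` when the demanded carboxylation reaches
    or exceeds capacity (``r >= 1``).
    """
    ratio = (A + adj.Rd) / adj.Vcmax
    if ratio >= 1.0:
        raise InfeasibleError(
            f"(A + Rd)/Vcmax = {ratio:.4g} >= 1: demanded carboxylation exceeds capacity"
        )
    Os_ub = Os * UBAR_PER_MBAR
    numerator = adj.gamma_star * Os_ub + adj.Kc * (1.0 + Os / adj.Ko) * ratio
    return numerator / (1.0 - ratio)
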