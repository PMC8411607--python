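"""Light capture, electron flow stoichiometry, and light-limited assimilation.

The chloroplast electron chain is modelled as a pooled whole-leaf resource:
linear (whole-chain) flow ``J`` produces NADPH and, together with cyclic
flow around PSI, protons and hence ATP.  With ``f_cyc`` the fraction of PSI
electron flow that is cyclic and ``h`` protons per ATP, each linear
electron yields ``z = (3 - f_cyc) / (h (1 - f_cyc))`` ATP.  A fraction
``x`` of the ATP supports PEP regeneration (the C4 cycle), the remainder
the C3 cycle.  Balancing the two ATP sinks against the mesophyll and
bundle-sheath flux equations yields a quadratic in the light-limited net
rate ``Aj``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import minimize_scalar

from .enzyme import UBAR_PER_MBAR, bundle_sheath_o2, leak_rate, solve_printed_quadratic
from .errors import DomainError
from .parameters import AdjustedParameters

BRANCH_C4 = "c4_cycle"
BRANCH_C3 = "c3_cycle"


def atp_per_electron(f_cyc: float, h: float) -> float:
    """ATP produced per linear electron, ``z = (3 - f_cyc)/(h (1 - f_cyc))``.

    With ``h = 4``: 0.75 without cyclic flow, 1.25 when half of PSI flow is
    cyclic.
    """
    if not 0.0 <= f_cyc < 1.0:
        raise DomainError(f"f_cyc must lie in [0, 1), got {f_cyc}")
    if h <= 0:
        raise DomainError(f"h must be positive, got {h}")
    return (3.0 - f_cyc) / (h * (1.0 - f_cyc))


def psii_light_fraction(f_cyc: float) -> float:
    """Fraction of absorbed quanta allocated to PSII, ``(1-f_cyc)/(2-f_cyc)``."""
    if not 0.0 <= f_cyc < 1.0:
        raise DomainError(f"f_cyc must lie in [0, 1), got {f_cyc}")
    return (1.0 - f_cyc) / (2.0 - f_cyc)


def useful_irradiance(
    I: float, absorptance: float, f_spectral: float, rho: float
) -> float:
    """PSII-useful absorbed irradiance ``I2 = I · absorptance · ρ · (1 - f)``."""
    if I < 0:
        raise DomainError(f"I must be non-negative, got {I}")
    return I * absorptance * rho * (1.0 - f_spectral)


def electron_transport_rate(I2: float, Jmax: float, theta: float) -> float:
    """Potential linear electron transport from the non-rectangular hyperbola.

    Smaller root of ``θJ² - J(I2 + Jmax) + I2·Jmax = 0`` (the larger root
    exceeds ``Jmax``).  Evaluated in the numerically stable form
    ``2 I2 Jmax / (S + sqrt(S² - 4θ I2 Jmax))`` which passes continuously
    into the rectangular-hyperbola limit at ``θ = 0``.
    """
    if I2 < 0:
        raise DomainError(f"I2 must be non-negative, got {I2}")
    if Jmax <= 0:
        raise DomainError(f"Jmax must be positive, got {Jmax}")
    if not 0.0 <= theta <= 1.0:
        raise DomainError(f"theta must lie in [0, 1], got {theta}")
    S = I2 + Jmax
    disc = S * S - 4.0 * theta * I2 * Jmax
    return 2.0 * I2 * Jmax / (S + math.sqrt(disc))


@dataclass(frozen=True)
class LightReactionState:
    """Electron-flow bookkeeping for one irradiance."""

    I: float      # incident irradiance, µmol quanta m⁻² s⁻¹
    I2: float     # PSII-useful absorbed irradiance
    J: float      # linear (whole-chain) electron transport, µmol e⁻ m⁻² s⁻¹
    J1: float     # PSI electron flow
    Jcyc: float   # cyclic flow
    JH: float     # proton production, µmol H⁺ m⁻² s⁻¹
    JATP: float   # ATP production, µmol ATP m⁻² s⁻¹
    z: float      # JATP / J
    rho: float    # PSII light fraction
    Jm: float     # allocation to the C4 cycle, x·J
    Js: float     # allocation to the C3 cycle, (1-x)·J


def light_reactions(I: float, adj: AdjustedParameters) -> LightReactionState:
    """Resolve irradiance into linear/cyclic electron flows and ATP supply."""
    I2 = useful_irradiance(I, adj.absorptance, adj.f_spectral, adj.rho)
    J = electron_transport_rate(I2, adj.Jmax, adj.theta)
    J1 = J / (1.0 - adj.f_cyc)
    JH = J * (3.0 - adj.f_cyc) / (1.0 - adj.f_cyc)
    return LightReactionState(
        I=I, I2=I2, J=J, J1=J1, Jcyc=J1 - J, JH=JH, JATP=JH / adj.h,
        z=adj.z, rho=adj.rho, Jm=adj.x * J, Js=(1.0 - adj.x) * J,
    )


@dataclass(frozen=True)
class LightLimitedState:
    """Co-solved fluxes and pressures of the electron-transport-limited branch."""

    Aj: float
    Vp: float
    Vc: float
    Vo: float
    Cs: float
    Os: float
    L: float
    atp_rate: float
    nadph_rate: float


def energy_budget(
    Vc: float, Vp: float, Cs: float, Os: float, gamma_star: float
) -> tuple[float, float]:
    """ATP and NADPH consumption rates of the combined C3 + C4 cycles.

    ATP: 2 per PEP regenerated plus ``(3 + 7 γ*Os/Cs)`` per Rubisco
    carboxylation (the γ* term is the photorespiratory surcharge).
    NADPH: ``(2 + 4 γ*Os/Cs)`` per carboxylation.  ``Os`` in mbar is
    converted to µbar before forming the γ* products.
    """
    if Cs <= 0:
        raise DomainError(f"Cs must be positive, got {Cs}")
    r = gamma_star * Os * UBAR_PER_MBAR / Cs
    return 2.0 * Vp + (3.0 + 7.0 * r) * Vc, (2.0 + 4.0 * r) * Vc


def light_limited_assimilation(
    Cm: float, Om: float, J: float, adj: AdjustedParameters
) -> LightLimitedState:
    """Solve the electron-transport-limited quadratic for the net rate ``Aj``.

    The ATP supply ``z·J`` is split ``x : (1-x)`` between PEP regeneration
    (``Vp = z·x·J/2``) and the C3 cycle; the bundle-sheath CO2 and O2
    pressures adjust so that the mesophyll flux balance and the
    photorespiration-corrected C3 demand agree simultaneously.
    """
    if J < 0:
        raise DomainError(f"J must be non-negative, got {J}")
    if Cm < 0:
        raise DomainError(f"Cm must be non-negative, got {Cm}")
    if Om <= 0:
        raise DomainError(f"Om must be positive, got {Om}")

    Om_ub = Om * UBAR_PER_MBAR
    Q4 = adj.z * adj.x * J / 2.0          # ATP-limited PEP carboxylation
    Q3 = adj.z * (1.0 - adj.x) * J / 3.0  # ATP-limited Rubisco carboxylation
    Pj = Q4 - adj.Rm + adj.gbs * Cm
    gs_ = adj.gamma_star

    a = 7.0 * gs_ * adj.alpha / (3.0 * adj.ao) - 1.0
    b = (
        Pj
        + Q3
        - adj.Rd
        + (7.0 / 3.0) * gs_ * adj.gbs * Om_ub
        + (gs_ * adj.alpha / adj.ao) * (Q3 + (7.0 / 3.0) * adj.Rd)
    )
    c = (
        adj.Rd * Pj
        - Q3 * Pj
        + gs_ * adj.gbs * Om_ub * (Q3 + (7.0 / 3.0) * adj.Rd)
    )

    Aj = solve_printed_quadratic(a, b, c, "light-limited assimilation")

    Os = bundle_sheath_o2(Aj, adj.alpha, adj.ao, adj.gbs, Om)
    Os_ub = Os * UBAR_PER_MBAR
    # Bundle-sheath CO2 from the C3-side relation when defined, else from
    # the mesophyll balance (both hold at the root; the former degenerates
    # when gamma_star -> 0).
    denom = Q3 - (Aj + adj.Rd)
    if gs_ > 0.0 and denom > 0.0:
        Cs = gs_ * Os_ub * ((7.0 / 3.0) * (Aj + adj.Rd) + Q3) / denom
    else:
        Cs = Cm + (Q4 - adj.Rm - Aj) / adj.gbs

    if Cs > 0:
        r = gs_ * Os_ub / Cs
        Vc = Q3 / (1.0 + 7.0 * r / 3.0)
        Vo = 2.0 * r * Vc
        atp_rate, nadph_rate = energy_budget(Vc, Q4, Cs, Os, gs_)
    else:
        Vc = Vo = 0.0
        atp_rate = 2.0 * Q4 + 3.0 * Q3
        nadph_rate = 2.0 * Q3
    L = leak_rate(adj.gbs, Cs, Cm) if Cs != Cm else 0.0
    return LightLimitedState(
        Aj=Aj, Vp=Q4, Vc=Vc, Vo=Vo, Cs=Cs, Os=Os, L=L,
        atp_rate=atp_rate, nadph_rate=nadph_rate,
    )


def light_limited_approx(
    Cm: float, J: float, adj: AdjustedParameters
) -> tuple[float, str]:
    """Photorespiration-free approximation: min of the two ATP branches.

    Returns ``(Aj, branch)`` with branch ``"c4_cycle"`` when PEP
    regeneration limits and ``"c3_cycle"`` when the C3 cycle limits; ties
    resolve to ``"c3_cycle"``.
    """
    c4 = adj.z * adj.x * J / 2.0 - adj.Rm + adj.gbs * Cm
    c3 = adj.z * (1.0 - adj.x) * J / 3.0 - adj.Rd
    if c4 < c3:
        return c4, BRANCH_C4
    return c3, BRANCH_C3


def optimal_partitioning(
    Cm: float, Om: float, I: float, adj: AdjustedParameters
) -> float:
    """Electron-transport partitioning fraction that maximizes ``Aj``.

    Bounded scalar search over ``x ∈ [0, 1]`` at the ``J`` implied by the
    irradiance ``I`` (tolerance 1e-4).  In the photorespiration- and
    respiration-free limit the optimum is exactly 0.4 (two of five ATP to
    the C4 cycle).
    """
    J = light_reactions(I, adj).J

    def negative_aj(x: float) -> float:
        return -light_limited_assimilation(Cm, Om, J, replace(adj, x=x)).Aj

    result = minimize_scalar(
        negative_aj, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(result.x)
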