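"""Independent oracles for the quadratic solutions.

Each oracle solves the simultaneity system behind a quadratic by
bracketing bisection on the scalar residual (demand-side rate minus trial
rate), never touching the closed-form coefficients.  The physical root is
the one with non-negative bundle-sheath CO2, i.e. the root below the
supply ceiling ``Vp - Rm + gbs*Cm``; the scan starts at that ceiling and
expands downward.
"""

from __future__ import annotations

from scipy.optimize import brentq

from c4photo.parameters import AdjustedParameters

UBAR_PER_MBAR = 1000.0


def _bracketed_root(residual, hi: float) -> float:
    """Root of ``residual`` on (-inf, hi], scanning down for a sign change."""
    f_hi = residual(hi)
    if f_hi == 0.0:
        return hi
    if f_hi > 0.0:
        # Supply ceiling not binding from above; expand upward instead.
        lo, f_lo = hi, f_hi
        step = 1.0
        for _ in range(200):
            hi = lo + step
            f_hi = residual(hi)
            if f_lo * f_hi <= 0:
                return brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
            lo, f_lo = hi, f_hi
            step *= 1.5
        raise RuntimeError("oracle failed to bracket (upward)")
    lo = hi - 1.0
    step = 1.0
    for _ in range(300):
        if residual(lo) > 0.0:
            return brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
        lo -= step
        step *= 1.5
    raise RuntimeError("oracle failed to bracket (downward)")


def enzyme_oracle(Cm: float, Om: float, adj: AdjustedParameters) -> float:
    """Enzyme-limited net rate from the PEPC/Rubisco/leak balance system."""
    mm = Cm * adj.Vpmax / (Cm + adj.Kp) if Cm > 0 else 0.0
    Vp = min(mm, adj.Vpr)
    Om_ub = Om * UBAR_PER_MBAR
    Ko_ub = adj.Ko * UBAR_PER_MBAR

    def residual(A: float) -> float:
        Os_ub = adj.alpha * A / (adj.ao * adj.gbs) + Om_ub
        Cs = Cm + (Vp - A - adj.Rm) / adj.gbs
        denom = Cs + adj.Kc * (1.0 + Os_ub / Ko_ub)
        if denom <= 0.0:
            return -1e12 - A
        rubisco = (Cs - adj.gamma_star * Os_ub) * adj.Vcmax / denom - adj.Rd
        return rubisco - A

    return _bracketed_root(residual, Vp - adj.Rm + adj.gbs * Cm)


def light_oracle(Cm: float, Om: float, J: float, adj: AdjustedParameters) -> float:
    """Light-limited net rate from the two ATP-branch balance equations."""
    Q4 = adj.z * adj.x * J / 2.0
    Q3 = adj.z * (1.0 - adj.x) * J / 3.0
    Om_ub = Om * UBAR_PER_MBAR

    def residual(A: float) -> float:
        Os_ub = adj.alpha * A / (adj.ao * adj.gbs) + Om_ub
        Cs = Cm + (Q4 - adj.Rm - A) / adj.gbs
        if Cs <= 1e-12:
            return -1e12 - A
        r = adj.gamma_star * Os_ub / Cs
        c3 = (1.0 - r) * Q3 / (1.0 + 7.0 * r / 3.0) - adj.Rd
        return c3 - A

    return _bracketed_root(residual, Q4 - adj.Rm + adj.gbs * Cm)


def lowco2_gm_oracle(Ci: float, adj: AdjustedParameters) -> float:
    """Initial-slope system: PEPC Michaelis-Menten supply (no Vpr cap, no
    bundle-sheath inward diffusion) balanced against mesophyll diffusion."""

    def residual(Cm: float) -> float:
        supply = Cm * adj.Vpmax / (Cm + adj.Kp) - adj.Rm
        return supply - adj.gm * (Ci - Cm)

    hi = max(Ci, 1.0) + (adj.Rm + 1.0) / adj.gm
    Cm = brentq(residual, 0.0, hi, xtol=1e-12)
    return adj.gm * (Ci - Cm)
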