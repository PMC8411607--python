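"""Inverse diagnostics: electron transport and C4-cycle fluxes from data.

Two back-calculations supported by the model:

* ``actual_electron_transport`` — the linear electron flow ``Ja`` needed
  to sustain a *measured* CO2 assimilation rate at known ``Cm``;
* ``c4_cycle_from_leakiness`` — the PEP carboxylation rate, leak rate and
  bundle-sheath CO2 implied by a measured assimilation rate and an
  isotope-derived leakiness ϕ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .electron_transport import light_limited_assimilation
from .enzyme import UBAR_PER_MBAR
from .errors import DomainError, InfeasibleError
from .parameters import AdjustedParameters, ParameterSet, adjust_to_temperature

#: Round-trip acceptance for the Ja root, µmol m⁻² s⁻¹.
_ROUNDTRIP_TOL = 1e-6


@dataclass(frozen=True)
class LeakinessFluxes:
    """C4-cycle fluxes recovered from a (A, ϕ) measurement."""

    Vp: float  # PEP carboxylation, µmol m⁻² s⁻¹
    L: float   # leak rate, µmol m⁻² s⁻¹
    Cs: float  # bundle-sheath CO2, µbar


def actual_electron_transport(
    A: float, Cm: float, Om: float, adj: AdjustedParameters
) -> float:
    """Linear electron transport ``Ja`` sustaining a measured rate ``A``.

    Solves the light-limited system for ``J`` at fixed ``A``: with ``A``
    known, the bundle-sheath O2 pressure is fixed and the bundle-sheath
    CO2 is linear in ``J``, so the system collapses to a quadratic in
    ``J``.  The returned root is validated by the round trip
    ``Aj(Ja) == A``; if the printed root form fails the round trip but the
    companion root passes, the companion is returned with a warning.
    """
    if A <= -adj.Rd:
        raise DomainError(f"A must exceed -Rd = {-adj.Rd:.4g}, got {A}")
    if Cm < 0:
        raise DomainError(f"Cm must be non-negative, got {Cm}")

    Om_ub = Om * UBAR_PER_MBAR
    z, x = adj.z, adj.x
    W = adj.gbs * Cm - adj.Rm - A
    G = adj.gbs * Om_ub + adj.alpha * A / adj.ao  # gbs * Os in µbar

    a = z * z * x * (1.0 - x) / 6.0
    b = (z * (1.0 - x) / 3.0) * (W - adj.gamma_star * G) - (z * x / 2.0) * (A + adj.Rd)
    c = -(A + adj.Rd) * (W + (7.0 / 3.0) * adj.gamma_star * G)

    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise InfeasibleError(
            f"A = {A} is unattainable at any electron transport rate "
            f"(negative discriminant)"
        )
    sqrt_disc = math.sqrt(disc)
    printed = (-b + sqrt_disc) / (2.0 * a)
    companion = (-b - sqrt_disc) / (2.0 * a)

    def roundtrip_error(J: float) -> float:
        if not (J >= 0 and math.isfinite(J)):
            return float("inf")
        return abs(light_limited_assimilation(Cm, Om, J, adj).Aj - A)

    if roundtrip_error(printed) < _ROUNDTRIP_TOL:
        return printed
    if roundtrip_error(companion) < _ROUNDTRIP_TOL:
        warnings.warn(
            "printed Ja root failed the forward round trip; using companion root",
            stacklevel=2,
        )
        return companion
    raise InfeasibleError(
        f"no Ja root reproduces A = {A} within {_ROUNDTRIP_TOL} "
        f"(roots {printed:.6g}, {companion:.6g})"
    )


def c4_cycle_from_leakiness(
    A: float, phi: float, Cm: float, adj: AdjustedParameters
) -> LeakinessFluxes:
    """C4-cycle fluxes from measured assimilation and leakiness.

    ``Vp = (A + Rm)/(1 - ϕ)`` restores the mesophyll flux balance exactly;
    ``L = ϕ·Vp`` and ``Cs = Cm + L/gbs`` follow from the definitions of
    leakiness and of the diffusive leak.
    """
    if not 0.0 <= phi < 1.0:
        raise DomainError(f"phi must lie in [0, 1), got {phi}")
    Vp = (A + adj.Rm) / (1.0 - phi)
    L = phi * Vp
    return LeakinessFluxes(Vp=Vp, L=L, Cs=Cm + L / adj.gbs)


def overcycling(L: float, A: float) -> float:
    """Leak rate as a fraction of net assimilation, ``L/A``.

    Equivalently ``(Vp - (A + Rm))/A``: the fractional excess of C4-cycle
    turnover over net fixation.
    """
    if A == 0:
        raise DomainError("overcycling is undefined at A = 0")
    return L / A


def process_measurements(
    table: pd.DataFrame, params: ParameterSet
) -> pd.DataFrame:
    """Augment a measured gas-exchange table with inverse diagnostics.

    Expects columns ``A_umol_m2_s``, ``I_umol_m2_s``, ``T_C``, ``Om_mbar``
    (optional, default 200), and either ``Cm_ubar`` or ``Ci_ubar`` (the
    latter converted through ``A = gm (Ci - Cm)``).  Adds ``Ja``; when a
    ``phi`` column is present also adds ``Vp``, ``L``, ``Cs_ubar`` and
    ``overcycling``.  Unknown columns are preserved.
    """
    required = {"A_umol_m2_s", "T_C"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"missing required columns: {sorted(missing)}")
    if "Cm_ubar" not in table.columns and "Ci_ubar" not in table.columns:
        raise DomainError("need a Cm_ubar or Ci_ubar column")

    out = table.copy()
    ja, vp, leak, cs, over = [], [], [], [], []
    for idx, row in out.iterrows():
        T = float(row["T_C"])
        adj = adjust_to_temperature(params, T)
        A = float(row["A_umol_m2_s"])
        Om = float(row["Om_mbar"]) if "Om_mbar" in out.columns else 200.0
        if "Cm_ubar" in out.columns and pd.notna(row.get("Cm_ubar")):
            Cm = float(row["Cm_ubar"])
        else:
            Cm = float(row["Ci_ubar"]) - A / adj.gm
        try:
            ja.append(actual_electron_transport(A, Cm, Om, adj))
        except (DomainError, InfeasibleError) as exc:
            raise InfeasibleError(f"row {idx}: {exc}") from exc
        if "phi" in out.columns and pd.notna(row.get("phi")):
            fluxes = c4_cycle_from_leakiness(A, float(row["phi"]), Cm, adj)
            vp.append(fluxes.Vp)
            leak.append(fluxes.L)
            cs.append(fluxes.Cs)
            over.append(overcycling(fluxes.L, A) if A != 0 else float("nan"))
        else:
            vp.append(float("nan"))
            leak.append(float("nan"))
            cs.append(float("nan"))
            over.append(float("nan"))
    out["Ja"] = ja
    if "phi" in out.columns:
        out["Vp"] = vp
        out["L"] = leak
        out["Cs_ubar"] = cs
        out["overcycling"] = over
    return out
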