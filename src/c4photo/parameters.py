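"""Kinetic parameters of the C4 leaf model and their temperature responses.

The default parameter set describes *Setaria viridis* (NADP-ME type) at
25 °C.  Enzyme kinetic constants and respiration follow a simple Arrhenius
response parameterized by an activation energy per quantity; maximal
electron transport follows a Gaussian function of leaf temperature peaking
at ``To``; bundle-sheath conductance ``gbs`` and the PEP-regeneration
ceiling ``Vpr`` are temperature invariant.

Unit conventions (used throughout the package):

* CO2 partial pressures and CO2 Michaelis constants in µbar,
* O2 partial pressures and ``Ko`` in mbar,
* fluxes in µmol m⁻² s⁻¹,
* conductances in mol m⁻² s⁻¹ bar⁻¹ (so conductance × µbar = µmol m⁻² s⁻¹).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import ConfigError, DomainError

#: Universal gas constant, J K⁻¹ mol⁻¹.
R_GAS = 8.314

#: Activation energies (kJ mol⁻¹) of the temperature-dependent quantities.
ACTIVATION_ENERGIES_KJ = {
    "Vcmax": 78.0,
    "Kc": 64.2,
    "Ko": 10.5,
    "gamma_star": 31.1,
    "Vpmax": 50.1,
    "Kp": 38.3,
    "Rd": 66.4,
    "ao": 1.63,
    "gm": 49.8,
}


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    return value


def arrhenius_scale(value25: float, energy_kj: float, temperature: float) -> float:
    """Scale a quantity from 25 °C to ``temperature`` with an Arrhenius response.

    Parameters
    ----------
    value25 : float
        Value of the quantity at 25 °C (must be positive).
    energy_kj : float
        Activation energy in kJ mol⁻¹ (converted to J mol⁻¹ internally).
    temperature : float
        Leaf temperature in °C (must exceed absolute zero).

    Returns
    -------
    float
        ``value25 * exp[(T - 25) * E / (298 * R * (273 + T))]``.

    Notes
    -----
    The exponent is zero at 25 °C, and the response is monotone increasing
    in temperature for positive activation energies.
    """
    value25 = _require_finite("value25", value25)
    energy_kj = _require_finite("energy_kj", energy_kj)
    temperature = _require_finite("temperature", temperature)
    if value25 <= 0:
        raise DomainError(f"value25 must be positive, got {value25}")
    if temperature <= -273.0:
        raise DomainError(f"temperature must exceed -273 °C, got {temperature}")
    exponent = (temperature - 25.0) * (energy_kj * 1000.0) / (
        298.0 * R_GAS * (273.0 + temperature)
    )
    return value25 * math.exp(exponent)


def jmax_at_temperature(
    jmax_opt: float, t_opt: float, omega: float, temperature: float
) -> float:
    """Gaussian temperature response of maximal electron transport.

    ``Jmax(T) = Jmax(To) * exp(-((T - To)/Ω)²)``; ``Ω`` is the temperature
    offset from the optimum at which ``Jmax`` has fallen to 1/e of its peak.
    """
    jmax_opt = _require_finite("jmax_opt", jmax_opt)
    t_opt = _require_finite("t_opt", t_opt)
    omega = _require_finite("omega", omega)
    temperature = _require_finite("temperature", temperature)
    if jmax_opt <= 0:
        raise DomainError(f"jmax_opt must be positive, got {jmax_opt}")
    if omega <= 0:
        raise DomainError(f"omega must be positive, got {omega}")
    return jmax_opt * math.exp(-(((temperature - t_opt) / omega) ** 2))


def rescale_kp_for_ph(kp_ref: float, ph_ref: float, ph_new: float) -> float:
    """Rescale the PEPC Michaelis constant for CO2 to a different cytosolic pH.

    The measured constant is a Km for bicarbonate; expressed on a CO2 basis
    it scales with the CO2/HCO3⁻ equilibrium, i.e. by ``10**(pH_ref - pH_new)``.
    """
    kp_ref = _require_finite("kp_ref", kp_ref)
    ph_ref = _require_finite("ph_ref", ph_ref)
    ph_new = _require_finite("ph_new", ph_new)
    if kp_ref <= 0:
        raise DomainError(f"kp_ref must be positive, got {kp_ref}")
    return kp_ref * 10.0 ** (ph_ref - ph_new)


@dataclass(frozen=True)
class ParameterSet:
    """Leaf-level parameters at 25 °C.

    Defaults are the *Setaria viridis* parameterization.  ``Rd25`` defaults
    to 1% of ``Vcmax25`` (resolved at construction); ``Jmax25`` defaults to
    the Gaussian ``jmax_at_temperature`` evaluated at 25 °C (≈247.7 for the
    default ``Jmax_To``/``To``/``Omega``).
    """

    Vcmax25: float = 40.0      # µmol m⁻² s⁻¹, maximum Rubisco carboxylation
    Kc25: float = 1210.0       # µbar, Rubisco Michaelis constant for CO2
    Ko25: float = 292.0        # mbar, Rubisco Michaelis constant for O2
    gamma_star25: float = 0.5 / 1310.0  # dimensionless, half reciprocal Sc/o
    Vpmax25: float = 200.0     # µmol m⁻² s⁻¹, maximum PEPC carboxylation
    Vpr: float = 80.0          # µmol m⁻² s⁻¹, PEP-regeneration ceiling
    Kp25: float = 82.0         # µbar, PEPC Michaelis constant for CO2
    gbs: float = 0.003         # mol m⁻² s⁻¹ bar⁻¹, bundle-sheath CO2 conductance
    ao25: float = 0.047        # dimensionless, O2/CO2 solubility-diffusivity ratio
    Rd25: float | None = None  # µmol m⁻² s⁻¹; None -> 0.01 * Vcmax25
    Rm_fraction: float = 0.5   # Rm / Rd
    alpha: float = 0.0         # fraction of PSII activity in the bundle sheath
    x: float = 0.4             # electron transport fraction allocated to the C4 cycle
    Jmax25: float | None = None  # µmol e⁻ m⁻² s⁻¹; None -> Gaussian at 25 °C
    Jmax_To: float = 400.0     # µmol e⁻ m⁻² s⁻¹ at the temperature optimum
    To: float = 43.0           # °C, temperature optimum of Jmax
    Omega: float = 26.0        # °C, Gaussian width of the Jmax response
    h: float = 4.0             # protons per ATP
    f_cyc: float = 0.3         # fraction of PSI electron flow that is cyclic
    theta: float = 0.7         # curvature of the light response
    absorptance: float = 0.85  # leaf absorptance
    f_spectral: float = 0.15   # spectral quality correction
    gm25: float = 1.0          # mol m⁻² s⁻¹ bar⁻¹, mesophyll conductance
    rho: float | None = None   # PSII light fraction; None -> (1-f_cyc)/(2-f_cyc)

    def __post_init__(self) -> None:
        if self.Rd25 is None:
            object.__setattr__(self, "Rd25", 0.01 * self.Vcmax25)
            object.__setattr__(self, "_rd25_tied", True)
        else:
            object.__setattr__(self, "_rd25_tied", False)
        if self.Jmax25 is None:
            object.__setattr__(
                self, "Jmax25", jmax_at_temperature(self.Jmax_To, self.To, self.Omega, 25.0)
            )
        self._validate()

    def _validate(self) -> None:
        positive = (
            "Vcmax25", "Kc25", "Ko25", "Vpmax25", "Vpr",
            "Kp25", "gbs", "ao25", "gm25", "h", "Jmax25", "Jmax_To", "Omega",
        )
        for name in positive:
            value = _require_finite(name, getattr(self, name))
            if value <= 0:
                raise DomainError(f"{name} must be strictly positive, got {value}")
        if not math.isfinite(self.Rd25) or self.Rd25 < 0:
            raise DomainError(f"Rd25 must be non-negative, got {self.Rd25}")
        # gamma_star25 = 0 is the admissible no-photorespiration limit.
        if not math.isfinite(self.gamma_star25) or self.gamma_star25 < 0:
            raise DomainError(f"gamma_star25 must be non-negative, got {self.gamma_star25}")
        for name in ("alpha", "x", "Rm_fraction", "theta"):
            value = _require_finite(name, getattr(self, name))
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 <= self.f_cyc < 1.0:
            raise DomainError(f"f_cyc must lie in [0, 1), got {self.f_cyc}")
        for name in ("absorptance", "f_spectral"):
            value = _require_finite(name, getattr(self, name))
            if not 0.0 < value < 1.0:
                raise DomainError(f"{name} must lie in (0, 1), got {value}")
        if self.rho is not None and not 0.0 < self.rho < 1.0:
            raise DomainError(f"rho must lie in (0, 1), got {self.rho}")

    @property
    def rd25_tied_to_vcmax(self) -> bool:
        """True when ``Rd25`` was defaulted to 0.01·Vcmax25 at construction."""
        return self._rd25_tied  # type: ignore[attr-defined]

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_config(cls, text: str) -> "ParameterSet":
        """Build a parameter set from flat ``key = value`` text.

        Lines that are empty or start with ``#`` are ignored.  Unknown keys
        raise :class:`~c4photo.errors.ConfigError`; omitted keys keep their
        defaults.
        """
        known = set(cls.field_names())
        overrides: dict[str, float] = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown parameter {key!r}")
            try:
                overrides[key] = float(value.strip())
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key!r}: {value.strip()!r}") from exc
        return cls(**overrides)


def default_parameters() -> ParameterSet:
    """The default *Setaria viridis* parameter set at 25 °C."""
    return ParameterSet()


@dataclass(frozen=True)
class AdjustedParameters:
    """Parameter values evaluated at a stated leaf temperature.

    Also carries the derived quantities that downstream equations need:
    the bundle-sheath O2 conductance ``go = ao * gbs``, the ATP yield per
    linear electron ``z``, the PSII light fraction ``rho``, and the
    mesophyll/bundle-sheath split of mitochondrial respiration
    (``Rm + Rs = Rd``).
    """

    T: float
    Vcmax: float
    Kc: float
    Ko: float
    gamma_star: float
    Vpmax: float
    Vpr: float
    Kp: float
    gbs: float
    ao: float
    go: float
    Rd: float
    Rm: float
    Rs: float
    gm: float
    Jmax: float
    z: float
    rho: float
    alpha: float
    x: float
    h: float
    f_cyc: float
    theta: float
    absorptance: float
    f_spectral: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def adjust_to_temperature(params: ParameterSet, temperature: float) -> AdjustedParameters:
    """Evaluate a :class:`ParameterSet` at a leaf temperature (°C).

    Arrhenius-scaled: Vcmax, Kc, Ko, γ*, Vpmax, Kp, Rd, ao, gm.  Gaussian:
    Jmax (anchored at ``Jmax25`` and shaped by ``Jmax_To``/``To``/``Omega``).
    Temperature-invariant: gbs, Vpr.  At 25 °C every scaled field equals its
    base value exactly.
    """
    temperature = _require_finite("temperature", temperature)
    if temperature <= -273.0:
        raise DomainError(f"temperature must exceed -273 °C, got {temperature}")
    E = ACTIVATION_ENERGIES_KJ
    rd = arrhenius_scale(params.Rd25, E["Rd"], temperature) if params.Rd25 > 0 else 0.0
    ao = arrhenius_scale(params.ao25, E["ao"], temperature)
    gaussian_25 = jmax_at_temperature(params.Jmax_To, params.To, params.Omega, 25.0)
    gaussian_T = jmax_at_temperature(params.Jmax_To, params.To, params.Omega, temperature)
    jmax = params.Jmax25 * (gaussian_T / gaussian_25)
    z = (3.0 - params.f_cyc) / (params.h * (1.0 - params.f_cyc))
    rho = params.rho if params.rho is not None else (1.0 - params.f_cyc) / (2.0 - params.f_cyc)
    rm = params.Rm_fraction * rd
    return AdjustedParameters(
        T=temperature,
        Vcmax=arrhenius_scale(params.Vcmax25, E["Vcmax"], temperature),
        Kc=arrhenius_scale(params.Kc25, E["Kc"], temperature),
        Ko=arrhenius_scale(params.Ko25, E["Ko"], temperature),
        gamma_star=(
            arrhenius_scale(params.gamma_star25, E["gamma_star"], temperature)
            if params.gamma_star25 > 0
            else 0.0
        ),
        Vpmax=arrhenius_scale(params.Vpmax25, E["Vpmax"], temperature),
        Vpr=params.Vpr,
        Kp=arrhenius_scale(params.Kp25, E["Kp"], temperature),
        gbs=params.gbs,
        ao=ao,
        go=ao * params.gbs,
        Rd=rd,
        Rm=rm,
        Rs=rd - rm,
        gm=arrhenius_scale(params.gm25, E["gm"], temperature),
        Jmax=jmax,
        z=z,
        rho=rho,
        alpha=params.alpha,
        x=params.x,
        h=params.h,
        f_cyc=params.f_cyc,
        theta=params.theta,
        absorptance=params.absorptance,
        f_spectral=params.f_spectral,
    )
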