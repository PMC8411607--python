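"""Response curves and synthetic gas-exchange data.

A :class:`GasExchangeCurve` is an ordered table of environmental drivers
plus modelled, synthetic (model + Gaussian noise) or measured assimilation
rates.  Curves serialize to plain CSV with unit-suffixed column names.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .leaf import Environment, net_assimilation
from .parameters import ParameterSet

SWEEP_VARIABLES = ("Ci", "I", "T")

#: Canonical column order for CSV output.
COLUMNS = (
    "Ci_ubar", "Cm_ubar", "I_umol_m2_s", "T_C", "Om_mbar",
    "A_umol_m2_s", "limitation", "phi",
)

#: Default A-Ci grid for fitting designs: spans 20-1500 µbar with denser
#: low-Ci coverage, where the PEPC-limited initial slope carries the
#: information on Vpmax.
DEFAULT_ACI_GRID = (
    20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 85.0, 100.0, 120.0, 150.0,
    200.0, 300.0, 500.0, 900.0, 1500.0,
)

PROVENANCE_MODELLED = "modelled"
PROVENANCE_SYNTHETIC = "synthetic"
PROVENANCE_MEASURED = "measured"


@dataclass(frozen=True)
class GasExchangeCurve:
    """An ordered gas-exchange table with provenance metadata."""

    data: pd.DataFrame
    provenance: str = PROVENANCE_MODELLED
    noise_sd: float | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        """Write the curve as CSV (comma, dot decimal, UTF-8, header).

        Provenance and noise metadata go into ``# key = value`` comment
        lines ahead of the header.
        """
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(f"# provenance = {self.provenance}\n")
            if self.noise_sd is not None:
                fh.write(f"# noise_sd = {self.noise_sd}\n")
            if self.seed is not None:
                fh.write(f"# seed = {self.seed}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GasExchangeCurve":
        """Read a curve written by :meth:`to_csv` (or any compatible CSV)."""
        path = Path(path)
        meta: dict[str, str] = {}
        with path.open("r", encoding="utf-8") as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if line.startswith("#"):
                body_start += 1
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                break
        from io import StringIO

        data = pd.read_csv(StringIO("".join(lines[body_start:])))
        noise_sd = float(meta["noise_sd"]) if "noise_sd" in meta else None
        seed = int(meta["seed"]) if "seed" in meta else None
        return cls(
            data=data,
            provenance=meta.get("provenance", PROVENANCE_MEASURED),
            noise_sd=noise_sd,
            seed=seed,
        )


def _validate_grid(grid: Sequence[float]) -> np.ndarray:
    values = np.asarray(list(grid), dtype=float)
    if values.size == 0:
        raise DomainError("grid must be non-empty")
    if values.size > 1 and not np.all(np.diff(values) > 0):
        raise DomainError("grid must be strictly increasing (no duplicates)")
    return values


def sweep(
    variable: str,
    grid: Sequence[float],
    env_base: Environment,
    params: ParameterSet,
    gm_mode: str = "finite",
) -> GasExchangeCurve:
    """Sweep one environmental driver and simulate each grid point.

    ``variable`` is one of ``"Ci"``, ``"I"`` or ``"T"``; the other drivers
    are held at their ``env_base`` values.  Each row records the solved
    mesophyll CO2, the net rate, the limitation flag and leakiness.
    """
    if variable not in SWEEP_VARIABLES:
        raise DomainError(f"variable must be one of {SWEEP_VARIABLES}, got {variable!r}")
    values = _validate_grid(grid)
    rows = []
    for value in values:
        env = replace(env_base, **{variable: float(value)})
        state = net_assimilation(env, params, gm_mode=gm_mode)
        rows.append(
            {
                "Ci_ubar": env.Ci,
                "Cm_ubar": state.Cm,
                "I_umol_m2_s": env.I,
                "T_C": env.T,
                "Om_mbar": env.Om,
                "A_umol_m2_s": state.A,
                "limitation": state.limitation,
                "phi": state.phi if state.phi is not None else np.nan,
            }
        )
    return GasExchangeCurve(data=pd.DataFrame(rows, columns=list(COLUMNS)))


def synthesize(
    variable: str,
    grid: Sequence[float],
    env_base: Environment,
    params: ParameterSet,
    noise_sd: float,
    seed: int,
    gm_mode: str = "finite",
) -> GasExchangeCurve:
    """Model curve plus independent additive Gaussian measurement noise.

    Noise is homoscedastic on the assimilation rate, drawn from one
    seeded generator per call, so output is bit-reproducible for a given
    seed.  ``noise_sd = 0`` returns the model curve unchanged.
    """
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be non-negative, got {noise_sd}")
    curve = sweep(variable, grid, env_base, params, gm_mode=gm_mode)
    data = curve.data.copy()
    rng = np.random.default_rng(seed)
    data["A_umol_m2_s"] = data["A_umol_m2_s"] + rng.normal(0.0, noise_sd, size=len(data))
    return GasExchangeCurve(
        data=data, provenance=PROVENANCE_SYNTHETIC, noise_sd=noise_sd, seed=seed
    )
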