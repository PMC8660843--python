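"""Marcus-theory charge-transfer rates.

Classical (high-temperature) nonadiabatic Marcus expression:

    k = (2 pi / hbar) |V|^2 (4 pi lambda k_B T)^(-1/2)
        * exp( -(dG + lambda)^2 / (4 lambda k_B T) )

with the electronic coupling V supplied in cm^-1 and the driving force dG
and reorganization energy lambda in eV; all unit conversions are internal
(CODATA 2022).  The rate is maximal at the barrierless point dG = -lambda,
decreases with increasing dG in the normal region (dG > -lambda) and
mirrors into the inverted region below it.

A quenching channel is judged "active" when its CT rate is at least a
configurable multiple of the competing intrinsic decay rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HBAR_J_S, BOLTZMANN_J_K, WAVENUMBER_TO_J, EV_TO_J

__all__ = ["MarcusInput", "RateResult", "marcus_rate", "channel_activity", "marcus_table"]


@dataclass(frozen=True)
class MarcusInput:
    """Electronic coupling (cm^-1), driving force and reorganization
    energy (eV), temperature (K)."""

    coupling_cm1: float
    dG_eV: float
    lambda_eV: float
    temperature_K: float = 300.0

    def __post_init__(self):
        if self.lambda_eV <= 0:
            raise ValueError("reorganization energy must be > 0")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class RateResult:
    rate_s1: float
    activation: float  # (dG + lambda)^2 / (4 lambda k_B T), dimensionless


def marcus_rate(inp: MarcusInput) -> RateResult:
    """Classical Marcus CT rate in s^-1 plus the dimensionless activation term."""
    v_j = inp.coupling_cm1 * WAVENUMBER_TO_J
    dg_j = inp.dG_eV * EV_TO_J
    lam_j = inp.lambda_eV * EV_TO_J
    kbt = BOLTZMANN_J_K * inp.temperature_K
    activation = (dg_j + lam_j) ** 2 / (4.0 * lam_j * kbt)
    prefactor = (2.0 * np.pi / HBAR_J_S) * v_j**2 / np.sqrt(4.0 * np.pi * lam_j * kbt)
    return RateResult(rate_s1=float(prefactor * np.exp(-activation)),
                      activation=float(activation))


def channel_activity(
    rate_s1: float,
    competing_decay_rate_s1: float,
    threshold_ratio: float = 1.0,
) -> str:
    """'active' when the CT rate reaches threshold_ratio x the competing
    decay rate (boundary inclusive), else 'inactive'."""
    if rate_s1 < 0 or competing_decay_rate_s1 < 0:
        raise ValueError("rates must be >= 0")
    return "active" if rate_s1 >= threshold_ratio * competing_decay_rate_s1 else "inactive"


def marcus_table(
    df: pd.DataFrame,
    competing_decay_rate_s1: float | None = None,
    threshold_ratio: float = 1.0,
) -> pd.DataFrame:
    """Apply :func:`marcus_rate` row-wise to an energetics table.

    Expects columns V_cm1, dG_eV, lambda_eV and optionally T_K (default
    300 K); returns the table with rate_s1, activation and, when a
    competing rate is given, an activity column.
    """
    required = {"V_cm1", "dG_eV", "lambda_eV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energetics table missing columns: {sorted(missing)}")
    out = df.copy()
    temps = out["T_K"] if "T_K" in out.columns else pd.Series(300.0, index=out.index)
    results = [
        marcus_rate(MarcusInput(v, g, l, t))
        for v, g, l, t in zip(out["V_cm1"], out["dG_eV"], out["lambda_eV"], temps)
    ]
    out["rate_s1"] = [r.rate_s1 for r in results]
    out["activation"] = [r.activation for r in results]
    if competing_decay_rate_s1 is not None:
        out["activity"] = [
            channel_activity(r.rate_s1, competing_decay_rate_s1, threshold_ratio)
            for r in results
        ]
    return out
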