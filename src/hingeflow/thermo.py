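"""Interfacial tension from the pressure tensor, and water solubility.

The planar Kirkwood-Buff route gives the interfacial tension of a slab
with N_int interfaces from the time-averaged anisotropy of the diagonal
pressure tensor,

    γ = (L_z / (2 N_int)) · ⟨P_zz − (P_xx + P_yy)/2⟩ ,

with the exact unit chain 1 bar·Å = 1e-2 mN/m.  The mole-fraction
solubility of water in the octanol-rich phase is the density ratio
x_w = ρ_w / (ρ_w + ρ_oct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

BAR_ANGSTROM_TO_MN_PER_M = 1.0e-2  # 1 bar·Å = 1e5 Pa · 1e-10 m = 1e-2 mN/m


@dataclass
class PressureSeries:
    times: np.ndarray  # ps
    P_xx: np.ndarray  # bar
    P_yy: np.ndarray
    P_zz: np.ndarray
    L_z: float  # Å
    N_int: int = 2

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.P_xx = np.asarray(self.P_xx, dtype=float)
        self.P_yy = np.asarray(self.P_yy, dtype=float)
        self.P_zz = np.asarray(self.P_zz, dtype=float)
        n = len(self.times)
        if not (len(self.P_xx) == len(self.P_yy) == len(self.P_zz) == n):
            raise ValueError("pressure series length mismatch")
        if self.L_z <= 0:
            raise ValueError("L_z must be positive")
        if self.N_int < 1:
            raise ValueError("N_int must be at least 1")

    @property
    def anisotropy(self) -> np.ndarray:
        return self.P_zz - 0.5 * (self.P_xx + self.P_yy)


@dataclass
class PhaseComposition:
    region: str
    water_density: float  # molecules Å^-3
    octanol_density: float

    def __post_init__(self) -> None:
        if self.water_density < 0 or self.octanol_density < 0:
            raise ValueError("densities must be non-negative")


def interfacial_tension(series: PressureSeries, n_blocks: int = 3):
    """(γ, SEM) in mN/m from a pressure-tensor time series, 3-block SEM."""
    dp = series.anisotropy
    if len(dp) < n_blocks:
        raise ValueError(f"need at least {n_blocks} samples")
    pref = series.L_z / (2.0 * series.N_int) * BAR_ANGSTROM_TO_MN_PER_M
    gamma = pref * float(dp.mean())
    block_means = np.array([b.mean() for b in np.array_split(dp, n_blocks)])
    sem = pref * float(block_means.std(ddof=1) / math.sqrt(n_blocks))
    return gamma, sem


def mole_fraction_solubility(composition: PhaseComposition) -> float:
    """x_w = ρ_w / (ρ_w + ρ_oct) in the octanol-rich phase."""
    total = composition.water_density + composition.octanol_density
    if total == 0:
        raise ValueError("both phase densities are zero")
    return composition.water_density / total
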