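"""Strain-energy-density-per-unit-mass remodeling rule with a lazy zone.

The mechanical stimulus is S = U / rho (J/g): strain energy density per
unit bone mass.  The per-iteration density change is zero inside the
equilibrium ("lazy") zone [(1-delta)S0, (1+delta)S0], grows linearly with
distance from the zone edge outside it (slope B*dt), and saturates at
+/- 5% of the current density.  The saturation thresholds S_l and S_u are
thereby defined implicitly as the stimuli where the linear branches reach
the cap — the unique continuous completion of the five-branch rule.
Density is clamped to [0.1, 2.2] g/cm^3 after every update (the upper
clamp is the apparent density of cortical bone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RemodelingParams", "stimulus", "density_increment", "apply_update"]


@dataclass(frozen=True)
class RemodelingParams:
    """Parameters of the density-update rule.

    S0: reference stimulus (J/g); delta: equilibrium-zone half-width as a
    fraction of S0; BdT: remodeling rate constant times time step,
    g^2/(J*cm^3); saturation_fraction: cap on |d rho| per iteration as a
    fraction of rho; rho_min/rho_max: density clamps (g/cm^3);
    convergence_tol: relative change of mean density below which the loop
    stops (checked over the last two steps); max_iter: iteration budget.
    """

    S0: float = 0.008
    delta: float = 0.15
    BdT: float = 2.0
    saturation_fraction: float = 0.05
    rho_min: float = 0.1
    rho_max: float = 2.2
    convergence_tol: float = 0.0003
    max_iter: int = 80

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if self.BdT <= 0:
            raise ValueError("BdT must be > 0")
        if not 0.0 < self.saturation_fraction < 1.0:
            raise ValueError("saturation_fraction must be in (0, 1)")
        if not 0.0 < self.rho_min < self.rho_max:
            raise ValueError("need 0 < rho_min < rho_max")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def zone(self) -> tuple[float, float]:
        """Equilibrium-zone stimulus bounds [(1-delta)S0, (1+delta)S0]."""
        return ((1.0 - self.delta) * self.S0, (1.0 + self.delta) * self.S0)


def stimulus(U, rho, rho_min: float = 0.1):
    """Mechanical stimulus S = U / rho in J/g.

    U in MPa (== J/cm^3), rho in g/cm^3.  Densities below ``rho_min``
    indicate a violated clamping contract upstream and raise.
    """
    U = np.asarray(U, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < rho_min - 1e-12):
        raise ValueError("density below rho_min: clamping contract violated")
    S = U / rho
    return float(S) if S.ndim == 0 else S


def density_increment(rho, S, params: RemodelingParams):
    """Per-iteration density change d(rho) in g/cm^3 for stimulus S.

    Piecewise-linear, continuous, monotone non-decreasing in S, zero on the
    equilibrium zone and clipped to +/- saturation_fraction * rho.
    """
    rho = np.asarray(rho, dtype=float)
    S = np.asarray(S, dtype=float)
    lower, upper = params.zone
    linear = np.where(
        S > upper,
        (S - upper) * params.BdT,
        np.where(S < lower, (S - lower) * params.BdT, 0.0),
    )
    cap = params.saturation_fraction * rho
    d = np.clip(linear, -cap, cap)
    return float(d) if d.ndim == 0 else d


def apply_update(field, increments, params: RemodelingParams):
    """Simultaneous (Jacobi-style) update: rho <- clamp(rho + d rho).

    Returns a new array; the input field is left unchanged.
    """
    field = np.asarray(field, dtype=float)
    increments = np.asarray(increments, dtype=float)
    if field.shape != increments.shape:
        raise ValueError(
            f"density field shape {field.shape} != increments shape {increments.shape}")
    return np.clip(field + increments, params.rho_min, params.rho_max)
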