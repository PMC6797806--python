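"""Tissue elastic constants and the trabecular modulus–density power law.

All tissues are isotropic linear elastic.  Non-trabecular tissues carry
fixed constants; trabecular bone gets its nominal Young's modulus from the
apparent density through the cubic power law E = C·rho^3 (E in MPa, rho in
g/cm^3, C in MPa·cm^9/g^3).  The unit system is mm–N–MPa throughout, so
strain energy density in MPa is numerically identical to J/cm^3 and the
stimulus U/rho comes out directly in J/g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Mesh, RegionLabel

__all__ = [
    "MaterialTable",
    "DEFAULT_MODULUS_DENSITY_CONSTANT",
    "modulus_from_density",
    "material_for_element",
    "elastic_arrays",
]

#: C in E = C·rho^3, MPa·cm^9/g^3 (Carter–Hayes type law for trabecular bone).
DEFAULT_MODULUS_DENSITY_CONSTANT = 3790.0

#: Fixed elastic constants per tissue: (Young's modulus MPa, Poisson ratio).
_DEFAULT_CONSTANTS = {
    RegionLabel.ENAMEL: (79600.0, 0.3),
    RegionLabel.DENTIN: (18600.0, 0.31),
    RegionLabel.PULP: (150.0, 0.49),
    RegionLabel.CEMENTUM: (13700.0, 0.3),
    RegionLabel.PDL: (200.0, 0.45),
    RegionLabel.GINGIVA: (200.0, 0.45),
    RegionLabel.CORTICAL: (13700.0, 0.3),
}

#: Trabecular Poisson ratio is not density-dependent here; 0.3 matches the
#: cortical value and common bone-FE practice.
DEFAULT_TRABECULAR_POISSON = 0.3


def modulus_from_density(rho, C: float = DEFAULT_MODULUS_DENSITY_CONSTANT):
    """Nominal trabecular Young's modulus E = C·rho^3 in MPa.

    ``rho`` is apparent density in g/cm^3 (scalar or array); must be > 0 —
    the density clamps upstream guarantee this in the simulation loop.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("apparent density must be > 0 (clamping violated upstream)")
    E = C * rho**3
    return float(E) if E.ndim == 0 else E


@dataclass
class MaterialTable:
    """Per-region elastic constants plus the trabecular density law constant."""

    constants: dict = field(
        default_factory=lambda: {r: v for r, v in _DEFAULT_CONSTANTS.items()}
    )
    trabecular_poisson: float = DEFAULT_TRABECULAR_POISSON
    modulus_density_constant: float = DEFAULT_MODULUS_DENSITY_CONSTANT

    def __post_init__(self) -> None:
        for region, (E, nu) in self.constants.items():
            if E <= 0:
                raise ValueError(f"{RegionLabel(region).label}: modulus must be > 0")
            if not 0.0 <= nu < 0.5:
                raise ValueError(
                    f"{RegionLabel(region).label}: Poisson ratio must be in [0, 0.5)"
                )
        if not 0.0 <= self.trabecular_poisson < 0.5:
            raise ValueError("trabecular Poisson ratio must be in [0, 0.5)")
        if self.modulus_density_constant <= 0:
            raise ValueError("modulus-density constant must be > 0")

    def to_dict(self) -> dict:
        d = {
            RegionLabel(r).label: {"youngs_modulus": E, "poisson_ratio": nu}
            for r, (E, nu) in sorted(self.constants.items())
        }
        d["trabecular"] = {
            "poisson_ratio": self.trabecular_poisson,
            "modulus_density_constant": self.modulus_density_constant,
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialTable":
        """Build from a config mapping keyed by region name; omitted regions
        keep their defaults, unknown keys are rejected."""
        table = cls()
        for name, rec in (data or {}).items():
            if name not in [r.label for r in RegionLabel]:
                raise ValueError(f"materials: unknown region '{name}'")
            region = RegionLabel[name.upper()]
            rec = dict(rec)
            if region == RegionLabel.TRABECULAR:
                table.trabecular_poisson = float(
                    rec.pop("poisson_ratio", table.trabecular_poisson))
                table.modulus_density_constant = float(
                    rec.pop("modulus_density_constant",
                            table.modulus_density_constant))
            else:
                E0, nu0 = table.constants[region]
                table.constants[region] = (
                    float(rec.pop("youngs_modulus", E0)),
                    float(rec.pop("poisson_ratio", nu0)),
                )
            if rec:
                raise ValueError(
                    f"materials.{name}: unknown keys {sorted(rec)}")
        table.__post_init__()
        return table


def material_for_element(
    region: RegionLabel,
    rho: float | None = None,
    table: MaterialTable | None = None,
) -> tuple[float, float]:
    """(E in MPa, Poisson ratio) for one element.

    ``rho`` is required exactly for trabecular elements and ignored (must be
    absent) otherwise.
    """
    table = table or MaterialTable()
    region = RegionLabel(region)
    if region == RegionLabel.TRABECULAR:
        if rho is None:
            raise ValueError("trabecular element requires an apparent density")
        return (
            modulus_from_density(rho, table.modulus_density_constant),
            table.trabecular_poisson,
        )
    return table.constants[region]


def elastic_arrays(
    mesh: Mesh, table: MaterialTable, density: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (E, nu) arrays for a mesh, with trabecular moduli derived
    from ``density`` (one value per trabecular element, mesh order)."""
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    for region, (Er, nur) in table.constants.items():
        m = mesh.region == int(region)
        E[m], nu[m] = Er, nur
    trab = mesh.trabecular_mask
    if trab.sum() != np.size(density):
        raise ValueError(
            f"density field length {np.size(density)} != "
            f"trabecular element count {int(trab.sum())}")
    E[trab] = modulus_from_density(density, table.modulus_density_constant)
    nu[trab] = table.trabecular_poisson
    return E, nu
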