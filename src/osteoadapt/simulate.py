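"""Iterative FE-solve / density-update loop with trajectory recording.

Each iteration assigns trabecular moduli from the current density via the
power law, solves the elasticity problem, evaluates the stimulus
S = U / rho on trabecular elements, and applies the lazy-zone update rule
to all elements simultaneously.  The loop stops when the mean trabecular
density changes by less than the convergence tolerance over the last two
consecutive iterations, or at the iteration budget.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import LoadCase, assemble_and_solve
from .geometry import Mesh
from .materials import MaterialTable
from .remodeling import RemodelingParams, apply_update, density_increment, stimulus

logger = logging.getLogger(__name__)

__all__ = [
    "InitialDensity",
    "Trajectory",
    "run_simulation",
    "convergence_check",
    "checkerboard_index",
    "DEFAULT_SNAPSHOT_ITERATIONS",
]

#: Iterations at which full density/stimulus fields are stored.
DEFAULT_SNAPSHOT_ITERATIONS = (0, 1, 5, 10, 20, 50, 80)


@dataclass(frozen=True)
class InitialDensity:
    """Uniform initial apparent density (g/cm^3), optionally with an i.i.d.
    uniform multiplicative perturbation within +/- ``perturbation``
    (a fraction, e.g. 0.01 for 1%)."""

    value: float = 0.8
    perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("initial density must be > 0")
        if not 0.0 <= self.perturbation < 1.0:
            raise ValueError("perturbation must be a fraction in [0, 1)")

    def sample(self, n: int, params: RemodelingParams,
               rng: np.random.Generator | None = None) -> np.ndarray:
        rho = np.full(n, self.value)
        if self.perturbation > 0:
            if rng is None:
                raise ValueError("perturbed initial density requires a seeded RNG")
            rho *= 1.0 + rng.uniform(-self.perturbation, self.perturbation, size=n)
        return np.clip(rho, params.rho_min, params.rho_max)


@dataclass
class Trajectory:
    """Per-iteration summary statistics plus field snapshots.

    Index 0 is the initial state.  ``final_density``/``final_stimulus`` are
    the trabecular fields at the recorded last iteration.
    """

    mean_density: list = field(default_factory=list)
    min_density: list = field(default_factory=list)
    max_density: list = field(default_factory=list)
    eq_zone_fraction: list = field(default_factory=list)
    checkerboard: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)
    termination_reason: str = "max_iter"
    iterations: int = 0
    converged_at: int | None = None
    final_density: np.ndarray | None = None
    final_stimulus: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.mean_density)),
                "mean_density": self.mean_density,
                "min_density": self.min_density,
                "max_density": self.max_density,
                "eq_zone_fraction": self.eq_zone_fraction,
                "checkerboard_index": self.checkerboard,
            }
        )


def convergence_check(mean_density_history, tol: float) -> bool:
    """True iff the relative change of the mean density is below ``tol`` for
    the last two consecutive steps (requires at least 3 entries)."""
    h = list(mean_density_history)
    if len(h) < 3:
        return False
    r1 = abs(h[-1] - h[-2]) / abs(h[-2])
    r2 = abs(h[-2] - h[-3]) / abs(h[-3])
    return r1 < tol and r2 < tol


def checkerboard_index(mesh: Mesh, density_field: np.ndarray) -> float:
    """Mean absolute density jump across edge-adjacent trabecular element
    pairs, normalized by the field's range.

    0 for a uniform field; 1 for perfect min/max alternation.  Values well
    below 1 indicate a spatially smooth field (no checkerboarding).
    """
    trab = mesh.trabecular_mask
    pairs = mesh.adjacency_pairs(mask=trab)
    if pairs.shape[0] == 0:
        raise ValueError("no adjacent trabecular element pairs in mesh")
    rho = np.full(mesh.n_elements, np.nan)
    rho[trab] = density_field
    diffs = np.abs(rho[pairs[:, 0]] - rho[pairs[:, 1]])
    rng = float(density_field.max() - density_field.min())
    if rng < 1e-12:
        return 0.0
    return float(diffs.mean() / rng)


def run_simulation(
    mesh: Mesh,
    materials: MaterialTable,
    load: LoadCase,
    params: RemodelingParams,
    initial_density: InitialDensity | float = InitialDensity(),
    seed: int | None = None,
    snapshot_iterations=DEFAULT_SNAPSHOT_ITERATIONS,
    stop_on_convergence: bool = True,
) -> Trajectory:
    """Run the remodeling loop to convergence or the iteration budget.

    Deterministic for a given seed (only the initial perturbation draws
    random numbers).  With ``stop_on_convergence=False`` the loop always
    runs the full iteration budget (the parametric-study protocol, which
    compares every run at the same iteration count); the iteration at
    which the mean-density criterion was first met is still recorded.
    """
    if isinstance(initial_density, (int, float)):
        initial_density = InitialDensity(value=float(initial_density))
    trab = mesh.trabecular_mask
    n_trab = int(trab.sum())
    if n_trab == 0:
        raise ValueError("mesh has no trabecular elements to remodel")
    rng = np.random.default_rng(seed) if seed is not None else None
    rho = initial_density.sample(n_trab, params, rng)
    snapshot_iterations = set(snapshot_iterations)
    lower, upper = params.zone

    traj = Trajectory()
    for k in range(params.max_iter + 1):
        t0 = time.perf_counter()
        try:
            sol = assemble_and_solve(mesh, materials, rho, load)
        except Exception as exc:
            raise RuntimeError(f"FE solve failed at iteration {k}: {exc}") from exc
        S = stimulus(sol.energy_density[trab], rho, params.rho_min)

        traj.mean_density.append(float(rho.mean()))
        traj.min_density.append(float(rho.min()))
        traj.max_density.append(float(rho.max()))
        traj.eq_zone_fraction.append(float(np.mean((S >= lower) & (S <= upper))))
        traj.checkerboard.append(checkerboard_index(mesh, rho))
        if k in snapshot_iterations:
            traj.snapshots[k] = {"density": rho.copy(), "stimulus": S.copy()}
        traj.iterations = k
        traj.final_density = rho
        traj.final_stimulus = S
        logger.info(
            "iteration %d: mean density %.4f g/cm^3, eq-zone %.1f%% (%.3f s)",
            k, rho.mean(), 100 * traj.eq_zone_fraction[-1], time.perf_counter() - t0,
        )

        if convergence_check(traj.mean_density, params.convergence_tol):
            if traj.converged_at is None:
                traj.converged_at = k
            if stop_on_convergence:
                traj.termination_reason = "converged"
                break
        if k == params.max_iter:
            traj.termination_reason = (
                "converged" if traj.converged_at is not None else "max_iter")
            break
        d = density_increment(rho, S, params)
        rho = apply_update(rho, d, params)
    return traj
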