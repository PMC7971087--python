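"""Closed-form canonical references for reduced two-group systems.

For a system whose configurational energy depends only on the distance r
between two group centers (one of them frozen), the RC Boltzmann density is

    p(r) ∝ r² exp(−U(r)/k_B·T)          on a bounded domain,

the r² factor being the spherical-shell volume Jacobian.  These quadrature
evaluations are the independent oracle that both the plain Langevin
histogram and the full zone-sampling + stitching + reweighting pipeline
must recover.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import simpson

from .constants import KB
from .errors import NonNormalizableError, InvalidSpecError
from .system import ToySystem, potential_energy

__all__ = ["radial_potential", "analytic_rc_boltzmann", "analytic_bin_probabilities"]


def radial_potential(system: ToySystem, r_grid: np.ndarray) -> np.ndarray:
    """U(r) for a 2-bead reduced system, mobile bead placed at distance r."""
    if system.n_beads != 2 or system.frozen.size != 1:
        raise InvalidSpecError(
            "radial potential needs a 2-bead system with one frozen bead")
    frozen = int(system.frozen[0])
    mobile = 1 - frozen
    origin = system.coords[frozen]
    out = np.empty(r_grid.shape[0])
    coords = system.coords.copy()
    for i, r in enumerate(np.asarray(r_grid, dtype=float)):
        coords[mobile] = origin + np.array([r, 0.0, 0.0])
        out[i], _ = potential_energy(system, coords)
    return out


def analytic_rc_boltzmann(system: ToySystem, temperature: float,
                          r_grid: np.ndarray) -> np.ndarray:
    """Normalized p(r) on ``r_grid`` (∫ p dr = 1 under Simpson quadrature)."""
    r = np.asarray(r_grid, dtype=float)
    if r.ndim != 1 or r.shape[0] < 3:
        raise InvalidSpecError("r_grid must be a 1-D grid with >= 3 points")
    if not np.all(np.isfinite(r)):
        raise NonNormalizableError("unbounded RC domain")
    u = radial_potential(system, r)
    beta = 1.0 / (KB * temperature)
    w = r * r * np.exp(-beta * (u - u.min()))
    z = simpson(w, x=r)
    if not np.isfinite(z) or z <= 0:
        raise NonNormalizableError("Boltzmann weight is not normalizable")
    return w / z


def analytic_bin_probabilities(system: ToySystem, temperature: float,
                               edges: np.ndarray, points_per_bin: int = 32) -> np.ndarray:
    """Exact per-bin probabilities of p(r) on histogram ``edges`` (sum to 1)."""
    edges = np.asarray(edges, dtype=float)
    probs = np.empty(edges.shape[0] - 1)
    beta = 1.0 / (KB * temperature)
    # one shared offset keeps the exponentials in range
    u_ref = radial_potential(system, np.array([0.5 * (edges[0] + edges[-1])]))[0]
    for b in range(probs.shape[0]):
        grid = np.linspace(edges[b], edges[b + 1], points_per_bin)
        u = radial_potential(system, grid)
        probs[b] = simpson(grid * grid * np.exp(-beta * (u - u_ref)), x=grid)
    total = probs.sum()
    if not np.isfinite(total) or total <= 0:
        raise NonNormalizableError("Boltzmann weight is not normalizable")
    return probs / total
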