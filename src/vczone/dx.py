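"""OpenDX export/import for volumetric grids.

Density grids, orientation-field magnitudes and Q-grid slices go out as
standard OpenDX regular grids (the format molecular viewers read for
contour rendering).  The DX origin is the *center* of the first voxel.
"""

from __future__ import annotations

import numpy as np
from gridData import Grid

from .errors import ExportError

__all__ = ["write_dx", "read_dx"]


def write_dx(grid, path) -> None:
    """Write a DensityGrid / OrientationField-like object or raw array.

    ``grid`` needs ``values`` (or ``weight``), ``origin`` and ``spacing``
    attributes; alternatively pass a tuple (values, origin, spacing).
    """
    if isinstance(grid, tuple):
        values, origin, spacing = grid
    elif hasattr(grid, "values"):
        values, origin, spacing = grid.values, grid.origin, grid.spacing
    else:
        values, origin, spacing = grid.weight, grid.origin, grid.spacing
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ExportError("OpenDX export requires a 3-D grid")
    if not np.all(np.isfinite(values)):
        raise ExportError("grid holds non-finite values")
    origin = np.asarray(origin, dtype=float)
    delta = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    g = Grid(values, origin=origin + 0.5 * delta, delta=delta)
    g.export(str(path), file_format="dx")


def read_dx(path):
    """Read an OpenDX grid back: (values, voxel-corner origin, spacing[3])."""
    g = Grid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    origin = np.asarray(g.origin, dtype=float) - 0.5 * delta
    return np.asarray(g.grid), origin, delta
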