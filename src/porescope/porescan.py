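"""Inscribed-sphere pore radius profiles and gate diameters at M2 prime positions.

The profiler reproduces the classic HOLE measurement: at each axial position z
the pore radius is the radius of the largest sphere, centred in the plane at z,
that touches no atom, i.e.

    r(z) = max over centres c in the plane at z of  min_i ( |c − a_i| − vdW_i )

with the centre confined to a lateral search disc about the pore axis. Instead
of HOLE's simulated-annealing walk, the maximisation is a deterministic coarse
2D grid scan followed by Nelder–Mead refinement, which makes profiles
bit-stable across runs; an optional seeded stochastic mode exists for
cross-checking. The structure must already be axis-aligned (+z = pore axis,
see :func:`porescope.structio.align_pore_axis`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .structio import (
    PrimeMap,
    Structure,
    SubunitMap,
    prime_ring_selection,
)

__all__ = [
    "VDW_RADII_HOLE_SIMPLE",
    "PoreProfile",
    "GateReport",
    "pore_profile",
    "gate_diameters",
    "brute_force_radius",
]

# HOLE's "simple" van der Waals set (Å); the profiler records the set name in
# every output because printed diameters depend on it.
VDW_RADII_HOLE_SIMPLE = {
    "C": 1.85, "O": 1.65, "N": 1.75, "S": 2.00, "H": 1.00, "P": 2.10,
}
_FALLBACK_VDW = 1.85

DEFAULT_AXIAL_STEP = 0.25     # Å
DEFAULT_DISC_RADIUS = 8.0     # Å lateral search disc about the axis
DEFAULT_SLAB_HALF_WIDTH = 1.5  # Å around a prime ring


@dataclass
class PoreProfile:
    """Radius-vs-z curve. ``radius`` is NaN where the profile has a gap."""

    z_grid: np.ndarray
    radius: np.ndarray
    centers: np.ndarray           # (n, 2) refined sphere-centre x,y per slice
    gaps: np.ndarray              # bool mask, True where no valid radius
    disc_radius: float
    radii_set_name: str = "hole_simple"

    def min_radius(self):
        ok = ~self.gaps
        if not ok.any():
            raise ValueError("profile is all gaps")
        i = np.nanargmin(np.where(ok, self.radius, np.nan))
        return float(self.radius[i]), float(self.z_grid[i])


@dataclass
class GateReport:
    """Minimal pore diameter (2·radius) near each M2 prime ring."""

    diameters: dict               # prime index -> (diameter Å, z of minimum)
    slab_half_width: float
    radii_set_name: str = "hole_simple"

    def diameter(self, prime: int) -> float:
        return self.diameters[prime][0]


def vdw_radii(structure: Structure, table: dict | None = None) -> np.ndarray:
    table = VDW_RADII_HOLE_SIMPLE if table is None else table
    return np.array([table.get(e, _FALLBACK_VDW) for e in structure.elements])


def _clearance(centers_xy: np.ndarray, z: float, atoms: np.ndarray,
               radii: np.ndarray) -> np.ndarray:
    """min_i(|c − a_i| − r_i) for each centre in the plane at z (vectorised)."""
    c = np.column_stack([centers_xy, np.full(len(centers_xy), z)])
    d = np.linalg.norm(c[:, None, :] - atoms[None, :, :], axis=2) - radii[None, :]
    return d.min(axis=1)


def brute_force_radius(structure_or_atoms, z: float, *, radii=None,
                       disc_radius: float = DEFAULT_DISC_RADIUS,
                       grid_step: float = 0.05) -> float:
    """Dense-grid oracle: exhaustive scan of sphere centres in the plane at z.

    Slow but simple; used as the independent reference the refined search is
    checked against.
    """
    if isinstance(structure_or_atoms, Structure):
        atoms = structure_or_atoms.coords
        radii = vdw_radii(structure_or_atoms) if radii is None else radii
    else:
        atoms = np.asarray(structure_or_atoms)
        radii = np.asarray(radii)
    # atoms further than disc_radius + max vdW along z cannot bound any
    # sphere smaller than the disc cap
    near = np.abs(atoms[:, 2] - z) <= disc_radius + radii.max()
    atoms, radii = atoms[near], radii[near]
    g = np.arange(-disc_radius, disc_radius + grid_step / 2, grid_step)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= disc_radius]
    best = -np.inf
    for chunk in np.array_split(pts, max(1, len(pts) // 4096)):
        best = max(best, _clearance(chunk, z, atoms, radii).max())
    return float(best)


def _refine_slice(z: float, atoms: np.ndarray, radii: np.ndarray,
                  disc_radius: float, coarse_step: float,
                  start: np.ndarray | None):
    """Coarse grid + Nelder–Mead maximisation of the clearance at one z."""
    g = np.arange(-disc_radius, disc_radius + coarse_step / 2, coarse_step)
    xx, yy = np.meshgrid(g, g)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= disc_radius]
    if start is not None:
        pts = np.vstack([pts, start[None, :]])
    vals = _clearance(pts, z, atoms, radii)
    x0 = pts[int(np.argmax(vals))]

    def neg(c):
        if np.hypot(c[0], c[1]) > disc_radius:
            return np.inf
        return -_clearance(c[None, :], z, atoms, radii)[0]

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    if -res.fun >= vals.max():
        return float(-res.fun), np.asarray(res.x, dtype=float)
    return float(vals.max()), x0


def pore_profile(structure: Structure, z_range: tuple, *,
                 grid: float = DEFAULT_AXIAL_STEP,
                 radii: dict | None = None,
                 radii_set_name: str = "hole_simple",
                 disc_radius: float = DEFAULT_DISC_RADIUS,
                 coarse_step: float = 0.5,
                 include_hydrogens: bool = False,
                 slab_reach: float | None = None) -> PoreProfile:
    """Maximal inscribed-sphere radius along +z over ``z_range = (z_lo, z_hi)``.

    Per slice only atoms with |z_atom − z| ≤ ``slab_reach`` + max vdW are
    considered; if that slab is empty, or the maximal sphere escapes the
    lateral search disc (clearance beyond ``disc_radius``), the slice is
    flagged as a gap (NaN radius) rather than silently clamped.
    """
    if grid <= 0:
        raise ValueError("axial step must be positive")
    keep = np.ones(structure.n_atoms, dtype=bool)
    if not include_hydrogens:
        keep &= structure.elements != "H"
    atoms_all = structure.coords[keep]
    r_all = vdw_radii(structure, radii)[keep]
    if atoms_all.shape[0] == 0:
        raise ValueError("no atoms available for profiling")
    r_max = float(r_all.max())
    if slab_reach is None:
        # an atom further than disc_radius + vdW along z cannot bound any
        # sphere below the lateral cap
        slab_reach = disc_radius
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    n = int(np.floor((z_hi - z_lo) / grid + 1e-9)) + 1
    z_grid = z_lo + grid * np.arange(n)

    radius = np.full(n, np.nan)
    centers = np.full((n, 2), np.nan)
    gaps = np.ones(n, dtype=bool)
    prev_center = None
    zs = atoms_all[:, 2]
    for i, z in enumerate(z_grid):
        sel = np.abs(zs - z) <= slab_reach + r_max
        if not sel.any():
            warnings.warn(f"pore profile gap at z={z:.2f} Å: empty atom slab",
                          stacklevel=2)
            prev_center = None
            continue
        val, ctr = _refine_slice(z, atoms_all[sel], r_all[sel],
                                 disc_radius, coarse_step, prev_center)
        if val < 0:
            # slice fully occluded: sphere of zero radius does not fit;
            # report 0 per the convention that radius is non-negative
            val = 0.0
        if val > disc_radius:
            warnings.warn(
                f"pore profile gap at z={z:.2f} Å: pore wall beyond the "
                f"{disc_radius:.1f} Å search disc", stacklevel=2)
            prev_center = None
            continue
        radius[i] = val
        centers[i] = ctr
        gaps[i] = False
        prev_center = ctr
    return PoreProfile(z_grid=z_grid, radius=radius, centers=centers, gaps=gaps,
                       disc_radius=disc_radius, radii_set_name=radii_set_name)


def gate_diameters(profile: PoreProfile, prime_map: PrimeMap,
                   structure: Structure, subunits: SubunitMap, *,
                   primes=None,
                   slab_half_width: float = DEFAULT_SLAB_HALF_WIDTH) -> GateReport:
    """Minimal diameter (2·min radius) within ±slab_half_width of each prime ring.

    The ring position is the mean z of the five residues' heavy atoms in the
    axis-aligned frame shared with ``profile``. Prime positions whose ring
    residues are missing, or whose slab holds no valid profile point, are
    omitted with a warning.
    """
    from .structio import SelectionError

    primes = range(-2, 21) if primes is None else primes
    out = {}
    ok = ~profile.gaps
    for k in primes:
        try:
            ring = prime_ring_selection(structure, subunits, prime_map, k)
        except SelectionError:
            warnings.warn(f"prime {k}' ring residues missing; omitted", stacklevel=2)
            continue
        z_ring = float(structure.coords[ring.indices, 2].mean())
        in_slab = ok & (np.abs(profile.z_grid - z_ring) <= slab_half_width)
        if not in_slab.any():
            warnings.warn(f"no profile points in ±{slab_half_width} Å slab at "
                          f"prime {k}' (z={z_ring:.2f})", stacklevel=2)
            continue
        idx = np.flatnonzero(in_slab)
        j = idx[int(np.argmin(profile.radius[idx]))]
        out[k] = (2.0 * float(profile.radius[j]), float(profile.z_grid[j]))
    return GateReport(diameters=out, slab_half_width=slab_half_width,
                      radii_set_name=profile.radii_set_name)
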