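"""Pore hydration counting and upper-ECD spread over trajectories.

Hydration: number of distinct water molecules whose oxygen lies within a
cutoff (default 3 Å) of any atom of the 9′ activation-gate ring — a per-frame
integer that shifts upward when the hydrophobic gate dilates.

Upper-ECD spread: after Cα alignment of the whole receptor to frame 0, the
per-frame dispersion of the five subunits' upper-extracellular-domain centres
of mass. Two modes ship because "spread" admits both readings:

- ``radial_spread`` (default): mean distance from each subunit's upper-ECD
  COM to the centroid of the five COMs — contraction of the ECD ring lowers
  it directly;
- ``com_displacement``: mean per-subunit |COM_i(t) − COM_i(0)|.

The shipped upper-ECD residue ranges are the α1/β2/γ2 blocks used for the
receptor this package targets; COMs are mass-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import (
    Selection,
    SelectionError,
    SubunitMap,
    Trajectory,
    WATER_RESNAMES,
    _kabsch,
)

__all__ = [
    "EcdRanges",
    "HydrationTrace",
    "SpreadTrace",
    "hydration_count",
    "ecd_spread",
    "DEFAULT_ECD_RANGES",
    "DEFAULT_HYDRATION_CUTOFF",
]

DEFAULT_HYDRATION_CUTOFF = 3.0  # Å

# Upper-ECD residue intervals (inclusive) per subunit class, author numbering.
DEFAULT_ECD_RANGES = {
    "alpha": [(10, 45), (66, 102), (107, 133), (157, 180), (200, 213)],
    "beta": [(7, 43), (62, 99), (104, 130), (154, 176), (194, 208)],
    "gamma": [(25, 57), (77, 113), (119, 145), (169, 189), (210, 223)],
}


@dataclass(frozen=True)
class EcdRanges:
    """Per subunit class, sorted non-overlapping residue intervals (inclusive)."""

    ranges: dict

    def __post_init__(self) -> None:
        clean = {}
        for cls, intervals in self.ranges.items():
            ivs = sorted(tuple(i) for i in intervals)
            for (a, b) in ivs:
                if a > b:
                    raise ValueError(f"{cls}: interval ({a}, {b}) is inverted")
            for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
                if a2 <= b1:
                    raise ValueError(f"{cls}: intervals overlap near {a2}")
            clean[cls] = ivs
        object.__setattr__(self, "ranges", clean)

    def mask(self, res_numbers: np.ndarray, cls: str) -> np.ndarray:
        m = np.zeros(res_numbers.size, dtype=bool)
        for a, b in self.ranges[cls]:
            m |= (res_numbers >= a) & (res_numbers <= b)
        return m

    @staticmethod
    def default() -> "EcdRanges":
        return EcdRanges(ranges={k: list(v) for k, v in DEFAULT_ECD_RANGES.items()})


@dataclass
class HydrationTrace:
    counts: np.ndarray            # per-frame integer water count
    gate_expression: str
    cutoff: float


@dataclass
class SpreadTrace:
    spread: np.ndarray            # per-frame value, Å
    mode: str                     # 'radial_spread' | 'com_displacement'
    ranges_used: dict             # chain -> residue numbers actually present


def hydration_count(traj: Trajectory, gate: Selection,
                    water_selector=None,
                    cutoff: float = DEFAULT_HYDRATION_CUTOFF) -> HydrationTrace:
    """Distinct waters whose oxygen is within ``cutoff`` of any gate atom.

    ``gate`` is typically all (heavy) atoms of the five 9′ leucines. Waters
    are residues named HOH/WAT/TIP3/SOL, identified by residue so a molecule
    straddling the cutoff counts once; the count uses the oxygen position.
    ``water_selector`` may override the default water Selection. Distances are
    plain Cartesian (whole-molecule input frames, no periodic imaging).
    """
    topo = traj.topology
    if water_selector is None:
        mask = np.isin(topo.res_names, list(WATER_RESNAMES)) & (topo.elements == "O")
        widx = np.flatnonzero(mask)
    else:
        widx = water_selector.indices
        widx = widx[topo.elements[widx] == "O"]
    if widx.size == 0:
        warnings.warn("no waters in topology: hydration trace is all zeros",
                      stacklevel=2)
        return HydrationTrace(counts=np.zeros(traj.n_frames, dtype=int),
                              gate_expression=gate.expression, cutoff=cutoff)
    wkeys = np.array([f"{c}:{r}" for c, r in
                      zip(topo.chain_ids[widx], topo.res_numbers[widx])])
    counts = np.empty(traj.n_frames, dtype=int)
    for t in range(traj.n_frames):
        tree = cKDTree(traj.frames[t][gate.indices])
        d, _ = tree.query(traj.frames[t][widx], k=1,
                          distance_upper_bound=cutoff + 1e-12)
        counts[t] = np.unique(wkeys[np.isfinite(d) & (d <= cutoff)]).size
    return HydrationTrace(counts=counts, gate_expression=gate.expression,
                          cutoff=cutoff)


def _align_to_first(traj: Trajectory, align_idx: np.ndarray) -> np.ndarray:
    ref = traj.frames[0][align_idx]
    out = np.empty_like(traj.frames)
    for t in range(traj.n_frames):
        tr, _ = _kabsch(traj.frames[t][align_idx], ref)
        out[t] = tr.apply(traj.frames[t])
    return out


def ecd_spread(traj: Trajectory, subunits: SubunitMap,
               ranges: EcdRanges | None = None,
               mode: str = "radial_spread",
               align: Selection | None = None) -> SpreadTrace:
    """Per-frame upper-ECD dispersion after Cα alignment to frame 0.

    Raises if any subunit resolves zero upper-ECD atoms (naming the chain);
    individual missing residues inside the ranges are tolerated and the used
    residue subset is recorded on the returned trace.
    """
    if mode not in ("radial_spread", "com_displacement"):
        raise ValueError(f"unknown spread mode {mode!r}")
    ranges = EcdRanges.default() if ranges is None else ranges
    topo = traj.topology
    if align is None:
        from .structio import select
        align = select(topo, "protein and name CA and heavy")
    chain_atom_idx, ranges_used = {}, {}
    for chain_id in subunits.chains():
        cls = subunits.class_of(chain_id)
        on_chain = topo.chain_ids == chain_id
        m = on_chain & ranges.mask(topo.res_numbers, cls) & (topo.elements != "H")
        idx = np.flatnonzero(m)
        if idx.size == 0:
            raise SelectionError(
                f"chain {chain_id} ({cls}): no atoms resolved in the upper-ECD "
                f"ranges {ranges.ranges[cls]}"
            )
        chain_atom_idx[chain_id] = idx
        ranges_used[chain_id] = sorted(set(topo.res_numbers[idx].tolist()))

    aligned = _align_to_first(traj, align.indices)
    masses = topo.masses()
    coms = np.empty((traj.n_frames, len(chain_atom_idx), 3))
    for ci, (chain_id, idx) in enumerate(chain_atom_idx.items()):
        w = masses[idx] / masses[idx].sum()
        coms[:, ci, :] = (aligned[:, idx, :] * w[None, :, None]).sum(axis=1)
    if mode == "radial_spread":
        centroid = coms.mean(axis=1, keepdims=True)
        spread = np.linalg.norm(coms - centroid, axis=2).mean(axis=1)
    else:
        spread = np.linalg.norm(coms - coms[0][None], axis=2).mean(axis=1)
    return SpreadTrace(spread=spread, mode=mode, ranges_used=ranges_used)
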