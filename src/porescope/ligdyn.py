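"""Ligand stability and pose analysis over trajectories.

Three observables used to judge whether a bound ligand (agonist in the
orthosteric site, or a sulfated neurosteroid in the pore) stays put:

- an rmsd trace relative to the starting pose, computed after superposing
  each frame on the reference via the protein Cα atoms (no further fitting on
  the ligand itself), optionally with a crop rule that maps extreme
  unbinding excursions to a fixed plotting value;
- a signed displacement of the ligand centre of mass along the pore axis
  (+z = toward the outer membrane leaflet);
- quality-threshold pose clustering of frames on the pairwise ligand-rmsd
  matrix, with a fixed rmsd cutoff and a maximum cluster count.

The shipped crop preset (threshold 60 Å → stored 10 Å) reflects the plotting
convention used for free agonist diffusion after unbinding events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import (
    Selection,
    SelectionError,
    Structure,
    Trajectory,
    _kabsch,
)

__all__ = [
    "RmsdTrace",
    "ZTrace",
    "ClusterResult",
    "ligand_rmsd_trace",
    "ligand_z_trace",
    "cluster_poses",
    "CROP_PRESET_UNBINDING",
]

# (threshold Å, stored value Å): excursions beyond the threshold after
# unbinding are cropped to a fixed value for comparability of violin plots
CROP_PRESET_UNBINDING = (60.0, 10.0)


@dataclass
class RmsdTrace:
    rmsd: np.ndarray              # per-frame, Å (after crop rule, if any)
    raw_rmsd: np.ndarray          # per-frame, Å, uncropped
    cropped: np.ndarray           # bool per frame
    crop_threshold: float | None
    crop_value: float | None
    reference: object             # frame index or external Structure

    @property
    def n_frames(self) -> int:
        return self.rmsd.size


@dataclass
class ZTrace:
    dz: np.ndarray                # per-frame signed COM z displacement, Å
    axis_note: str = "+z toward outer membrane leaflet"

    def slope_per_frame(self) -> float:
        """Least-squares drift in Å/frame (sign of net axial tendency)."""
        t = np.arange(self.dz.size)
        return float(np.polyfit(t, self.dz, 1)[0])


@dataclass
class ClusterResult:
    labels: np.ndarray            # per-frame cluster id, -1 = noise
    populations: np.ndarray       # per-cluster frame counts, extraction order
    representatives: np.ndarray   # per-cluster medoid frame index
    cutoff: float
    max_clusters: int

    @property
    def n_clusters(self) -> int:
        return self.populations.size

    def top_representatives(self, k: int = 5) -> np.ndarray:
        """Frame indices of the k most populated clusters' medoids."""
        return self.representatives[:k]


def _aligned_ligand_coords(traj: Trajectory, ligand: Selection,
                           align: Selection, reference) -> tuple:
    """Per-frame ligand coordinates after Cα (align-selection) superposition.

    Returns (lig_coords (n_frames, n_lig, 3), ref_lig (n_lig, 3)).
    """
    if len(ligand) == 0:
        raise SelectionError("empty ligand selection")
    if isinstance(reference, Structure):
        ref_align = reference.coords[align.indices]
        ref_lig = reference.coords[ligand.indices]
    else:
        ref_frame = traj.frames[int(reference)]
        ref_align = ref_frame[align.indices]
        ref_lig = ref_frame[ligand.indices]
    out = np.empty((traj.n_frames, len(ligand), 3))
    for t in range(traj.n_frames):
        frame = traj.frames[t]
        tr, _ = _kabsch(frame[align.indices], ref_align)
        out[t] = tr.apply(frame[ligand.indices])
    return out, ref_lig


def ligand_rmsd_trace(traj: Trajectory, ligand: Selection, align: Selection,
                      reference=0, crop_threshold: float | None = None,
                      crop_value: float | None = None) -> RmsdTrace:
    """Per-frame ligand rmsd from the reference pose, Cα-aligned.

    ``reference`` is a frame index (default 0, the experimentally derived
    pose) or an external Structure sharing the topology. When
    ``crop_threshold`` is set, frames whose raw rmsd exceeds it store
    ``crop_value`` instead and are flagged.
    """
    if (crop_threshold is None) != (crop_value is None):
        raise ValueError("crop_threshold and crop_value must be set together")
    lig, ref_lig = _aligned_ligand_coords(traj, ligand, align, reference)
    raw = np.sqrt(((lig - ref_lig[None]) ** 2).sum(axis=2).mean(axis=1))
    cropped = np.zeros(raw.size, dtype=bool)
    rmsd = raw.copy()
    if crop_threshold is not None:
        cropped = raw > crop_threshold
        rmsd[cropped] = crop_value
    return RmsdTrace(rmsd=rmsd, raw_rmsd=raw, cropped=cropped,
                     crop_threshold=crop_threshold, crop_value=crop_value,
                     reference=reference)


def ligand_z_trace(traj: Trajectory, ligand: Selection,
                   align: Selection | None = None, reference=0,
                   masses: np.ndarray | None = None) -> ZTrace:
    """Signed ligand-COM displacement along the pore axis relative to frame 0.

    Assumes the trajectory is in the axis-aligned frame (+z extracellular /
    outer leaflet). When ``align`` is given, frames are first Cα-superposed
    onto the reference so global receptor drift does not masquerade as ligand
    movement.
    """
    if align is not None:
        lig, _ = _aligned_ligand_coords(traj, ligand, align, reference)
    else:
        lig = traj.frames[:, ligand.indices, :]
    if masses is None:
        masses = traj.topology.masses()[ligand.indices]
    w = masses / masses.sum()
    com_z = (lig[:, :, 2] * w[None, :]).sum(axis=1)
    return ZTrace(dz=com_z - com_z[0])


def pairwise_rmsd_matrix(traj: Trajectory, ligand: Selection,
                         align: Selection, reference=0) -> np.ndarray:
    """Pairwise ligand rmsd between frames, each first aligned to the reference.

    Alignment is to the common reference (not mutual pairwise fitting), which
    matches the trace definition and keeps the cost at O(n) superpositions.
    """
    lig, _ = _aligned_ligand_coords(traj, ligand, align, reference)
    d2 = ((lig[:, None, :, :] - lig[None, :, :, :]) ** 2).sum(axis=3).mean(axis=2)
    return np.sqrt(d2)


def cluster_poses(traj: Trajectory, ligand: Selection, align: Selection,
                  cutoff: float = 1.0, max_clusters: int = 10,
                  reference=0) -> ClusterResult:
    """Greedy quality-threshold clustering of frames by ligand rmsd.

    Repeatedly extracts the unassigned frame with the largest
    cutoff-neighbourhood (ties → lowest frame index) together with its
    neighbours as a cluster, until ``max_clusters`` clusters exist or all
    frames are assigned; leftovers are labelled noise (−1). Cluster
    populations are non-increasing in extraction order by construction; the
    representative of a cluster is its medoid (minimal summed rmsd to the
    other members, ties → lowest frame index).
    """
    if cutoff <= 0:
        raise ValueError("rmsd cutoff must be positive")
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    if traj.n_frames < 2:
        raise ValueError("pose clustering needs at least 2 frames")
    dmat = pairwise_rmsd_matrix(traj, ligand, align, reference)
    n = dmat.shape[0]
    within = dmat <= cutoff
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    pops, reps = [], []
    for cluster_id in range(max_clusters):
        if not unassigned.any():
            break
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))          # argmax → lowest index on ties
        members = np.flatnonzero(within[seed] & unassigned)
        labels[members] = cluster_id
        unassigned[members] = False
        sub = dmat[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        pops.append(members.size)
        reps.append(int(medoid))
    return ClusterResult(labels=labels, populations=np.array(pops, dtype=int),
                         representatives=np.array(reps, dtype=int),
                         cutoff=cutoff, max_clusters=max_clusters)
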