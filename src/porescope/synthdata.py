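"""Ground-truthed synthetic pentameric channels, trajectories and ion samples.

Real counterparts of these objects are cluster-scale MD trajectories of the
α1β2γ2 GABA_A receptor; this module builds miniature stand-ins whose every
observable is known analytically, so the analysis stages (pore profiling,
ligand rmsd/z traces, pose clustering, contact fingerprints, hydration counts,
ECD spread) can be verified against exact ground truth without any downloads.

Geometry of the toy channel
---------------------------
Five pseudo-subunits (chains A–E mapped α/β/α/β/γ) each contribute two carbon
pseudo-atoms per ring; rings are stacked every 0.75 Å along +z, two rings per
M2-like residue (axial pitch 1.5 Å/residue, close to an α-helical rise).
Ring atoms sit at distance ``R(z) + r_C`` from the axis, so the maximal
inscribed sphere in the ring plane has radius exactly ``R(z)``; between ring
planes the radius bulges by at most ``sqrt((R+r)² + 0.375²) − r − R``
(≈ 0.02 Å at R ≈ 2 Å), which is the fixture's analytic tolerance. Residue
numbering follows the shipped prime anchors so the same prime-map machinery
used on deposited structures applies to the toys.

All generation is a pure function of (spec, seed); the spec is serialised
alongside every dataset the CLI writes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .structio import (
    DEFAULT_FRAME_INTERVAL_NS,
    DEFAULT_PRIME_ANCHORS,
    PrimeMap,
    Structure,
    SubunitMap,
    Trajectory,
)

__all__ = [
    "SyntheticSpec",
    "SpecError",
    "make_toy_channel",
    "make_toy_trajectory",
    "make_unbinding_trajectory",
    "toy_subunit_map",
    "cylinder",
    "hourglass",
]

_CARBON_VDW = 1.85  # must match the profiler's default table for carbon
_RING_SPACING = 0.75
_RESIDUE_PITCH = 1.5
_CHAIN_CLASSES = {"A": "alpha", "B": "beta", "C": "alpha", "D": "beta", "E": "gamma"}

ECD_RESIDUES = (400, 401, 402, 403, 404)   # pseudo upper-ECD block per chain
ECD_RADIUS = 10.0                           # Å from axis
ECD_Z0 = 40.0

LIGAND_CHAIN = "X"
LIGAND_RESNAME = "DHS"
WATER_CHAIN = "W"


class SpecError(ValueError):
    """Contradictory or unrealisable synthetic-data specification."""


def cylinder(radius: float):
    """Constant-radius pore profile function."""
    return lambda z: radius


def hourglass(r_end: float, r_waist: float, z_waist: float, width: float = 8.0):
    """Smooth hourglass: Gaussian waist of radius ``r_waist`` at ``z_waist``."""
    def f(z):
        return r_end - (r_end - r_waist) * math.exp(-0.5 * ((z - z_waist) / width) ** 2)
    return f


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic channel / trajectory; all units Å, ns, frames.

    ``contact_schedule`` maps (chain_id, residue_number) → fraction of frames
    in which that residue is placed in contact (< 4.5 Å) with the ligand.
    ``water_plan`` is a per-frame sequence of water counts inside the 3 Å
    shell of the 9′ gate. ``breathing`` is a per-frame radial scale factor
    applied to the pseudo-ECD blocks about the pore axis.
    """

    seed: int = 0
    pore_radius_function: object = field(default_factory=lambda: cylinder(4.0))
    z_min: float = -3.0
    z_max: float = 30.75
    n_frames: int = 50
    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS
    ligand_jitter_sigma: float = 0.0
    ligand_drift: float = 0.0              # Å per frame along +z
    contact_schedule: dict = field(default_factory=dict)
    water_plan: object = None              # sequence of ints, or None for no waters
    breathing: object = None               # sequence of floats, or None for static
    prime_anchors: dict = field(default_factory=lambda: dict(DEFAULT_PRIME_ANCHORS))
    escape_frame: int | None = None
    escape_speed: float = 8.0              # Å per frame after escape
    ligand_z0: float = 7.5

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(self.seed))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["pore_radius_function"] = "<callable>"
        d["contact_schedule"] = {f"{c}:{r}": f for (c, r), f in
                                 self.contact_schedule.items()}
        for k in ("water_plan", "breathing"):
            if d[k] is not None:
                d[k] = list(np.asarray(d[k]).tolist())
        return json.dumps(d, indent=2, sort_keys=True)


def toy_subunit_map() -> SubunitMap:
    return SubunitMap(chain_to_class=dict(_CHAIN_CLASSES))


def toy_prime_map(spec: SyntheticSpec) -> PrimeMap:
    return PrimeMap(anchors=dict(spec.prime_anchors))


def _channel_arrays(spec: SyntheticSpec):
    """Pseudo-atom arrays for the pentameric wall, grouped chain → residue.

    Chain-grouped ordering matches PDB conventions so written files round-trip
    with atom order intact.
    """
    pm = toy_prime_map(spec)
    chains, resnums, resnames, atomnames, xyz = [], [], [], [], []
    ring_levels = set()
    for ci, chain_id in enumerate(_CHAIN_CLASSES):
        cls = _CHAIN_CLASSES[chain_id]
        for prime in range(-2, 21):
            resnum = pm.residue_number(cls, prime)
            if prime == 9:
                rname = "LEU"
            elif prime == 2:
                rname = {"alpha": "VAL", "beta": "ALA", "gamma": "ILE"}[cls]
            else:
                rname = "ILE"
            for sub_ring in range(2):
                z = prime * _RESIDUE_PITCH + sub_ring * _RING_SPACING
                if not (spec.z_min - 1e-9 <= z <= spec.z_max + 1e-9):
                    continue
                R = float(spec.pore_radius_function(z))
                if R < _CARBON_VDW:
                    raise SpecError(
                        f"pore radius {R:.2f} Å at z={z:.2f} is smaller than "
                        f"the ring atom vdW radius {_CARBON_VDW} Å"
                    )
                ring_levels.add(z)
                # two concentric shells: the inner ring realises the requested
                # pore radius; the outer ring (radial offset < 2 vdW radii, so
                # the shells overlap into a solid wall) mimics the thick TMD
                # and keeps the maximal inscribed sphere from escaping through
                # the open exterior of a single-shell wall. 4 atoms per chain
                # per ring, staggered 9 deg between stacked rings, keeps the
                # azimuthal gaps small enough that the sphere stays on-axis.
                for si, dr in enumerate((0.0, 3.0)):
                    rho = R + _CARBON_VDW + dr
                    for ai in range(4):
                        theta = math.radians(72.0 * ci + 18.0 * ai
                                             + 9.0 * sub_ring)
                        chains.append(chain_id)
                        resnums.append(resnum)
                        resnames.append(rname)
                        atomnames.append(f"C{si * 8 + sub_ring * 4 + ai + 1}")
                        xyz.append([rho * math.cos(theta),
                                    rho * math.sin(theta), z])
    return chains, resnums, resnames, atomnames, xyz, sorted(ring_levels)


def _assemble(chains, resnums, resnames, atomnames, xyz, elements=None):
    n = len(chains)
    if elements is None:
        elements = [a.strip("0123456789")[:1] or "C" for a in atomnames]
    return Structure(
        chain_ids=np.array(chains, dtype="U4"),
        res_numbers=np.array(resnums, dtype=np.int64),
        icodes=np.full(n, " ", dtype="U1"),
        res_names=np.array(resnames, dtype="U4"),
        atom_names=np.array(atomnames, dtype="U4"),
        elements=np.array(elements, dtype="U2"),
        coords=np.array(xyz, dtype=float),
        altlocs=np.full(n, "", dtype="U1"),
        occupancies=np.ones(n),
    )


def make_toy_channel(spec: SyntheticSpec):
    """Build the pentameric wall; returns (Structure, ground_truth dict).

    Ground truth carries the requested radius function and the exact
    ring-geometry profile ``profile_exact(z)`` = min over rings of
    ``sqrt((R_ring + r_C)² + (z − z_ring)²) − r_C`` — the true maximal
    inscribed-sphere radius of the constructed wall on the axis.
    """
    chains, resnums, resnames, atomnames, xyz, ring_levels = _channel_arrays(spec)
    structure = _assemble(chains, resnums, resnames, atomnames, xyz)

    ring_z = np.array(ring_levels)
    ring_R = np.array([float(spec.pore_radius_function(z)) for z in ring_levels])

    def profile_exact(z):
        d = np.sqrt((ring_R + _CARBON_VDW) ** 2 + (np.asarray(z)[..., None] - ring_z) ** 2)
        return (d - _CARBON_VDW).min(axis=-1)

    truth = {
        "radius_function": spec.pore_radius_function,
        "profile_exact": profile_exact,
        "ring_z": ring_z,
        "ring_R": ring_R,
        "subunit_map": toy_subunit_map(),
        "prime_map": toy_prime_map(spec),
    }
    return structure, truth


def _ligand_base(spec: SyntheticSpec) -> np.ndarray:
    z0 = spec.ligand_z0
    pts = []
    for j, dz in enumerate((-0.4, 0.4)):
        for ai in range(4):
            theta = math.radians(90.0 * ai + 45.0 * j)
            pts.append([0.8 * math.cos(theta), 0.8 * math.sin(theta), z0 + dz])
    return np.array(pts)


def _validate_schedule(spec: SyntheticSpec, pm: PrimeMap):
    gate_res = {(c, pm.residue_number(cls, 9)) for c, cls in _CHAIN_CLASSES.items()}
    for (chain, resnum), frac in spec.contact_schedule.items():
        if chain not in _CHAIN_CLASSES:
            raise SpecError(f"contact schedule names unknown chain {chain!r}")
        if not 0.0 <= frac <= 1.0:
            raise SpecError(f"contact fraction {frac} for {chain}:{resnum} "
                            "outside [0, 1]")
        if spec.water_plan is not None and (chain, resnum) in gate_res:
            raise SpecError(
                f"residue {chain}:{resnum} is a 9' gate residue: scheduling it "
                "both as a ligand contact and as the hydration gate is "
                "contradictory"
            )


def make_toy_trajectory(spec: SyntheticSpec):
    """Toy trajectory realising programmed ligand motion, contacts, waters, ECD.

    Returns ``(Trajectory, ground_truth)`` where ground truth holds, per the
    same schemas the analysis modules emit:

    - ``ligand_displacement`` (n_frames, 3): rigid per-frame ligand offset, so
      the aligned ligand rmsd trace is exactly its row norms and the z trace
      its z column;
    - ``contact_frequency``: {(chain, resnum): realised contact fraction};
    - ``water_counts``: per-frame waters within 3 Å of the 9′ gate;
    - ``breathing``: per-frame radial factor; ``ecd_radial_spread`` the exact
      radial spread ``ECD_RADIUS × factor``.

    Frame 0 always carries zero ligand displacement (the "experimental pose").
    The protein wall is static except contact-scheduled residues, which move
    their side-chain pseudo-atoms (never any alignment atom) in or out of the
    4.5 Å contact shell.
    """
    pm = toy_prime_map(spec)
    _validate_schedule(spec, pm)
    rng = spec.rng()
    n = spec.n_frames
    if n < 1:
        raise SpecError("n_frames must be >= 1")

    wc, wr, wn, wa, wx, _ = _channel_arrays(spec)
    chains, resnums, resnames, atomnames, xyz = [], [], [], [], []
    # interleave each chain's wall block with its pseudo upper-ECD block
    # (one CA pseudo-atom per residue, C5-symmetric) to keep chains contiguous
    for ci, chain_id in enumerate(_CHAIN_CLASSES):
        for i in range(len(wc)):
            if wc[i] == chain_id:
                chains.append(wc[i])
                resnums.append(wr[i])
                resnames.append(wn[i])
                atomnames.append(wa[i])
                xyz.append(wx[i])
        theta = math.radians(72.0 * ci)
        for j, resnum in enumerate(ECD_RESIDUES):
            chains.append(chain_id)
            resnums.append(resnum)
            resnames.append("GLY")
            atomnames.append("CA")
            xyz.append([ECD_RADIUS * math.cos(theta),
                        ECD_RADIUS * math.sin(theta), ECD_Z0 + j])
    wall_n = len(chains)
    ecd_idx = np.flatnonzero(np.isin(np.array(resnums), list(ECD_RESIDUES)))

    lig_base = _ligand_base(spec)
    lig_slice = slice(len(chains), len(chains) + len(lig_base))
    for i, p in enumerate(lig_base):
        chains.append(LIGAND_CHAIN)
        resnums.append(1)
        resnames.append(LIGAND_RESNAME)
        atomnames.append(f"C{i + 1}")
        xyz.append(list(p))

    water_plan = None
    if spec.water_plan is not None:
        water_plan = np.asarray(spec.water_plan, dtype=int)
        if len(water_plan) != n:
            raise SpecError("water_plan length must equal n_frames")
        if (water_plan < 0).any():
            raise SpecError("water counts must be non-negative")
        n_waters = int(water_plan.max())
        # one slot per water: 2.5 Å radially inward of a distinct 9' gate atom
        gate_mask = [i for i in range(wall_n)
                     if (chains[i], resnums[i]) in
                     {(c, pm.residue_number(cls, 9))
                      for c, cls in _CHAIN_CLASSES.items()}]
        if n_waters > len(gate_mask):
            raise SpecError(f"water plan needs {n_waters} inside slots, gate "
                            f"ring only offers {len(gate_mask)}")
        inside_slots = []
        for i in gate_mask[:n_waters]:
            p = np.array(xyz[i])
            u = p[:2] / np.hypot(p[0], p[1])
            inside_slots.append([p[0] - 2.5 * u[0], p[1] - 2.5 * u[1], p[2]])
        inside_slots = np.array(inside_slots).reshape(-1, 3)
        water_slice = slice(len(chains), len(chains) + n_waters)
        for w in range(n_waters):
            chains.append(WATER_CHAIN)
            resnums.append(w + 1)
            resnames.append("HOH")
            atomnames.append("O")
            xyz.append([40.0 + 5.0 * w, 40.0, 80.0])

    topo = _assemble(chains, resnums, resnames, atomnames, xyz)
    base = topo.coords.copy()

    # programmed rigid ligand displacement; frame 0 pinned to the start pose
    disp = np.zeros((n, 3))
    if spec.ligand_jitter_sigma > 0:
        disp[1:] = rng.normal(0.0, spec.ligand_jitter_sigma, size=(n - 1, 3))
    disp[:, 2] += spec.ligand_drift * np.arange(n)
    if spec.escape_frame is not None:
        t = np.arange(n)
        esc = np.maximum(0, t - spec.escape_frame + 1) * spec.escape_speed
        disp[:, 2] += esc

    breathing = (np.ones(n) if spec.breathing is None
                 else np.asarray(spec.breathing, dtype=float))
    if len(breathing) != n:
        raise SpecError("breathing length must equal n_frames")

    # contact schedule → per-residue boolean in/out per frame (leading frames
    # in contact so realised fraction = round(f·n)/n)
    schedule = {}
    for (chain, resnum), frac in spec.contact_schedule.items():
        k = int(round(frac * n))
        schedule[(chain, resnum)] = np.arange(n) < k
    contact_atom_idx = {
        key: np.flatnonzero((topo.chain_ids == key[0])
                            & (topo.res_numbers == key[1]))
        for key in schedule
    }
    for key, idx in contact_atom_idx.items():
        if idx.size == 0:
            raise SpecError(f"contact schedule names missing residue {key}")

    frames = np.empty((n, topo.n_atoms, 3))
    for t in range(n):
        coords = base.copy()
        coords[ecd_idx, 0] *= breathing[t]
        coords[ecd_idx, 1] *= breathing[t]
        coords[lig_slice] = lig_base + disp[t]
        lig_center = lig_base.mean(axis=0) + disp[t]
        for key, idx in contact_atom_idx.items():
            if schedule[key][t]:
                # park the residue's pseudo-atoms in a tight cluster 3 Å from
                # the ligand centre (inside the 4.5 Å any-atom shell)
                offs = 0.2 * np.arange(idx.size)[:, None] * np.array([[0, 0, 1.0]])
                coords[idx] = lig_center + np.array([3.0, 0.0, 0.0]) + offs
            else:
                coords[idx, 0] += 30.0   # radially out, far beyond the cutoff
        if water_plan is not None:
            c = int(water_plan[t])
            coords[water_slice][:] = base[water_slice]
            if c:
                coords[water_slice.start:water_slice.start + c] = inside_slots[:c]
        frames[t] = coords

    traj = Trajectory(topology=topo, frames=frames,
                      frame_interval=spec.frame_interval)
    truth = {
        "ligand_displacement": disp,
        "ligand_rmsd": np.linalg.norm(disp, axis=1),
        "ligand_z": disp[:, 2].copy(),
        "contact_frequency": {key: float(schedule[key].mean())
                              for key in schedule},
        "water_counts": None if water_plan is None else water_plan.copy(),
        "breathing": breathing.copy(),
        "ecd_radial_spread": ECD_RADIUS * breathing,
        "subunit_map": toy_subunit_map(),
        "prime_map": pm,
        "ligand_selection_expr": f"resname {LIGAND_RESNAME}",
        "align_selection_expr": "protein and name CA",
        "spec": spec,
    }
    return traj, truth


def make_unbinding_trajectory(spec: SyntheticSpec):
    """Trajectory whose ligand departs its pocket at ``spec.escape_frame``.

    After the escape frame the ligand recedes along +z at ``escape_speed``
    Å/frame, so the raw aligned rmsd trace crosses any crop threshold a fixed
    number of frames later (threshold / escape_speed). A spec without an
    escape frame yields a bound trajectory with no crop events.
    """
    if spec.escape_frame is not None and not (0 <= spec.escape_frame < spec.n_frames):
        raise SpecError("escape_frame outside trajectory")
    return make_toy_trajectory(spec)
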