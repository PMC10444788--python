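"""Structure and trajectory I/O, selections, subunit conventions and rigid-body geometry.

This module is the plumbing layer for analysing pentameric ligand-gated ion
channel (pLGIC) models such as the synaptic α1β2γ2 GABA_A receptor: reading
PDB/mmCIF coordinates, multi-model PDB trajectories, mapping M2 pore-lining
residues to the conventional prime numbering (−2′ … 20′, 9′ = activation-gate
leucine), Kabsch superposition and alignment of the pseudo-C5 pore axis to +z.

Coordinates are Å throughout; residue numbers are 1-based author numbering;
internal atom indices are 0-based half-open.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "Trajectory",
    "SubunitMap",
    "PrimeMap",
    "Selection",
    "RigidTransform",
    "AxisFrame",
    "FormatError",
    "SelectionError",
    "GeometryError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "select",
    "build_prime_map",
    "superpose",
    "align_pore_axis",
    "DEFAULT_FRAME_INTERVAL_NS",
    "DEFAULT_PRIME_ANCHORS",
    "ATOMIC_MASSES",
    "WATER_RESNAMES",
    "AMINO_ACIDS",
]

# Sampling interval of the production trajectories this package targets.
DEFAULT_FRAME_INTERVAL_NS = 0.4

# 9' activation-gate leucine residue numbers for the α1β2γ2 receptor
# (author numbering of the deposited models; γ derived from the 20' pull
# residue γ2-285 = anchor + 11).
DEFAULT_PRIME_ANCHORS = {"alpha": 264, "beta": 259, "gamma": 274}

PRIME_MIN, PRIME_MAX = -2, 20

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE HSD HSE HSP".split()
)
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "CL": 35.45, "NA": 22.990, "K": 39.098,
}
_DEFAULT_MASS = 12.011


class FormatError(ValueError):
    """A coordinate file failed to parse under its declared standard."""


class SelectionError(ValueError):
    """A selection expression resolved to no atoms or referenced missing atoms."""


class GeometryError(ValueError):
    """Degenerate geometry (too few / collinear atoms, wrong oligomeric state)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A single coordinate model as parallel numpy arrays (one entry per atom)."""

    chain_ids: np.ndarray      # <U4
    res_numbers: np.ndarray    # int64
    icodes: np.ndarray         # <U1, ' ' when absent
    res_names: np.ndarray      # <U4
    atom_names: np.ndarray     # <U4
    elements: np.ndarray       # <U2, upper-case
    coords: np.ndarray         # (n, 3) float64, Å
    altlocs: np.ndarray        # <U1, '' or one letter
    occupancies: np.ndarray    # float64 in [0, 1]
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n == 0:
            raise FormatError("empty model: structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates in structure")
        for name in ("chain_ids", "res_numbers", "icodes", "res_names",
                     "atom_names", "elements", "altlocs", "occupancies"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"field {name} has length {arr.shape[0]}, expected {n}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            chain_ids=self.chain_ids[idx],
            res_numbers=self.res_numbers[idx],
            icodes=self.icodes[idx],
            res_names=self.res_names[idx],
            atom_names=self.atom_names[idx],
            elements=self.elements[idx],
            coords=self.coords[idx],
            altlocs=self.altlocs[idx],
            occupancies=self.occupancies[idx],
            model_id=self.model_id,
        )

    def copy(self) -> "Structure":
        return self.subset(np.arange(self.n_atoms))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(-1, 3).copy()
        if out.coords.shape != self.coords.shape:
            raise ValueError("coordinate array shape mismatch")
        return out

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, _DEFAULT_MASS) for e in self.elements])

    def residue_keys(self) -> np.ndarray:
        """Per-atom (chain, resnum, icode) key as a structured view for grouping."""
        return np.rec.fromarrays(
            [self.chain_ids, self.res_numbers, self.icodes],
            names="chain,resnum,icode",
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``frame_interval`` is the
    sampling interval in ns (default 0.4 ns, the production sampling rate of
    the simulations this package post-processes).
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"topology mismatch: frames carry {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class SubunitMap:
    """chain id → subunit class ('alpha'|'beta'|'gamma'); copy index is positional."""

    chain_to_class: dict
    stoichiometry_check: bool = True

    def __post_init__(self) -> None:
        bad = {c for c in self.chain_to_class.values()
               if c not in ("alpha", "beta", "gamma")}
        if bad:
            raise ValueError(f"unknown subunit classes: {sorted(bad)}")
        if self.stoichiometry_check:
            if len(self.chain_to_class) != 5:
                raise GeometryError(
                    f"pentamer expected: got {len(self.chain_to_class)} chains"
                )
            counts = {k: 0 for k in ("alpha", "beta", "gamma")}
            for c in self.chain_to_class.values():
                counts[c] += 1
            if counts != {"alpha": 2, "beta": 2, "gamma": 1}:
                raise GeometryError(
                    f"α1β2γ2 stoichiometry 2/2/1 expected, got {counts}"
                )

    def chains(self) -> list:
        return list(self.chain_to_class)

    def class_of(self, chain_id: str) -> str:
        return self.chain_to_class[chain_id]


@dataclass(frozen=True)
class PrimeMap:
    """M2 prime numbering: residue(k) = anchor + (k − 9) per subunit class.

    ``anchors`` maps class → residue number of the 9′ activation-gate leucine.
    Valid prime indices are −2 … 20 (cytoplasmic desensitisation gate to the
    extracellular end of M2).
    """

    anchors: dict

    def residue_number(self, subunit_class: str, prime: int) -> int:
        if not (PRIME_MIN <= prime <= PRIME_MAX):
            raise ValueError(f"prime index {prime} outside [{PRIME_MIN}, {PRIME_MAX}]")
        return self.anchors[subunit_class] + (prime - 9)

    def prime_of(self, subunit_class: str, residue_number: int):
        k = residue_number - self.anchors[subunit_class] + 9
        return k if PRIME_MIN <= k <= PRIME_MAX else None

    def residue_range(self, subunit_class: str):
        return (self.residue_number(subunit_class, PRIME_MIN),
                self.residue_number(subunit_class, PRIME_MAX))


@dataclass(frozen=True)
class Selection:
    """Resolved atom indices into a Structure, plus the expression used."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise SelectionError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x ↦ R·x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class AxisFrame:
    """Pore axis as origin + unit direction (in the frame of the structure)."""

    origin: np.ndarray
    direction: np.ndarray

    @staticmethod
    def z_axis() -> "AxisFrame":
        return AxisFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _structure_from_model(model: "gemmi.Model", altloc_policy: str = "best") -> Structure:
    chain_ids, res_numbers, icodes, res_names = [], [], [], []
    atom_names, elements, altlocs, occs = [], [], [], []
    xyz = []
    for chain in model:
        for res in chain:
            # altloc policy: keep the highest-occupancy alternate, ties broken
            # alphabetically, so downstream geometry sees a single conformer
            groups: dict = {}
            for atom in res:
                groups.setdefault(atom.name, []).append(atom)
            for name in groups:
                atoms = groups[name]
                if altloc_policy == "best" and len(atoms) > 1:
                    atoms = sorted(atoms, key=lambda a: (-a.occ, a.altloc))[:1]
                for atom in atoms:
                    chain_ids.append(chain.name)
                    res_numbers.append(res.seqid.num)
                    icodes.append(res.seqid.icode if res.seqid.icode.strip() else " ")
                    res_names.append(res.name)
                    atom_names.append(atom.name)
                    elements.append(atom.element.name.upper())
                    altlocs.append(atom.altloc)
                    occs.append(atom.occ)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise FormatError("empty model: no atoms parsed")
    return Structure(
        chain_ids=np.array(chain_ids, dtype="U4"),
        res_numbers=np.array(res_numbers, dtype=np.int64),
        icodes=np.array(icodes, dtype="U1"),
        res_names=np.array(res_names, dtype="U4"),
        atom_names=np.array(atom_names, dtype="U4"),
        elements=np.array(elements, dtype="U2"),
        coords=np.array(xyz, dtype=float),
        altlocs=np.array(altlocs, dtype="U1"),
        occupancies=np.array(occs, dtype=float),
        model_id=model.num,
    )


def _read_gemmi(path, fmt: str) -> "gemmi.Structure":
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"failed to parse {path!r} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path!r}: file contains no models")
    return st


def read_structure(path, format: str = "auto", model: int | None = None) -> Structure:
    """Read one model from a PDB or mmCIF file.

    Returns the first model unless ``model`` (a 1-based model number) is given.
    The highest-occupancy alternate location is kept per atom, ties broken
    alphabetically by altloc id.
    """
    st = _read_gemmi(path, format)
    if model is None:
        gm = st[0]
    else:
        matches = [m for m in st if m.num == model]
        if not matches:
            raise FormatError(f"{path!r}: no model numbered {model}")
        gm = matches[0]
    return _structure_from_model(gm)


def read_trajectory(path, topology: Structure | None = None,
                    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS,
                    format: str = "auto") -> Trajectory:
    """Read a coordinate trajectory.

    Multi-model PDB is the native dialect: every MODEL block is one frame and
    all models must carry the same atoms. Binary formats (DCD/XTC/TRR) are
    supported when MDAnalysis is installed, in which case ``topology`` must be
    provided as the structure matching the trajectory atoms.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if format == "auto" and ext in (".dcd", ".xtc", ".trr"):
        format = "binary"
    if format == "binary":
        return _read_binary_trajectory(path, topology, frame_interval)
    st = _read_gemmi(path, "auto" if format == "auto" else format)
    topo = topology if topology is not None else _structure_from_model(st[0])
    frames = []
    for gm in st:
        s = _structure_from_model(gm)
        if s.n_atoms != topo.n_atoms:
            raise FormatError(
                f"model {gm.num} has {s.n_atoms} atoms, topology has {topo.n_atoms}"
            )
        frames.append(s.coords)
    return Trajectory(topology=topo, frames=np.stack(frames),
                      frame_interval=frame_interval)


def _read_binary_trajectory(path, topology, frame_interval) -> Trajectory:
    if topology is None:
        raise ValueError("binary trajectories require an explicit topology Structure")
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "reading binary trajectory formats requires MDAnalysis "
            "(install the 'traj' extra)"
        ) from exc
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    u.load_new(str(path))
    frames = np.stack([u.trajectory.ts.positions.copy().astype(float)
                       for _ in u.trajectory])
    return Trajectory(topology=topology, frames=frames, frame_interval=frame_interval)


def _to_gemmi(structures) -> "gemmi.Structure":
    st = gemmi.Structure()
    st.name = "porescope"
    for i, s in enumerate(structures):
        model = gemmi.Model(i + 1)
        chain = None
        res = None
        last_chain = None
        last_res = None
        for j in range(s.n_atoms):
            ckey = s.chain_ids[j]
            rkey = (ckey, int(s.res_numbers[j]), s.icodes[j], s.res_names[j])
            if ckey != last_chain:
                chain = gemmi.Chain(str(ckey))
                model.add_chain(chain)
                chain = model[-1]
                last_chain = ckey
                last_res = None
            if rkey != last_res:
                res = gemmi.Residue()
                res.name = str(s.res_names[j])
                ic = s.icodes[j]
                res.seqid = gemmi.SeqId(int(s.res_numbers[j]),
                                        ic if ic.strip() else " ")
                res.het_flag = "A" if s.res_names[j] in AMINO_ACIDS else "H"
                chain.add_residue(res)
                res = chain[-1]
                last_res = rkey
            atom = gemmi.Atom()
            atom.name = str(s.atom_names[j])
            atom.element = gemmi.Element(str(s.elements[j]).capitalize())
            atom.altloc = str(s.altlocs[j]) if s.altlocs[j].strip() else "\0"
            atom.occ = float(s.occupancies[j])
            x, y, z = s.coords[j]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    _to_gemmi([structure]).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as multi-model PDB (one MODEL block per frame)."""
    _to_gemmi([traj.topology.with_coords(f) for f in traj.frames]).write_pdb(str(path))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_int_list(spec: str):
    """'248-270,275' → per-atom membership test values."""
    singles, ranges = [], []
    for tok in spec.split(","):
        tok = tok.strip()
        if "-" in tok[1:]:  # allow negative single numbers
            cut = tok.index("-", 1)
            ranges.append((int(tok[:cut]), int(tok[cut + 1:])))
        else:
            singles.append(int(tok))
    return singles, ranges


def select(structure: Structure, expression: str) -> Selection:
    """Resolve a simple selection expression to atom indices.

    Clauses joined by ``and``; supported clauses::

        chain A,B          resnum 248-270,300      resname DHS,HOH
        name CA,CB         element C,O             protein
        water              heavy                   not water

    ``protein`` matches standard amino-acid residue names; ``heavy`` excludes
    hydrogens. Raises :class:`SelectionError` if no atom matches.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        clause = clause.strip()
        if not clause:
            continue
        negate = False
        if clause.startswith("not "):
            negate = True
            clause = clause[4:].strip()
        parts = clause.split(None, 1)
        kw = parts[0].lower()
        arg = parts[1] if len(parts) > 1 else ""
        if kw == "chain":
            m = np.isin(structure.chain_ids, [t.strip() for t in arg.split(",")])
        elif kw == "resnum":
            singles, ranges = _parse_int_list(arg)
            m = np.isin(structure.res_numbers, singles)
            for lo, hi in ranges:
                m |= (structure.res_numbers >= lo) & (structure.res_numbers <= hi)
        elif kw == "resname":
            m = np.isin(structure.res_names, [t.strip() for t in arg.split(",")])
        elif kw == "name":
            m = np.isin(structure.atom_names, [t.strip() for t in arg.split(",")])
        elif kw == "element":
            m = np.isin(structure.elements,
                        [t.strip().upper() for t in arg.split(",")])
        elif kw == "protein":
            m = np.isin(structure.res_names, list(AMINO_ACIDS))
        elif kw == "water":
            m = np.isin(structure.res_names, list(WATER_RESNAMES))
        elif kw == "heavy":
            m = structure.elements != "H"
        else:
            raise SelectionError(f"unknown selection keyword {kw!r}")
        mask &= ~m if negate else m
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return Selection(indices=idx, expression=expression)


def residue_selection(structure: Structure, chain_id: str, residue_number: int) -> Selection:
    mask = (structure.chain_ids == chain_id) & (structure.res_numbers == residue_number)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"no atoms for chain {chain_id} residue {residue_number}")
    return Selection(indices=idx, expression=f"chain {chain_id} and resnum {residue_number}")


# ---------------------------------------------------------------------------
# Prime numbering
# ---------------------------------------------------------------------------

def build_prime_map(structure: Structure, subunits: SubunitMap,
                    anchors: dict | None = None) -> PrimeMap:
    """Build the M2 prime-numbering map, checking anchors against the structure.

    ``anchors`` maps subunit class → residue number of the 9′ residue
    (defaults to the shipped α1β2γ2 convention: α 264, β 259, γ 274). Prime k
    then resolves to residue ``anchor + (k − 9)``. An anchor residue that is
    present but not leucine triggers a warning only, to support engineered
    gate mutants. Insertion codes inside the M2 span are rejected because the
    anchor+offset rule assumes contiguous numbering.
    """
    anchors = dict(DEFAULT_PRIME_ANCHORS if anchors is None else anchors)
    pm = PrimeMap(anchors=anchors)
    for chain_id, cls in subunits.chain_to_class.items():
        on_chain = structure.chain_ids == chain_id
        if not on_chain.any():
            raise SelectionError(f"chain {chain_id!r} not present in structure")
        anchor = anchors[cls]
        at_anchor = on_chain & (structure.res_numbers == anchor)
        if not at_anchor.any():
            raise SelectionError(
                f"anchor residue {anchor} missing on chain {chain_id} ({cls})"
            )
        names = set(structure.res_names[at_anchor])
        if names != {"LEU"}:
            warnings.warn(
                f"9' anchor {cls} {anchor} on chain {chain_id} is {sorted(names)}, "
                "not LEU (engineered construct?)", stacklevel=2,
            )
        lo, hi = pm.residue_range(cls)
        span = on_chain & (structure.res_numbers >= lo) & (structure.res_numbers <= hi)
        if np.any(structure.icodes[span] != " "):
            raise ValueError(
                f"insertion codes inside M2 span {lo}-{hi} on chain {chain_id}: "
                "prime arithmetic assumes contiguous numbering"
            )
    return pm


def prime_ring_selection(structure: Structure, subunits: SubunitMap,
                         prime_map: PrimeMap, prime: int,
                         heavy_only: bool = True) -> Selection:
    """All atoms of the five residues at one prime position (the 'ring')."""
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for chain_id, cls in subunits.chain_to_class.items():
        resnum = prime_map.residue_number(cls, prime)
        mask |= (structure.chain_ids == chain_id) & (structure.res_numbers == resnum)
    if heavy_only:
        mask &= structure.elements != "H"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"no atoms found for prime ring {prime}'")
    return Selection(indices=idx, expression=f"prime {prime}' ring")


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def _kabsch(mobile_xyz: np.ndarray, ref_xyz: np.ndarray):
    """Least-squares rigid superposition (Kabsch); returns transform and rmsd."""
    mobile_xyz = np.asarray(mobile_xyz, dtype=float)
    ref_xyz = np.asarray(ref_xyz, dtype=float)
    n = mobile_xyz.shape[0]
    cm, cr = mobile_xyz.mean(axis=0), ref_xyz.mean(axis=0)
    a, b = mobile_xyz - cm, ref_xyz - cr
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = cr - R @ cm
    # rmsd from the actual residuals (more accurate near zero than the
    # optimiser's reported rssd)
    resid = a @ R.T - b
    rmsd = np.sqrt((resid ** 2).sum(axis=1).mean())
    return RigidTransform(rotation=R, translation=t), float(rmsd)


def superpose(mobile: Structure, reference: Structure,
              selection: Selection | tuple | None = None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    ``selection`` may be a single :class:`Selection` applied to both
    structures (atom-count equality required), a (mobile_sel, reference_sel)
    pair, or None to pair all atoms in order. Returns ``(RigidTransform,
    rmsd)`` where rmsd (Å) is the least-squares minimum over all proper rigid
    transforms.
    """
    if selection is None:
        mi = np.arange(mobile.n_atoms)
        ri = np.arange(reference.n_atoms)
    elif isinstance(selection, tuple):
        mi, ri = selection[0].indices, selection[1].indices
    else:
        mi = ri = selection.indices
    if mi.size != ri.size:
        raise GeometryError(
            f"paired selections differ in size: {mi.size} vs {ri.size}"
        )
    if mi.size < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    a = mobile.coords[mi]
    b = reference.coords[ri]
    # collinearity check: rank of centred coordinates must be >= 2
    if np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) atom set for superposition")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return _kabsch(a, b)


def apply_transform(structure: Structure, transform: RigidTransform) -> Structure:
    return structure.with_coords(transform.apply(structure.coords))


def align_pore_axis(structure: Structure, subunits: SubunitMap,
                    prime_map: PrimeMap | None = None,
                    m2_selection_per_chain: dict | None = None,
                    ecd_selection: Selection | None = None):
    """Rotate/translate a pentamer so its pseudo-C5 pore axis is +z.

    The axis is the normal of the plane through the five per-subunit M2 Cα
    centroids (eigenvector of the centroid ring's smallest principal moment),
    signed so the bulk of the receptor mass beyond the ring — the ECD — lies
    at +z. The ring centroid is moved to the origin. Returns ``(aligned
    structure, AxisFrame in the input frame)``.

    M2 residues are taken from ``m2_selection_per_chain`` (chain id →
    Selection) when given, otherwise from the prime map span −2′…20′.
    """
    chains = subunits.chains()
    if len(chains) != 5:
        raise GeometryError(f"pentamer expected, got {len(chains)} chains")
    if prime_map is None and m2_selection_per_chain is None:
        prime_map = build_prime_map(structure, subunits)
    centroids = []
    for chain_id in chains:
        if m2_selection_per_chain is not None:
            idx = m2_selection_per_chain[chain_id].indices
        else:
            cls = subunits.class_of(chain_id)
            lo, hi = prime_map.residue_range(cls)
            mask = ((structure.chain_ids == chain_id)
                    & (structure.res_numbers >= lo)
                    & (structure.res_numbers <= hi)
                    & (structure.atom_names == "CA"))
            idx = np.flatnonzero(mask)
            if idx.size == 0:  # synthetic channels may carry no CA atoms
                mask = ((structure.chain_ids == chain_id)
                        & (structure.res_numbers >= lo)
                        & (structure.res_numbers <= hi))
                idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"no M2 atoms on chain {chain_id}")
        centroids.append(structure.coords[idx].mean(axis=0))
    centroids = np.asarray(centroids)
    center = centroids.mean(axis=0)
    ring = centroids - center
    # plane normal = eigenvector of the smallest eigenvalue of the ring covariance
    evals, evecs = np.linalg.eigh(ring.T @ ring)
    axis = evecs[:, 0]
    # sign: the receptor's extracellular domain carries the bulk of the mass
    # beyond the M2 ring, so point the axis toward the mean atom position
    if ecd_selection is not None:
        probe = structure.coords[ecd_selection.indices].mean(axis=0)
    else:
        probe = structure.coords.mean(axis=0)
    if np.dot(probe - center, axis) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), axis[None, :])
    R = rot.as_matrix()
    transform = RigidTransform(rotation=R, translation=-R @ center)
    aligned = apply_transform(structure, transform)
    return aligned, AxisFrame(origin=center, direction=axis)
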