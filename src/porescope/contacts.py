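"""Residue–ligand contact-frequency fingerprints and replicate aggregation.

A residue is "in contact" in a frame iff any of its heavy atoms lies within a
distance cutoff (default 4.5 Å) of any ligand heavy atom; its frequency is the
fraction of frames in contact. This aggregate any-heavy-atom criterion stands
in for typed interaction fingerprints: the reported quantity is a single
interaction frequency per residue, and a plain distance criterion is
reproducible without parameterised chemistry. The cutoff is configurable and
recorded in every output.

Replicate summaries report per-residue sample mean ± sd (n−1 denominator)
across independent simulation replicates, and the frequent-contact rule keeps
residues whose mean frequency is ≥ 50% (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import (
    AMINO_ACIDS,
    PrimeMap,
    Selection,
    SubunitMap,
    Trajectory,
)

__all__ = [
    "ContactTable",
    "ContactSummary",
    "contact_frequencies",
    "summarize_replicates",
    "frequent_contacts",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Å, any-heavy-atom criterion


@dataclass
class ContactTable:
    """Per-residue contact frequency for one trajectory."""

    frequencies: dict             # (chain, resnum) -> fraction in [0, 1]
    res_names: dict               # (chain, resnum) -> residue name
    cutoff: float
    frames_counted: int

    def to_frame(self, prime_map: PrimeMap | None = None,
                 subunits: SubunitMap | None = None) -> pd.DataFrame:
        rows = []
        for (chain, resnum), f in sorted(self.frequencies.items()):
            prime = None
            if prime_map is not None and subunits is not None:
                prime = prime_map.prime_of(subunits.class_of(chain), resnum)
            rows.append({"chain": chain, "residue_number": resnum,
                         "residue_name": self.res_names[(chain, resnum)],
                         "prime_index": prime, "frequency": f})
        return pd.DataFrame(rows)


@dataclass
class ContactSummary:
    """Mean ± sd of contact frequencies across replicates."""

    mean: dict                    # (chain, resnum) -> mean frequency
    sd: dict                      # (chain, resnum) -> sample sd
    n_replicates: int
    cutoff: float
    res_names: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chain": c, "residue_number": r,
                 "residue_name": self.res_names.get((c, r), ""),
                 "mean": self.mean[(c, r)], "sd": self.sd[(c, r)],
                 "n": self.n_replicates}
                for (c, r) in sorted(self.mean)]
        return pd.DataFrame(rows)


def contact_frequencies(traj: Trajectory, ligand: Selection,
                        cutoff: float = DEFAULT_CONTACT_CUTOFF,
                        residue_universe: str = "protein") -> ContactTable:
    """Contact frequency of every candidate residue with the ligand.

    ``residue_universe`` is ``"protein"`` (standard amino acids only; waters,
    lipids and the ligand itself are excluded) or ``"all"`` (everything except
    the ligand and waters).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory: no frames to count")
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    topo = traj.topology
    lig_idx = ligand.indices[topo.elements[ligand.indices] != "H"]
    if lig_idx.size == 0:
        raise ValueError("ligand selection has no heavy atoms")

    mask = topo.elements != "H"
    mask[lig_idx] = False
    if residue_universe == "protein":
        mask &= np.isin(topo.res_names, list(AMINO_ACIDS))
    else:
        from .structio import WATER_RESNAMES
        mask &= ~np.isin(topo.res_names, list(WATER_RESNAMES))
        mask[ligand.indices] = False
    cand = np.flatnonzero(mask)
    # group candidate atoms by residue once
    keys = list(zip(topo.chain_ids[cand].tolist(),
                    topo.res_numbers[cand].tolist()))
    uniq = sorted(set(keys))
    key_to_row = {k: i for i, k in enumerate(uniq)}
    atom_rows = np.array([key_to_row[k] for k in keys])
    res_names = {}
    for k, i in zip(keys, cand):
        res_names.setdefault(k, topo.res_names[i])

    counts = np.zeros(len(uniq), dtype=int)
    for t in range(traj.n_frames):
        tree = cKDTree(traj.frames[t][lig_idx])
        d, _ = tree.query(traj.frames[t][cand], k=1,
                          distance_upper_bound=cutoff + 1e-12)
        hit_rows = np.unique(atom_rows[np.isfinite(d) & (d <= cutoff)])
        counts[hit_rows] += 1
    freqs = {k: counts[i] / traj.n_frames for k, i in key_to_row.items()}
    return ContactTable(frequencies=freqs, res_names=res_names, cutoff=cutoff,
                        frames_counted=traj.n_frames)


def summarize_replicates(tables) -> ContactSummary:
    """Per-residue sample mean and sd over ≥2 replicate contact tables.

    The residue universe is the union over replicates; a residue absent from a
    replicate contributes frequency 0 there (it was never in contact).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("replicate summary needs at least 2 tables")
    cutoffs = {t.cutoff for t in tables}
    if len(cutoffs) > 1:
        raise ValueError(f"replicates used different cutoffs: {sorted(cutoffs)}")
    keys = sorted(set().union(*(t.frequencies for t in tables)))
    mat = np.array([[t.frequencies.get(k, 0.0) for k in keys] for t in tables])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    res_names = {}
    for t in tables:
        for k, name in t.res_names.items():
            res_names.setdefault(k, name)
    return ContactSummary(mean=dict(zip(keys, mean.tolist())),
                          sd=dict(zip(keys, sd.tolist())),
                          n_replicates=len(tables), cutoff=tables[0].cutoff,
                          res_names=res_names)


def frequent_contacts(summary: ContactSummary, threshold: float = 0.5):
    """Residues whose mean frequency is ≥ threshold (inclusive).

    Returned as a list of (chain, resnum) keys sorted by frequency descending,
    then by residue number ascending.
    """
    hits = [(k, v) for k, v in summary.mean.items() if v >= threshold]
    hits.sort(key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    return [k for k, _ in hits]
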