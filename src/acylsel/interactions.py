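"""Time-averaged protein–ligand interaction fingerprints.

Heavy-atom contact maps at a 4 Å cutoff, hydrogen-bond occupancies with the
>10% reporting threshold, and arginine–adenine π-cation lifetimes. A
*lifetime* throughout is the fraction of trajectory frames in which the
interaction's geometric criterion holds (simple occupancy, the "fraction of
MD states" convention), not a continuous-segment duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traj_io import Trajectory

__all__ = [
    "ContactMap",
    "HBondRecord",
    "PiCationRecord",
    "contact_map",
    "find_hbonds",
    "filter_hbonds",
    "pi_cation",
]

_POLAR = {"N", "O", "S"}
_DH_BOND_MAX = 1.25  # Å; covalent donor-hydrogen bond detection


def _indices(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, str):
        return traj.select(selection)
    return np.asarray(selection, dtype=int)


def _heavy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return np.array(
        [i for i in idx if traj.topology[i].element != "H"], dtype=int
    )


@dataclass
class ContactMap:
    """Contact frequencies: protein residues × ligand heavy atoms."""

    table: pd.DataFrame  # values are fractions of frames in [0, 1]
    cutoff: float
    n_frames: int

    def nonzero_residues(self) -> list[str]:
        return list(self.table.index[(self.table > 0).any(axis=1)])


def contact_map(
    traj: Trajectory, ligand_sel, protein_sel, cutoff: float = 4.0
) -> ContactMap:
    """Per-(residue, ligand-atom) fraction of frames within ``cutoff``.

    Hydrogens are excluded on both sides: the 4 Å criterion is a heavy-atom
    contact convention, and acyl-chain hydrogens would double-count their
    carbons. A residue/atom pair counts in a frame when any heavy-atom
    distance is strictly below the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig = _heavy(traj, _indices(traj, ligand_sel))
    prot = _heavy(traj, _indices(traj, protein_sel))
    if lig.size == 0 or prot.size == 0:
        raise ValueError("contact_map needs non-empty heavy-atom selections")

    res_labels: list[str] = []
    res_of: list[int] = []
    for i in prot:
        lab = traj.topology[i].residue_label
        if not res_labels or res_labels[-1] != lab:
            res_labels.append(lab)
        res_of.append(len(res_labels) - 1)
    res_of_arr = np.asarray(res_of)

    lig_names = _unique_atom_labels(traj, lig)

    # (F, n_lig, n_prot) pair distances; selections are small so this fits
    diff = traj.coordinates[:, lig, None, :] - traj.coordinates[:, None, prot, :]
    close = (diff ** 2).sum(axis=-1) < cutoff ** 2

    freq = np.zeros((len(res_labels), lig.size))
    for r in range(len(res_labels)):
        cols = res_of_arr == r
        freq[r] = close[:, :, cols].any(axis=2).mean(axis=0)

    table = pd.DataFrame(
        freq, index=pd.Index(res_labels, name="residue"),
        columns=pd.Index(lig_names, name="ligand_atom"),
    )
    return ContactMap(table=table, cutoff=cutoff, n_frames=traj.n_frames)


def _unique_atom_labels(traj: Trajectory, idx: np.ndarray) -> list[str]:
    names = [traj.topology[i].name for i in idx]
    if len(set(names)) == len(names):
        return names
    return [f"{traj.topology[i].residue_label}:{traj.topology[i].name}" for i in idx]


@dataclass
class HBondRecord:
    """A donor–hydrogen···acceptor bond and its occupancy lifetime."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    donor_residue: str
    acceptor_residue: str
    donor_atom: str
    acceptor_atom: str
    lifetime: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lifetime <= 1.0:
            raise ValueError("lifetime must lie in [0, 1]")


def find_hbonds(
    traj: Trajectory,
    donors_sel,
    acceptors_sel,
    d_max: float = 3.5,
    angle_max: float = 30.0,
) -> list[HBondRecord]:
    """Hydrogen bonds between donor and acceptor selections.

    A (D, H, A) triple counts in a frame when the donor–acceptor distance
    is ≤ ``d_max`` and the H–D–A angle at the donor is ≤ ``angle_max`` (the
    classic gmx-hbond geometric criterion). Donors are polar heavy atoms of
    the donor selection with at least one covalently bonded hydrogen
    (detected at ≤ 1.25 Å in the first frame); donors without a hydrogen
    are skipped with a warning. Records with nonzero lifetime are returned;
    apply :func:`filter_hbonds` for the reporting threshold.
    """
    don_heavy = [i for i in _indices(traj, donors_sel)
                 if traj.topology[i].element in _POLAR]
    acc = [i for i in _indices(traj, acceptors_sel)
           if traj.topology[i].element in _POLAR]
    if not don_heavy or not acc:
        raise ValueError("find_hbonds needs polar donor and acceptor atoms")

    first = traj.coordinates[0]
    hydrogens = [i for i, a in enumerate(traj.topology) if a.element == "H"]
    pairs: list[tuple[int, int]] = []
    for d in don_heavy:
        rec = traj.topology[d]
        bonded = [
            h for h in hydrogens
            if traj.topology[h].chain_id == rec.chain_id
            and traj.topology[h].residue_number == rec.residue_number
            and np.linalg.norm(first[h] - first[d]) <= _DH_BOND_MAX
        ]
        if not bonded:
            warnings.warn(
                f"donor {rec.residue_label}:{rec.name} has no bonded hydrogen; skipped",
                stacklevel=2,
            )
            continue
        pairs.extend((d, h) for h in bonded)

    records: list[HBondRecord] = []
    coords = traj.coordinates
    cos_min = np.cos(np.radians(angle_max))
    for d, h in pairs:
        drec = traj.topology[d]
        dh = coords[:, h, :] - coords[:, d, :]
        dh_norm = np.linalg.norm(dh, axis=1)
        for a in acc:
            arec = traj.topology[a]
            if a == d or (
                arec.chain_id == drec.chain_id
                and arec.residue_number == drec.residue_number
            ):
                continue  # intra-residue pairs are not intermolecular bonds
            da = coords[:, a, :] - coords[:, d, :]
            da_norm = np.linalg.norm(da, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (dh * da).sum(axis=1) / (dh_norm * da_norm)
            hit = (da_norm <= d_max) & (cosang >= cos_min)
            lifetime = float(hit.mean())
            if lifetime > 0:
                records.append(
                    HBondRecord(
                        donor_index=d,
                        hydrogen_index=h,
                        acceptor_index=a,
                        donor_residue=drec.residue_label,
                        acceptor_residue=arec.residue_label,
                        donor_atom=drec.name,
                        acceptor_atom=arec.name,
                        lifetime=lifetime,
                    )
                )
    return records


def filter_hbonds(
    records: list[HBondRecord], min_lifetime: float = 0.10
) -> list[HBondRecord]:
    """Keep bonds with lifetime strictly above the reporting threshold.

    When pooling several trajectories, concatenate their record lists
    first: a bond (or residue) is reported if it passes in at least one
    trajectory.
    """
    return [r for r in records if r.lifetime > min_lifetime]


@dataclass
class PiCationRecord:
    """A cation/aromatic-ring stacking interaction and its lifetime."""

    cation_residue: str
    ring_residue: str
    lifetime: float
    d_max: float
    tilt_max: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lifetime <= 1.0:
            raise ValueError("lifetime must lie in [0, 1]")


def pi_cation(
    traj: Trajectory,
    cation_sel,
    ring_sel,
    d_max: float = 6.0,
    tilt_max: float = 45.0,
) -> PiCationRecord:
    """π-cation lifetime between a cation atom and an aromatic ring.

    The cation position is a single atom (for arginine, the central
    guanidinium carbon CZ); the ring is given by ≥ 5 atoms (for adenine,
    the purine six-membered ring). A frame counts when the cation sits
    within ``d_max`` Å of the ring centroid and within ``tilt_max`` degrees
    of the ring normal.
    """
    cat = _indices(traj, cation_sel)
    ring = _indices(traj, ring_sel)
    if cat.size != 1:
        raise ValueError("cation selection must resolve to exactly 1 atom")
    if ring.size < 5:
        raise ValueError("ring selection needs at least 5 atoms to define a plane")
    cat_i = int(cat[0])

    ring_xyz = traj.coordinates[:, ring, :]
    centroid = ring_xyz.mean(axis=1)
    centered = ring_xyz - centroid[:, None, :]
    # batched plane fit: the normal is the singular vector of the smallest
    # singular value of each frame's centered ring coordinates
    _, svals, vts = np.linalg.svd(centered)
    if np.any(svals[:, 1] < 1e-6):
        raise ValueError("ring atoms are nearly collinear; plane is undefined")
    normals = vts[:, 2, :]

    to_cat = traj.coordinates[:, cat_i, :] - centroid
    dist = np.linalg.norm(to_cat, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        costilt = np.abs((to_cat * normals).sum(axis=1)) / np.where(dist > 0, dist, np.inf)
    tilt = np.degrees(np.arccos(np.clip(costilt, -1.0, 1.0)))
    hit = (dist <= d_max) & (tilt <= tilt_max)

    return PiCationRecord(
        cation_residue=traj.topology[cat_i].residue_label,
        ring_residue=traj.topology[int(ring[0])].residue_label,
        lifetime=float(hit.mean()),
        d_max=d_max,
        tilt_max=tilt_max,
    )
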