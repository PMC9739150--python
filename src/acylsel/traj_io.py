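"""Structure/trajectory reading and writing, and atom selections.

File parsing (PDB, GRO, and binary XTC/DCD streams) and the selection
grammar are delegated to :mod:`MDAnalysis`; this module wraps them behind
small immutable containers that carry author residue numbering, so that
catalytic positions such as Cys156 of hDHHC20 stay addressable by the
residue numbers used in the structural literature.

Coordinates are always Ångström internally (GRO nanometres are converted on
read). The canonical text trajectory dialect is multi-model PDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader

from ._masses import guess_element, mass_of

__all__ = [
    "AtomRecord",
    "MolecularFrame",
    "Trajectory",
    "SelectionExpr",
    "TrajectoryError",
    "read_structure",
    "read_trajectory",
    "resolve_selection",
    "write_trajectory",
]

#: Default analysis timestep (ps) assigned when a coordinate file carries no
#: time information. 100 ps is the coarse end of the usual post-processing
#: stride for long equilibrium runs.
DEFAULT_STRIDE_PS = 100.0


class TrajectoryError(RuntimeError):
    """Raised for malformed structures, frames or selections."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology, with author numbering and a standard mass."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    mass: float

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise TrajectoryError(
                f"atom {self.name!r} (serial {self.serial}) has non-positive mass"
            )

    @property
    def residue_label(self) -> str:
        """Human-readable residue tag, e.g. ``A:CYS156``."""
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}"


@dataclass
class MolecularFrame:
    """A single coordinate frame (Å) with an optional orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("frame coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("frame contains non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)[:3]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a shared topology.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)`` in Å; ``boxes`` is
    ``(n_frames, 3)`` orthorhombic box lengths or ``None``; ``times`` are
    picoseconds and strictly increasing.
    """

    topology: list[AtomRecord]
    coordinates: np.ndarray
    times: np.ndarray | None = None
    boxes: np.ndarray | None = None
    stride: float = DEFAULT_STRIDE_PS
    _mda_universe: mda.Universe | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                "trajectory coordinates must have shape (n_frames, n_atoms, 3)"
            )
        if self.n_frames < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        if self.coordinates.shape[1] != len(self.topology):
            raise TrajectoryError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {len(self.topology)}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("trajectory contains non-finite coordinates")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float) * self.stride
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise TrajectoryError("times length does not match frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)
            if self.boxes.ndim == 1:
                self.boxes = np.tile(self.boxes[:3], (self.n_frames, 1))
            self.boxes = self.boxes[:, :3]

    # -- basic queries ---------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def frame(self, i: int) -> MolecularFrame:
        box = self.boxes[i] if self.boxes is not None else None
        return MolecularFrame(self.coordinates[i], box=box, time=float(self.times[i]))

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression against this trajectory's topology."""
        return resolve_selection(expression, self.topology)


@dataclass(frozen=True)
class SelectionExpr:
    """A textual atom selection (MDAnalysis grammar)."""

    expression: str

    def resolve(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        return resolve_selection(self.expression, topology)


# ---------------------------------------------------------------------------
# MDAnalysis bridging
# ---------------------------------------------------------------------------

_UNIVERSE_CACHE: dict[int, tuple[object, mda.Universe]] = {}
_UNIVERSE_CACHE_MAX = 8


def topology_universe(topology: Sequence[AtomRecord]) -> mda.Universe:
    """An in-memory MDAnalysis Universe mirroring ``topology`` (cached)."""
    key = id(topology)
    hit = _UNIVERSE_CACHE.get(key)
    if hit is not None and hit[0] is topology:
        return hit[1]

    n = len(topology)
    res_keys: list[tuple[str, int, str]] = []
    resindex = np.empty(n, dtype=int)
    for i, a in enumerate(topology):
        rk = (a.chain_id, a.residue_number, a.residue_name)
        if not res_keys or res_keys[-1] != rk:
            res_keys.append(rk)
        resindex[i] = len(res_keys) - 1
    seg_keys = sorted({rk[0] for rk in res_keys})
    segindex = np.array([seg_keys.index(rk[0]) for rk in res_keys], dtype=int)

    u = mda.Universe.empty(
        n,
        n_residues=len(res_keys),
        atom_resindex=resindex,
        residue_segindex=segindex,
        n_segments=len(seg_keys),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in topology])
    u.add_TopologyAttr("elements", [a.element for a in topology])
    u.add_TopologyAttr("masses", [a.mass for a in topology])
    u.add_TopologyAttr("chainIDs", [a.chain_id for a in topology])
    u.add_TopologyAttr("resids", [rk[1] for rk in res_keys])
    u.add_TopologyAttr("resnames", [rk[2] for rk in res_keys])
    u.add_TopologyAttr("segids", seg_keys)

    if len(_UNIVERSE_CACHE) >= _UNIVERSE_CACHE_MAX:
        _UNIVERSE_CACHE.pop(next(iter(_UNIVERSE_CACHE)))
    _UNIVERSE_CACHE[key] = (topology, u)
    return u


def _topology_from_universe(u: mda.Universe) -> list[AtomRecord]:
    atoms = u.atoms
    names = atoms.names
    resnames = atoms.resnames
    resids = atoms.resids
    if hasattr(atoms, "chainIDs"):
        chains = [c if c.strip() else s for c, s in zip(atoms.chainIDs, atoms.segids)]
    else:
        chains = list(atoms.segids)
    have_elements = hasattr(atoms, "elements")
    topology: list[AtomRecord] = []
    for i in range(len(atoms)):
        element = atoms.elements[i].strip() if have_elements else ""
        if not element:
            element = guess_element(names[i], resnames[i])
        element = element.upper()
        topology.append(
            AtomRecord(
                serial=i + 1,
                name=str(names[i]),
                element=element,
                residue_name=str(resnames[i]),
                residue_number=int(resids[i]),
                chain_id=str(chains[i]),
                mass=mass_of(element),
            )
        )
    return topology


def _boxes_ok(dim: np.ndarray | None) -> bool:
    return dim is not None and np.all(np.asarray(dim)[:3] > 0)


def _open_universe(path: str | Path, topology_path: str | Path | None = None,
                   fmt: str | None = None) -> mda.Universe:
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if topology_path is not None:
                return mda.Universe(str(topology_path), str(path))
            return mda.Universe(str(path), format=fmt)
    except TrajectoryError:
        raise
    except Exception as exc:  # MDAnalysis raises a zoo of parse errors
        raise TrajectoryError(f"could not parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path, fmt: str | None = None
) -> tuple[list[AtomRecord], MolecularFrame]:
    """Read a single-model PDB or GRO file.

    Returns the topology (author residue numbering preserved) and the first
    coordinate frame in Å. GRO nanometre coordinates are converted by the
    reader.
    """
    u = _open_universe(path, fmt=fmt)
    topology = _topology_from_universe(u)
    ts = u.trajectory[0]
    box = ts.dimensions[:3].astype(float) if _boxes_ok(ts.dimensions) else None
    frame = MolecularFrame(ts.positions.astype(float), box=box, time=0.0)
    return topology, frame


def read_trajectory(
    path: str | Path,
    topology: str | Path | Sequence[AtomRecord] | None = None,
    stride: float = DEFAULT_STRIDE_PS,
) -> Trajectory:
    """Read a coordinate stream into a :class:`Trajectory`.

    ``path`` may be a multi-model (or single-model) PDB/GRO, or a binary
    XTC/DCD stream, in which case ``topology`` must name a structure file
    providing the atom topology. Frame times are taken from the file when
    present and strictly increasing, otherwise synthesised as
    ``i * stride`` ps.
    """
    top_path: str | Path | None = None
    records: list[AtomRecord] | None = None
    if topology is not None and not isinstance(topology, (str, Path)):
        records = list(topology)
    elif topology is not None:
        top_path = topology

    u = _open_universe(path, topology_path=top_path)
    if records is None:
        records = _topology_from_universe(u)
    if len(records) != len(u.atoms):
        raise TrajectoryError(
            f"topology atom count {len(records)} does not match "
            f"coordinate atom count {len(u.atoms)} in {path}"
        )

    n_atoms = len(u.atoms)
    coords, boxes, times = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers warn when dt is absent
        for i, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != n_atoms:
                raise TrajectoryError(f"atom-count mismatch at frame {i} of {path}")
            coords.append(ts.positions.astype(float).copy())
            boxes.append(
                ts.dimensions[:3].astype(float) if _boxes_ok(ts.dimensions) else None
            )
            times.append(float(getattr(ts, "time", 0.0)))

    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(times_arr), dtype=float) * stride
    box_arr = None
    if all(b is not None for b in boxes):
        box_arr = np.vstack(boxes)
    return Trajectory(
        topology=records,
        coordinates=np.asarray(coords),
        times=times_arr,
        boxes=box_arr,
        stride=stride,
    )


def resolve_selection(
    expression: str | SelectionExpr, topology: Sequence[AtomRecord]
) -> np.ndarray:
    """Resolve a selection string to an ascending array of atom indices.

    A pure function of (expression, topology): the same inputs always give
    the same ordered index set, and an expression matching nothing yields an
    empty array rather than an error.
    """
    if isinstance(expression, SelectionExpr):
        expression = expression.expression
    u = topology_universe(topology)
    try:
        group = u.select_atoms(expression)
    except Exception as exc:
        raise TrajectoryError(f"bad selection {expression!r}: {exc}") from exc
    return np.sort(group.ix.astype(int))


def write_trajectory(
    traj: Trajectory, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a trajectory as a multi-model PDB (or a GRO for one frame).

    Round-trips with :func:`read_trajectory` within format precision
    (1e-3 Å for PDB, 1e-2 Å for GRO).
    """
    path = Path(path)
    if traj.n_frames < 1:
        raise TrajectoryError("cannot write an empty trajectory")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in {"pdb", "gro"}:
        raise TrajectoryError(f"unsupported output format {fmt!r}")
    if fmt == "gro" and traj.n_frames > 1:
        raise TrajectoryError(
            "GRO holds a single frame; write each frame separately or use PDB"
        )

    u = topology_universe(traj.topology)
    if traj.boxes is not None:
        dims = np.hstack([traj.boxes, np.full((traj.n_frames, 3), 90.0)])
    else:
        dims = None
    u.load_new(
        traj.coordinates.astype(np.float32),
        format=MemoryReader,
        dimensions=dims,
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), traj.n_atoms, multiframe=(fmt == "pdb")) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return path
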