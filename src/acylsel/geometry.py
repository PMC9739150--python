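"""Elementary structural geometry.

Centers of mass, distances, bond/attack angles, membrane framing along the
laboratory Z axis, principal-axis orientation of a transmembrane helix
bundle, and Kabsch (optimal-superposition) RMSD. Everything operates on
plain ``(n_atoms, 3)`` or ``(n_frames, n_atoms, 3)`` Å coordinate arrays so
the higher-level analyses stay free of file-format concerns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MembraneFrame",
    "center_of_mass",
    "distance",
    "angle",
    "membrane_frame",
    "orient_by_principal_axis",
    "kabsch_rmsd",
]


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: Z = 0 at the bilayer center.

    The membrane normal is the laboratory Z axis; ``z_origin`` is the Å
    offset subtracted from laboratory Z so that the mean Z of the lipid
    phosphorus atoms becomes zero.
    """

    z_origin: float = 0.0
    normal_axis: int = 2

    def z(self, coordinates: np.ndarray) -> np.ndarray:
        """Membrane-frame Z of coordinates shaped ``(..., 3)``."""
        return np.asarray(coordinates)[..., self.normal_axis] - self.z_origin


def _as_frame(coordinates: np.ndarray) -> np.ndarray:
    arr = np.asarray(coordinates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected coordinates of shape (n_atoms, 3)")
    return arr


def center_of_mass(
    coordinates: np.ndarray,
    indices: np.ndarray | list[int],
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """(Optionally mass-weighted) center of a coordinate subset.

    Works on a single frame ``(n, 3)`` or a stack ``(F, n, 3)``; the result
    is ``(3,)`` or ``(F, 3)`` accordingly.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("center_of_mass of an empty selection")
    arr = np.asarray(coordinates, dtype=float)
    sub = arr[..., idx, :]
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted=True requires masses")
        w = np.asarray(masses, dtype=float)
        w = w[idx] if w.shape[0] != idx.shape[0] else w
        return (sub * w[:, None]).sum(axis=-2) / w.sum()
    return sub.mean(axis=-2)


def distance(coordinates: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance (Å) between atoms ``i`` and ``j`` of one frame.

    No periodic wrapping is applied: the analyses assume the complex is
    whole within the box after centering on the protein.
    """
    frame = _as_frame(coordinates)
    if i == j:
        warnings.warn("distance between an atom and itself is 0", stacklevel=2)
        return 0.0
    return float(np.linalg.norm(frame[i] - frame[j]))


def angle(coordinates: np.ndarray, a: int, b: int, c: int) -> float:
    """Angle a–b–c in degrees, vertex at ``b``, in [0, 180]."""
    frame = _as_frame(coordinates)
    if b == a or b == c:
        raise ValueError("angle vertex must differ from the end atoms")
    v1 = frame[a] - frame[b]
    v2 = frame[c] - frame[b]
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero-length vector in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def membrane_frame(
    coordinates: np.ndarray, lipid_p_indices: np.ndarray | list[int]
) -> MembraneFrame:
    """Membrane frame whose origin puts the lipid-phosphorus mean Z at 0."""
    idx = np.asarray(lipid_p_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("membrane_frame needs a non-empty lipid phosphorus selection")
    arr = np.asarray(coordinates, dtype=float)
    z_mean = float(arr[..., idx, 2].mean())
    return MembraneFrame(z_origin=z_mean)


def orient_by_principal_axis(
    coordinates: np.ndarray,
    tm_ca_indices: np.ndarray | list[int],
    upper_indices: np.ndarray | list[int] | None = None,
    lower_indices: np.ndarray | list[int] | None = None,
) -> np.ndarray:
    """Rotate coordinates so the TM-bundle principal axis lies along +Z.

    The first principal axis of the transmembrane Cα cloud is aligned with
    the laboratory Z axis, rotating about the cloud's centroid. When
    ``upper_indices``/``lower_indices`` are given (e.g. the cavity-ceiling
    triad and the catalytic residue), the sign of the axis is chosen so the
    upper group ends with the larger Z — the teepee cavity narrows toward
    the extracellular side, so the ceiling must sit above the catalytic
    site. Accepts ``(n, 3)`` or ``(F, n, 3)`` arrays.
    """
    arr = np.asarray(coordinates, dtype=float)
    single = arr.ndim == 2
    stack = arr[None] if single else arr
    idx = np.asarray(tm_ca_indices, dtype=int)
    if idx.size < 3:
        raise ValueError("principal-axis orientation needs at least 3 atoms")

    ref = stack[0][idx]
    centroid = ref.mean(axis=0)
    centered = ref - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-10 or evals[1] < 1e-10 * evals[-1]:
        raise ValueError("degenerate (collinear or pointlike) Cα cloud")
    axis = evecs[:, -1]

    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), axis[None])
    out = rot.apply((stack - centroid).reshape(-1, 3)).reshape(stack.shape) + centroid

    if upper_indices is not None and lower_indices is not None:
        up = np.asarray(upper_indices, dtype=int)
        lo = np.asarray(lower_indices, dtype=int)
        if out[0][up, 2].mean() < out[0][lo, 2].mean():
            flip = Rotation.from_euler("x", 180, degrees=True)
            out = flip.apply((out - centroid).reshape(-1, 3)).reshape(stack.shape)
            out = out + centroid
    return out[0] if single else out


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    indices: np.ndarray | list[int] | None = None,
) -> float:
    """Minimum RMSD (Å) over all rigid superpositions of two frames.

    Optimal proper rotation found by the Kabsch algorithm
    (``scipy.spatial.transform.Rotation.align_vectors``) after removing the
    centroids; symmetric in its arguments and zero iff the point sets are
    congruent.
    """
    a = _as_frame(coords_a)
    b = _as_frame(coords_b)
    if indices is not None:
        idx = np.asarray(indices, dtype=int)
        a, b = a[idx], b[idx]
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shapes")
    if a.shape[0] < 3:
        raise ValueError("Kabsch RMSD needs at least 3 atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(a.shape[0]))
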