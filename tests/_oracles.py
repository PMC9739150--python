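"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: distances and angles
are recomputed per component in plain Python, the optimal-superposition
RMSD comes from Horn's closed-form quaternion method (vs. the SVD route in
the package) and, for planar point sets, from an exhaustive single-axis
rotation grid.
"""

from __future__ import annotations

import math

import numpy as np


def brute_distance(frame, i, j) -> float:
    dx = frame[i][0] - frame[j][0]
    dy = frame[i][1] - frame[j][1]
    dz = frame[i][2] - frame[j][2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def brute_angle(frame, a, b, c) -> float:
    v1 = [frame[a][k] - frame[b][k] for k in range(3)]
    v2 = [frame[c][k] - frame[b][k] for k in range(3)]
    dot = sum(x * y for x, y in zip(v1, v2))
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, dot / (n1 * n2)))))


def horn_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    m = b.T @ a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = ((a ** 2).sum() + (b ** 2).sum() - 2.0 * lam) / a.shape[0]
    return math.sqrt(max(msd, 0.0))


def planar_grid_rmsd(a: np.ndarray, b: np.ndarray, step_deg: float = 0.5) -> float:
    """Exhaustive rotation search for z-planar point sets.

    For planar configurations the optimal proper 3D rotation acts within
    the plane, either directly or composed with a 180° flip about an
    in-plane axis (which mirrors the 2D coordinates), so scanning both
    branches over a fine single-axis grid is exhaustive.
    """
    a = np.asarray(a, float) - np.asarray(a, float).mean(axis=0)
    b = np.asarray(b, float) - np.asarray(b, float).mean(axis=0)
    assert np.allclose(a[:, 2], 0) and np.allclose(b[:, 2], 0)
    flipped = b * np.array([1.0, -1.0, -1.0])  # 180° about x: proper rotation
    best = np.inf
    for deg in np.arange(0.0, 360.0, step_deg):
        t = math.radians(deg)
        rot = np.array(
            [[math.cos(t), -math.sin(t), 0.0],
             [math.sin(t), math.cos(t), 0.0],
             [0.0, 0.0, 1.0]]
        )
        for cand in (b, flipped):
            rmsd = math.sqrt(((a - cand @ rot.T) ** 2).sum() / a.shape[0])
            best = min(best, rmsd)
    return best


def brute_contact_fractions(coords, lig_idx, prot_idx, residue_of, n_res, cutoff):
    """All-pairs per-frame contact fractions, nested loops only."""
    n_frames = coords.shape[0]
    freq = np.zeros((n_res, len(lig_idx)))
    for f in range(n_frames):
        for li, lig in enumerate(lig_idx):
            hit = set()
            for pj, prot in enumerate(prot_idx):
                if brute_distance(coords[f], lig, prot) < cutoff:
                    hit.add(residue_of[pj])
            for r in hit:
                freq[r, li] += 1
    return freq / n_frames


def brute_histogram2d_mode(x, y, x_edges, y_edges):
    """Mode of a 2D histogram by exhaustive bin scan (lowest-x, lowest-y ties)."""
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    counts = [[0] * ny for _ in range(nx)]
    for xi, yi in zip(x, y):
        for i in range(nx):
            last_x = i == nx - 1
            if x_edges[i] <= xi < x_edges[i + 1] or (last_x and xi == x_edges[-1]):
                for j in range(ny):
                    last_y = j == ny - 1
                    if y_edges[j] <= yi < y_edges[j + 1] or (last_y and yi == y_edges[-1]):
                        counts[i][j] += 1
                        break
                break
    best = max(max(row) for row in counts)
    for i in range(nx):
        for j in range(ny):
            if counts[i][j] == best:
                return (
                    0.5 * (x_edges[i] + x_edges[i + 1]),
                    0.5 * (y_edges[j] + y_edges[j + 1]),
                    np.array(counts),
                )
    raise AssertionError
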