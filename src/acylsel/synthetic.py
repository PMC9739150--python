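"""Seeded generator of toy hDHHC20-like systems with exact ground truth.

The generator builds a pseudo-protein that mimics the enzyme's topology —
four transmembrane helices leaning together into a teepee whose cavity
narrows toward the extracellular side, a ceiling triad (Ser29, Val185,
Ser217), the catalytic residue 156 at the cavity bottom, the Trp158 gate,
the CoA-binding cytosolic residues (Lys135, His140, His141, Ser143,
Arg246) — plus a slab of pseudo-lipid phosphorus atoms marking the bilayer
leaflets and an acyl-CoA-like ligand (thioester carbonyl, an n-carbon acyl
chain in ideal zig-zag geometry, a pyrophosphate-like group, an
adenine-like six-membered ring).

Per frame, D2 and αBD are drawn from truncated normal distributions and D1
from a normal, and the nucleophile/carbonyl/terminal atoms are *placed* to
realise the sampled values exactly; hydrogen bonds and the π-cation
geometry are toggled to prescribed occupancies. Every realised value is
recorded in a ground-truth ledger, so analysis results can be checked
against an exact oracle without running molecular dynamics. The analysis
modules never read the ledger.

The pseudo-protein is not a physical model: only the residue names,
numbers and the geometry consumed by selections are guaranteed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special
from scipy.stats import truncnorm

from ._masses import guess_element, mass_of
from .traj_io import AtomRecord, Trajectory, write_trajectory

__all__ = [
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "build_topology",
    "generate_trajectory",
    "make_benchmark_suite",
    "make_crystal_reference",
    "write_system",
    "BENCHMARK_REACTIVE_PROBABILITIES",
    "CRYSTAL_D1",
    "CRYSTAL_D2",
    "CRYSTAL_ABD",
]

# Crystal-pose geometry of the trapped mutant complex: the acyl tail tip
# 4.07 Å below the ceiling COM, the Ser156 hydroxyl O 6.6 Å from the
# thioester carbonyl carbon at a 127° attack angle.
CRYSTAL_D1 = -4.07
CRYSTAL_D2 = 6.6
CRYSTAL_ABD = 127.0

#: Benchmark reactive-state probabilities per chain length: the C16 chain
#: is geometrically optimal, shorter and longer chains fall off steeply.
BENCHMARK_REACTIVE_PROBABILITIES = {
    "C12": 0.05, "C14": 0.10, "C16": 0.60, "C18": 0.30, "C20": 0.08,
}

#: Per-chain D1 (Å) mean/sd emulation targets for the representative runs:
#: the tail tip always sits a couple of Å below the ceiling.
BENCHMARK_D1 = {
    "C12": (-2.7, 0.6), "C14": (-2.0, 0.6), "C16": (-2.1, 0.3),
    "C18": (-2.1, 0.8), "C20": (-1.9, 0.3),
}

_CEILING_Z = 8.1          # Å; triad heavy atoms sit at this Z exactly
_LEAFLET_Z = 17.5         # Å; |Z| of each pseudo-lipid P leaflet
_BOX = (64.0, 64.0, 80.0)
_CC_BOND = 1.53           # Å
_TETRA_HALF = np.radians(109.47 / 2.0)
_ZIG_RISE = _CC_BOND * np.sin(_TETRA_HALF)     # axial advance per C-C bond
_ZIG_X = _CC_BOND * np.cos(_TETRA_HALF)        # lateral zig-zag offset
_CO_BOND = 1.23           # Å carbonyl C=O


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic system.

    D2 and αBD follow truncated normals; D1 is normal. H-bond and π-cation
    occupancies are target frame fractions; with deterministic toggling the
    realised lifetime is exactly ``round(occ · n_frames) / n_frames``.
    ``ar1`` adds AR(1) frame-to-frame correlation through a Gaussian
    copula, which preserves the marginals (0 = independent frames, the
    default under which the recovery statistics are stated).
    """

    chain_length: int = 16
    n_frames: int = 5000
    seed: int = 0
    d2_mean: float = 5.1
    d2_sd: float = 0.5
    d2_bounds: tuple[float, float] = (3.0, 12.0)
    abd_mean: float = 105.0
    abd_sd: float = 35.0
    abd_bounds: tuple[float, float] = (30.0, 170.0)
    d1_mean: float = -2.1
    d1_sd: float = 0.3
    hbond_occupancies: dict[str, float] = field(
        default_factory=lambda: {
            "SER143": 0.30, "LYS135": 0.85, "HIS140": 0.80, "HIS141": 0.75,
        }
    )
    hbond_deterministic: bool = True
    pi_cation_occupancy: float = 0.95
    pi_cation_deterministic: bool = True
    ar1: float = 0.0
    bilayer_z_offset: float = 0.0
    mutant_ser156: bool = False
    stride_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.chain_length % 2 or not 12 <= self.chain_length <= 20:
            raise ValueError("chain_length must be an even number in 12..20")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.d2_bounds[0] <= 2.0:
            raise ValueError("d2 lower bound must exceed the 2 Å steric limit")
        if not (0 < self.abd_bounds[0] < self.abd_bounds[1] < 180):
            raise ValueError("abd bounds must lie inside (0, 180) degrees")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")
        for k, v in self.hbond_occupancies.items():
            if not 0 <= v <= 1:
                raise ValueError(f"occupancy for {k} must lie in [0, 1]")
        if not 0 <= self.pi_cation_occupancy <= 1:
            raise ValueError("pi_cation_occupancy must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"C{self.chain_length}"

    def prescribed_reactive_probability(
        self, d2_max: float = 6.0, abd_min: float = 90.0
    ) -> float:
        """P(D2 < d2_max) · P(αBD > abd_min) under the spec's marginals.

        Frames are sampled independently (for ar1 = 0), so the reactive
        probability factorises over the two truncated normals.
        """
        p_d2 = _truncnorm(self.d2_mean, self.d2_sd, self.d2_bounds).cdf(d2_max)
        p_abd = _truncnorm(self.abd_mean, self.abd_sd, self.abd_bounds).sf(abd_min)
        return float(p_d2 * p_abd)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["d2_bounds"] = list(self.d2_bounds)
        d["abd_bounds"] = list(self.abd_bounds)
        return d


@dataclass
class SyntheticGroundTruth:
    """Exact per-frame ledger of everything the generator realised."""

    table: pd.DataFrame  # d1, d2, abd, reactive, improper, hb_*, pi_cation
    prescribed_reactive_probability: float
    spec: SyntheticSpec
    n_resampled: int = 0

    @property
    def realized_reactive_fraction(self) -> float:
        return float(self.table["reactive"].mean())

    @property
    def realized_improper_fraction(self) -> float:
        return float(self.table["improper"].mean())


def _truncnorm(mean: float, sd: float, bounds: tuple[float, float]):
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def _atom(serial: int, name: str, resname: str, resid: int, chain: str,
          element: str | None = None) -> AtomRecord:
    el = element or guess_element(name, resname)
    return AtomRecord(
        serial=serial, name=name, element=el, residue_name=resname,
        residue_number=resid, chain_id=chain, mass=mass_of(el),
    )


def _helix_points(phi_deg: float, n: int = 25) -> np.ndarray:
    """Cα line of one teepee helix: wide at the cytosolic base, narrow on top."""
    t = np.linspace(0.0, 1.0, n)
    z = -16.0 + (_CEILING_Z + 16.0) * t
    r = 13.0 - 7.5 * t
    phi = np.radians(phi_deg)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # mild helical wobble so the cloud is not four perfect lines
    wob = 1.0
    pts[:, 0] += wob * np.cos(2 * np.pi * 3.3 * t + phi)
    pts[:, 1] += wob * np.sin(2 * np.pi * 3.3 * t + phi)
    return pts


# Static side-group geometry of the cytosolic CoA-binding site. Each donor
# has a fixed unit direction along which its hydrogen (at covalent bond
# length) and, per frame, the paired acceptor oxygen are placed.
_HBOND_SITES = {
    # donor residue -> (resname, donor atom, hydrogen, CA pos, donor pos,
    #                   direction, acceptor atom name)
    "SER143": ("SER", "OG", "HG", (-5.0, -3.0, -18.3), (-6.3, -4.3, -19.2),
               (-0.46, -0.46, -0.76), "O1P"),
    "LYS135": ("LYS", "NZ", "HZ1", (-8.0, 5.0, -19.0), (-7.0, 5.8, -19.6),
               (0.30, -0.80, -0.52), "O2P"),
    "HIS140": ("HIS", "NE2", "HE2", (-9.5, 1.0, -18.5), (-8.6, 0.4, -19.0),
               (0.60, 0.00, -0.80), "O3P"),
    "HIS141": ("HIS", "ND1", "HD1", (-7.5, -0.8, -17.5), (-6.8, -1.5, -18.1),
               (0.50, -0.50, -0.707), "O4P"),
}

_ADENINE_CENTER = np.array([8.0, -6.0, -21.0])
_ADENINE_NORMAL = np.array([0.0, 0.0, 1.0])
_ARG_CZ_STACKED = _ADENINE_CENTER + 4.0 * _ADENINE_NORMAL
_ARG_CZ_APART = _ADENINE_CENTER + np.array([8.0, 0.0, 0.0])
_ARG_OFFSETS = {"NE": (-1.33, 0.0, 0.2), "NH1": (0.6, 1.2, 0.0),
                "NH2": (0.6, -1.2, 0.0)}


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def build_topology(spec: SyntheticSpec) -> tuple[list[AtomRecord], np.ndarray]:
    """Deterministic pseudo-enzyme topology and its reference frame (Å).

    Chain A holds the protein, chain L the ligand (residue 1 the acyl
    chain ``C1..C{n}`` with the thioester carbonyl ``C1``/``O1``, residue 2
    a pyrophosphate-like group, residue 3 an adenine-like ring), chain M
    the pseudo-lipid phosphorus slab. The ceiling triad's heavy atoms all
    sit at Z = +8.1 Å so its COM is exact by construction, and it lies
    above the catalytic site, as the teepee topology requires.
    """
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name, resname, resid, chain, xyz, element=None):
        atoms.append(_atom(len(atoms) + 1, name, resname, resid, chain, element))
        coords.append(np.asarray(xyz, dtype=float))

    # --- protein, ascending author residue numbers ---------------------
    # ceiling triad residue 29
    add("CA", "SER", 29, "A", (3.4, 0.9, _CEILING_Z))
    add("CB", "SER", 29, "A", (2.4, 0.4, _CEILING_Z))
    add("OG", "SER", 29, "A", (1.6, -0.3, _CEILING_Z))
    # helix 1 (residues 40-64, base->top) and helix 2 (70-94, top->base)
    h1, h2 = _helix_points(45.0), _helix_points(135.0)
    for k, p in enumerate(h1):
        add("CA", "ALA", 40 + k, "A", p)
    for k, p in enumerate(h2[::-1]):
        add("CA", "ALA", 70 + k, "A", p)
    # cytosolic CoA-binding residues
    for resid_key in ("LYS135", "HIS140", "HIS141", "SER143"):
        resname, dname, hname, ca, dpos, ddir, _acc = _HBOND_SITES[resid_key]
        resid = int(resid_key[3:])
        add("CA", resname, resid, "A", ca)
        add(dname, resname, resid, "A", dpos)
        hpos = np.asarray(dpos) + 0.98 * _normalize(ddir)
        add(hname, resname, resid, "A", hpos, element="H")
    # catalytic residue 156: CYS (wild type) or SER (trapped mutant)
    if spec.mutant_ser156:
        add("CA", "SER", 156, "A", (4.0, 0.5, -11.5))
        add("CB", "SER", 156, "A", (3.0, 0.9, -11.0))
        add("OG", "SER", 156, "A", (2.0, 0.0, -11.0))
    else:
        add("CA", "CYS", 156, "A", (4.0, 0.5, -11.5))
        add("CB", "CYS", 156, "A", (3.0, 0.9, -11.0))
        add("SG", "CYS", 156, "A", (2.0, 0.0, -11.0))
    # Trp158 gate at the cavity entrance
    add("CA", "TRP", 158, "A", (5.0, 3.0, -13.5))
    add("CB", "TRP", 158, "A", (3.5, 2.5, -13.0))
    # helix 3 (160-184) and triad residue 185
    for k, p in enumerate(_helix_points(225.0)):
        add("CA", "ALA", 160 + k, "A", p)
    add("CA", "VAL", 185, "A", (-2.2, 2.9, _CEILING_Z))
    add("CB", "VAL", 185, "A", (-1.4, 1.9, _CEILING_Z))
    add("CG1", "VAL", 185, "A", (-2.0, 0.9, _CEILING_Z))
    add("CG2", "VAL", 185, "A", (-0.6, 1.3, _CEILING_Z))
    # helix 4 (190-214, top->base) and triad residue 217
    for k, p in enumerate(_helix_points(315.0)[::-1]):
        add("CA", "ALA", 190 + k, "A", p)
    add("CA", "SER", 217, "A", (-0.9, -3.3, _CEILING_Z))
    add("CB", "SER", 217, "A", (-0.7, -2.2, _CEILING_Z))
    add("OG", "SER", 217, "A", (-1.2, -1.2, _CEILING_Z))
    # Arg246 guanidinium over the adenine ring (reference: stacked)
    add("CA", "ARG", 246, "A", (11.0, -7.0, -22.0))
    for nm, off in (("NE", _ARG_OFFSETS["NE"]), ("CZ", (0, 0, 0)),
                    ("NH1", _ARG_OFFSETS["NH1"]), ("NH2", _ARG_OFFSETS["NH2"])):
        add(nm, "ARG", 246, "A", _ARG_CZ_STACKED + np.asarray(off, float))

    # --- ligand ---------------------------------------------------------
    ceiling_com_z = _CEILING_Z  # exact: all triad atoms share this Z
    chain_xyz = _acyl_chain(spec.chain_length, ceiling_com_z + spec.d1_mean)
    add("C1", "ACL", 1, "L", chain_xyz[0])
    add("O1", "ACL", 1, "L", chain_xyz[0] + _carbonyl_o_offset())
    for k in range(2, spec.chain_length + 1):
        add(f"C{k}", "ACL", 1, "L", chain_xyz[k - 1])
    # pyrophosphate-like group: P atoms static, acceptor O's toggled per frame
    add("PA", "PPS", 2, "L", (-7.5, -5.5, -20.5))
    add("PB", "PPS", 2, "L", (-9.0, -5.0, -21.0))
    for key in ("SER143", "LYS135", "HIS140", "HIS141"):
        _resname, _d, _h, _ca, dpos, ddir, acc = _HBOND_SITES[key]
        add(acc, "PPS", 2, "L", np.asarray(dpos) + 2.8 * _normalize(ddir))
    # adenine-like six-membered ring (CoA atom naming)
    ring_names = ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A"]
    for k, nm in enumerate(ring_names):
        ang = np.radians(60.0 * k)
        pos = _ADENINE_CENTER + 1.39 * np.array([np.cos(ang), np.sin(ang), 0.0])
        add(nm, "ADN", 3, "L", pos)

    # --- pseudo-lipid bilayer slab --------------------------------------
    resid = 1
    grid = np.arange(-28.0, 28.1, 8.0)
    for leaflet in (+1, -1):
        for x in grid:
            for y in grid:
                if x * x + y * y < 13.0 ** 2:
                    continue  # the protein occupies the center
                z = spec.bilayer_z_offset + leaflet * _LEAFLET_Z
                add("P", "POPC", resid, "M", (x, y, z))
                resid += 1

    return atoms, np.vstack(coords)


def _acyl_chain(n_carbons: int, terminal_z: float) -> np.ndarray:
    """Ideal all-anti zig-zag chain (1.53 Å bonds, tetrahedral angles).

    The chain hangs down the cavity axis from the terminal carbon C{n} at
    (0, 0, terminal_z); index 0 of the result is the thioester carbonyl
    carbon C1 at the bottom.
    """
    xyz = np.zeros((n_carbons, 3))
    for k in range(1, n_carbons + 1):
        steps = n_carbons - k
        xyz[k - 1] = (_ZIG_X * (steps % 2), 0.0, terminal_z - _ZIG_RISE * steps)
    return xyz


def _carbonyl_o_offset() -> np.ndarray:
    """Fixed C1→O1 unit direction times the C=O bond length (along +x)."""
    return _CO_BOND * np.array([1.0, 0.0, 0.0])


def _nucleophile_position(c1: np.ndarray, d2: float, abd_deg: float) -> np.ndarray:
    """Place the nucleophile so |Nu−C1| = d2 and ∠(Nu, C1, O1) = αBD exactly.

    The C1→O1 direction is +x and the attack plane is x–z, so
    Nu = C1 + d2·(cos α · x̂ + sin α · ẑ).
    """
    a = np.radians(abd_deg)
    return c1 + d2 * np.array([np.cos(a), 0.0, np.sin(a)])


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def _sample_truncnorm(rng: np.random.Generator, dist, n: int, ar1: float) -> np.ndarray:
    """Truncated-normal draws, optionally AR(1)-correlated via a Gaussian copula."""
    z = rng.standard_normal(n)
    if ar1 > 0:
        for t in range(1, n):
            z[t] = ar1 * z[t - 1] + np.sqrt(1.0 - ar1 ** 2) * z[t]
    u = special.ndtr(z)
    return dist.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))


def _toggle(rng: np.random.Generator, occupancy: float, n: int,
            deterministic: bool) -> np.ndarray:
    if deterministic:
        k = int(round(occupancy * n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        return flags
    return rng.random(n) < occupancy


def generate_trajectory(
    spec: SyntheticSpec,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Sample per-frame observables, realise them in coordinates, ledger them.

    The nucleophile atom (Sγ of Cys156, or the Ser156 hydroxyl O for the
    mutant) and the thioester carbonyl group are placed each frame so the
    sampled (D2, αBD) are realised to machine precision; the acyl chain is
    translated along Z so the sampled D1 is exact. H-bond acceptor oxygens
    and the Arg246 guanidinium toggle between bound and unbound geometries
    according to their occupancies.
    """
    topology, ref = build_topology(spec)
    n = spec.n_frames
    rng = np.random.default_rng(spec.seed)

    d2 = _sample_truncnorm(rng, _truncnorm(spec.d2_mean, spec.d2_sd, spec.d2_bounds),
                           n, spec.ar1)
    abd = _sample_truncnorm(rng, _truncnorm(spec.abd_mean, spec.abd_sd, spec.abd_bounds),
                            n, spec.ar1)
    d1 = spec.d1_mean + spec.d1_sd * rng.standard_normal(n)

    name_index = {(a.chain_id, a.residue_number, a.name): i
                  for i, a in enumerate(topology)}
    lig = {a.name: i for i, a in enumerate(topology)
           if a.chain_id == "L" and a.residue_number == 1}
    nu_name = "OG" if spec.mutant_ser156 else "SG"
    i_nu = name_index[("A", 156, nu_name)]
    i_c1, i_o1 = lig["C1"], lig["O1"]
    chain_idx = [lig[f"C{k}"] for k in range(1, spec.chain_length + 1)]

    coords = np.broadcast_to(ref, (n,) + ref.shape).copy()

    # acyl chain: translate the ideal zig-zag so C{n} realises each d1
    for k, idx in enumerate(chain_idx):
        steps = spec.chain_length - 1 - k
        coords[:, idx, 0] = _ZIG_X * (steps % 2)
        coords[:, idx, 1] = 0.0
        coords[:, idx, 2] = _CEILING_Z + d1 - _ZIG_RISE * steps
    # carbonyl O rides on C1; nucleophile placed from sampled (d2, abd)
    coords[:, i_o1, :] = coords[:, i_c1, :] + _carbonyl_o_offset()
    a_rad = np.radians(abd)
    coords[:, i_nu, 0] = coords[:, i_c1, 0] + d2 * np.cos(a_rad)
    coords[:, i_nu, 1] = coords[:, i_c1, 1]
    coords[:, i_nu, 2] = coords[:, i_c1, 2] + d2 * np.sin(a_rad)

    ledger: dict[str, np.ndarray] = {"d1": d1, "d2": d2, "abd": abd}
    reactive = (d2 < 6.0) & (abd > 90.0)
    improper = (d2 < 6.0) & (abd < 90.0)
    ledger["reactive"] = reactive
    ledger["improper"] = improper

    # hydrogen bonds: acceptor oxygen near/far along the donor direction
    for key, occ in spec.hbond_occupancies.items():
        if key not in _HBOND_SITES:
            raise ValueError(f"unknown h-bond site {key!r}")
        _resname, _d, _h, _ca, dpos, ddir, acc = _HBOND_SITES[key]
        i_acc = name_index[("L", 2, acc)]
        flags = _toggle(rng, occ, n, spec.hbond_deterministic)
        direction = _normalize(ddir)
        near = np.asarray(dpos) + 2.8 * direction
        far = np.asarray(dpos) + 6.5 * direction
        coords[:, i_acc, :] = np.where(flags[:, None], near, far)
        ledger[f"hb_{key}"] = flags

    # pi-cation: Arg246 guanidinium stacked over / pulled off the ring
    flags = _toggle(rng, spec.pi_cation_occupancy, n, spec.pi_cation_deterministic)
    for nm in ("NE", "CZ", "NH1", "NH2"):
        i_at = name_index[("A", 246, nm)]
        off = np.asarray(_ARG_OFFSETS.get(nm, (0.0, 0.0, 0.0)))
        coords[:, i_at, :] = np.where(
            flags[:, None], _ARG_CZ_STACKED + off, _ARG_CZ_APART + off
        )
    ledger["pi_cation"] = flags

    traj = Trajectory(
        topology=topology,
        coordinates=coords,
        boxes=np.tile(np.array(_BOX), (n, 1)),
        stride=spec.stride_ps,
    )
    truth = SyntheticGroundTruth(
        table=pd.DataFrame(ledger),
        prescribed_reactive_probability=spec.prescribed_reactive_probability(),
        spec=spec,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Benchmark suite and crystal-pose reference
# ---------------------------------------------------------------------------

def _solve_d2_mean(target_p_d2: float, sd: float,
                   bounds: tuple[float, float]) -> float:
    """D2 truncated-normal mean whose P(D2 < 6 Å) equals ``target_p_d2``."""
    if not 0 < target_p_d2 < 1:
        raise ValueError("target P(D2<6) must lie strictly inside (0, 1)")

    def gap(mean: float) -> float:
        return _truncnorm(mean, sd, bounds).cdf(6.0) - target_p_d2

    return float(optimize.brentq(gap, bounds[0] + 0.05, bounds[1] - 0.05, xtol=1e-10))


def make_benchmark_suite(
    seed: int,
    n_frames: int = 5000,
    probabilities: dict[str, float] | None = None,
) -> dict[str, tuple[Trajectory, SyntheticGroundTruth]]:
    """Five systems (C12…C20) with prescribed reactive probabilities.

    The αBD distribution is shared; each chain length's D2 mean is solved
    so that P(D2 < 6)·P(αBD > 90) equals its prescription exactly, making
    the C16 system the most reactive — the enzyme's selectivity optimum.
    """
    probabilities = probabilities or BENCHMARK_REACTIVE_PROBABILITIES
    base = SyntheticSpec()
    p_abd = _truncnorm(base.abd_mean, base.abd_sd, base.abd_bounds).sf(90.0)
    suite: dict[str, tuple[Trajectory, SyntheticGroundTruth]] = {}
    for k, (label, p) in enumerate(sorted(probabilities.items())):
        chain_length = int(label.lstrip("C"))
        d1_mean, d1_sd = BENCHMARK_D1.get(label, (-2.1, 0.5))
        spec = SyntheticSpec(
            chain_length=chain_length,
            n_frames=n_frames,
            seed=(seed * 1009 + 7 * k) % (2 ** 31),
            d2_mean=_solve_d2_mean(p / p_abd, base.d2_sd, base.d2_bounds),
            d1_mean=d1_mean,
            d1_sd=d1_sd,
        )
        suite[label] = generate_trajectory(spec)
    return suite


def make_crystal_reference(
    seed: int | None = None,
) -> tuple[Trajectory, dict]:
    """Single-frame mutant (Ser156) complex in the crystal pose.

    The geometry encodes the trapped-complex reference values
    (D1 = −4.07 Å, D2 = 6.6 Å, αBD = 127°) exactly; when ``seed`` is given
    the whole structure is additionally subjected to a random rigid
    rotation + translation, so recovering the values requires the
    principal-axis orientation step. Returns the trajectory and a dict of
    recommended selections (including the TM Cα set).
    """
    spec = SyntheticSpec(chain_length=16, n_frames=1, seed=0,
                         d2_mean=CRYSTAL_D2, d2_sd=1.0,
                         abd_mean=CRYSTAL_ABD, abd_sd=1.0,
                         d1_mean=CRYSTAL_D1, d1_sd=1.0,
                         mutant_ser156=True)
    topology, ref = build_topology(spec)
    coords = ref.copy()

    name_index = {(a.chain_id, a.residue_number, a.name): i
                  for i, a in enumerate(topology)}
    chain_idx = [name_index[("L", 1, f"C{k}")] for k in range(1, 17)]
    for k, idx in enumerate(chain_idx):
        steps = 16 - 1 - k
        coords[idx] = (_ZIG_X * (steps % 2), 0.0,
                       _CEILING_Z + CRYSTAL_D1 - _ZIG_RISE * steps)
    i_c1 = name_index[("L", 1, "C1")]
    coords[name_index[("L", 1, "O1")]] = coords[i_c1] + _carbonyl_o_offset()
    coords[name_index[("A", 156, "OG")]] = _nucleophile_position(
        coords[i_c1], CRYSTAL_D2, CRYSTAL_ABD
    )
    # the crystal carries no bilayer
    keep = [i for i, a in enumerate(topology) if a.chain_id != "M"]
    topology = [dataclasses.replace(a, serial=j + 1)
                for j, a in enumerate(topology[i] for i in keep)]
    coords = coords[keep]

    if seed is not None:
        rng = np.random.default_rng(seed)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng)
        shift = rng.uniform(-20.0, 20.0, size=3)
        coords = rot.apply(coords) + shift

    traj = Trajectory(topology=topology, coordinates=coords[None],
                      boxes=np.array(_BOX))
    selections = {
        "tm_ca": "chainID A and name CA and resname ALA",
        "ceiling": "resid 29 185 217 and not element H",
        "nucleophile": "resid 156 and name OG",
        "carbonyl_c": "chainID L and resid 1 and name C1",
        "carbonyl_o": "chainID L and resid 1 and name O1",
        "terminal_c": "chainID L and resid 1 and name C16",
    }
    return traj, selections


def write_system(
    traj: Trajectory,
    truth: SyntheticGroundTruth,
    outdir: str | Path,
    label: str | None = None,
) -> dict[str, Path]:
    """Write a synthetic system: multi-model PDB, ledger CSV, spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    label = label or truth.spec.label
    paths = {
        "trajectory": outdir / f"{label}.pdb",
        "ledger": outdir / f"{label}_ground_truth.csv",
        "spec": outdir / f"{label}_spec.yaml",
    }
    write_trajectory(traj, paths["trajectory"])
    table = truth.table.copy()
    for col in table.columns:
        if table[col].dtype == bool:
            table[col] = table[col].astype(int)
    table.to_csv(paths["ledger"], index_label="frame", float_format="%.6f")
    meta = {
        "spec": truth.spec.to_dict(),
        "prescribed_reactive_probability":
            float(truth.prescribed_reactive_probability),
        "realized_reactive_fraction": float(truth.realized_reactive_fraction),
    }
    paths["spec"].write_text(yaml.safe_dump(meta, sort_keys=True))
    return paths
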