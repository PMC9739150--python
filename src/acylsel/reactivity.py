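"""Cavity fitness and nucleophilic-attack reactivity of acyl-CoA complexes.

The core geometric observables of the analysis:

* ``D1`` — ΔZ between the acyl tail's terminal carbon and the center of
  mass of the cavity "ceiling" (the Ser29/Val185/Ser217 triad in hDHHC20),
  both measured along the membrane normal. Negative D1 means the tail tip
  sits below the ceiling; D1 stays negative when the chain fits the cavity.
* ``D2`` — distance between the catalytic nucleophile (Cys156 Sγ, or the
  Ser156 hydroxyl O of the catalytically dead mutant) and the thioester
  carbonyl carbon of the acyl chain.
* ``αBD`` — the Bürgi–Dunitz angle of nucleophilic attack: the
  Nu···C(carbonyl)=O angle with its vertex at the carbonyl carbon. Ideal
  attack is near 107°; in enzymes it may relax toward 90° but remains
  obtuse.

A frame is *reactive* when D2 < 6 Å (van der Waals proximity of the
reaction centers) and αBD > 90°; it is *improper* when D2 < 6 Å but the
attack angle is acute. Comparing reactive fractions across acyl chain
lengths, normalised to 100%, gives the in-silico selectivity profile of the
enzyme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MembraneFrame, center_of_mass
from .traj_io import Trajectory

__all__ = [
    "ReactivityCriteria",
    "ReactivitySeries",
    "SummaryStats",
    "Density2D",
    "compute_d1",
    "compute_d2",
    "compute_abd",
    "classify_reactive",
    "summarize",
    "reactive_fraction",
    "selectivity_profile",
    "density2d",
]


@dataclass(frozen=True)
class ReactivityCriteria:
    """Reactive-state thresholds: D2 < ``d2_max`` and αBD > ``abd_min``.

    Both inequalities are strict; a frame exactly at a threshold is neither
    reactive nor improper.
    """

    d2_max: float = 6.0
    abd_min: float = 90.0

    def __post_init__(self) -> None:
        if not self.d2_max > 0:
            raise ValueError("d2_max must be positive")
        if not 0 < self.abd_min < 180:
            raise ValueError("abd_min must lie in (0, 180) degrees")


def _single_atom(traj: Trajectory, selection, what: str) -> int:
    idx = _indices(traj, selection)
    if idx.size != 1:
        raise ValueError(
            f"{what} selection must resolve to exactly 1 atom, got {idx.size}"
        )
    return int(idx[0])


def _indices(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, str):
        return traj.select(selection)
    return np.asarray(selection, dtype=int)


def compute_d1(
    traj: Trajectory,
    terminal_c_sel,
    ceiling_sel,
    frame: MembraneFrame | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame D1 (Å): Z(terminal C) − Z(ceiling heavy-atom COM).

    The ceiling COM uses all atoms of the ceiling selection (mass-weighted
    by default). D1 is a Z difference, so the membrane-frame origin cancels;
    the frame argument exists for symmetry with other observables and for
    explicitness about the axis convention.
    """
    tip = _single_atom(traj, terminal_c_sel, "terminal carbon")
    ceiling = _indices(traj, ceiling_sel)
    if ceiling.size == 0:
        raise ValueError("ceiling selection is empty")
    frame = frame or MembraneFrame()
    com = center_of_mass(
        traj.coordinates, ceiling, masses=traj.masses, mass_weighted=mass_weighted
    )
    return frame.z(traj.coordinates[:, tip, :]) - frame.z(com)


def compute_d2(traj: Trajectory, nucleophile_sel, carbonyl_c_sel) -> np.ndarray:
    """Per-frame D2 (Å): nucleophile ··· carbonyl-carbon distance."""
    nu = _single_atom(traj, nucleophile_sel, "nucleophile")
    cc = _single_atom(traj, carbonyl_c_sel, "carbonyl carbon")
    diff = traj.coordinates[:, nu, :] - traj.coordinates[:, cc, :]
    return np.linalg.norm(diff, axis=1)


def compute_abd(
    traj: Trajectory, nucleophile_sel, carbonyl_c_sel, carbonyl_o_sel
) -> np.ndarray:
    """Per-frame Bürgi–Dunitz angle (deg): Nu–C(=O)–O, vertex at carbonyl C."""
    nu = _single_atom(traj, nucleophile_sel, "nucleophile")
    cc = _single_atom(traj, carbonyl_c_sel, "carbonyl carbon")
    co = _single_atom(traj, carbonyl_o_sel, "carbonyl oxygen")
    v1 = traj.coordinates[:, nu, :] - traj.coordinates[:, cc, :]
    v2 = traj.coordinates[:, co, :] - traj.coordinates[:, cc, :]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("zero-length vector in Bürgi–Dunitz angle")
    cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def classify_reactive(
    d2: np.ndarray, abd: np.ndarray, criteria: ReactivityCriteria | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reactive / improper boolean series from D2 and αBD.

    ``reactive = (D2 < d2_max) & (αBD > abd_min)``;
    ``improper = (D2 < d2_max) & (αBD < abd_min)`` — close approach with an
    acute (wrong-side) attack angle. Inequalities are strict.
    """
    criteria = criteria or ReactivityCriteria()
    d2 = np.asarray(d2, dtype=float)
    abd = np.asarray(abd, dtype=float)
    if d2.shape != abd.shape:
        raise ValueError("d2 and abd series must have equal length")
    close = d2 < criteria.d2_max
    return close & (abd > criteria.abd_min), close & (abd < criteria.abd_min)


@dataclass
class ReactivitySeries:
    """Per-frame D1/D2/αBD with reactive-state flags."""

    d1: np.ndarray
    d2: np.ndarray
    abd: np.ndarray
    reactive: np.ndarray
    improper: np.ndarray
    criteria: ReactivityCriteria = field(default_factory=ReactivityCriteria)

    @classmethod
    def from_measurements(
        cls,
        d1: np.ndarray,
        d2: np.ndarray,
        abd: np.ndarray,
        criteria: ReactivityCriteria | None = None,
    ) -> "ReactivitySeries":
        criteria = criteria or ReactivityCriteria()
        reactive, improper = classify_reactive(d2, abd, criteria)
        return cls(
            d1=np.asarray(d1, float),
            d2=np.asarray(d2, float),
            abd=np.asarray(abd, float),
            reactive=reactive,
            improper=improper,
            criteria=criteria,
        )

    def __post_init__(self) -> None:
        n = len(self.d1)
        if not (len(self.d2) == len(self.abd) == len(self.reactive)
                == len(self.improper) == n):
            raise ValueError("all per-frame series must have equal length")
        if np.any(self.reactive & self.improper):
            raise ValueError("a frame cannot be both reactive and improper")

    @property
    def n_frames(self) -> int:
        return len(self.d1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d1_A": self.d1,
                "d2_A": self.d2,
                "abd_deg": self.abd,
                "reactive": self.reactive.astype(int),
                "improper": self.improper.astype(int),
            }
        )


@dataclass
class SummaryStats:
    """Trajectory-level summary, Table-style.

    D1 statistics are unconditional; D2 and αBD are averaged over frames
    with D2 below the proximity threshold (``conditional="d2"``, the
    default) or over reactive frames only (``conditional="reactive"``).
    Standard deviations are the sample (n−1) definition, recorded in
    ``sd_definition`` so downstream comparisons are unambiguous.
    """

    d1_mean: float
    d1_sd: float
    d2_mean: float
    d2_sd: float
    abd_mean: float
    abd_sd: float
    reactive_fraction: float
    improper_fraction: float
    n_frames: int
    n_conditional: int
    conditional: str = "d2"
    conditional_defined: bool = True
    sd_definition: str = "sample (n-1)"

    def to_dict(self) -> dict:
        return {
            "d1_mean_A": self.d1_mean,
            "d1_sd_A": self.d1_sd,
            "d2_mean_A": self.d2_mean,
            "d2_sd_A": self.d2_sd,
            "abd_mean_deg": self.abd_mean,
            "abd_sd_deg": self.abd_sd,
            "reactive_fraction": self.reactive_fraction,
            "improper_fraction": self.improper_fraction,
            "n_frames": self.n_frames,
            "n_conditional": self.n_conditional,
            "conditional": self.conditional,
            "conditional_defined": self.conditional_defined,
            "sd_definition": self.sd_definition,
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def summarize(
    series: ReactivitySeries,
    criteria: ReactivityCriteria | None = None,
    conditional: str = "d2",
) -> SummaryStats:
    """Summary statistics with conditional averaging of D2/αBD.

    ``conditional="d2"`` averages D2 and αBD over frames with D2 < d2_max;
    ``conditional="reactive"`` averages over reactive frames only. When no
    frame satisfies the condition the conditional fields are NaN and
    flagged undefined rather than zero.
    """
    if series.n_frames < 1:
        raise ValueError("summarize needs at least one frame")
    criteria = criteria or series.criteria
    if conditional == "d2":
        mask = series.d2 < criteria.d2_max
    elif conditional == "reactive":
        mask = series.reactive
    else:
        raise ValueError("conditional must be 'd2' or 'reactive'")

    d1_mean, d1_sd = _mean_sd(series.d1)
    d2_mean, d2_sd = _mean_sd(series.d2[mask])
    abd_mean, abd_sd = _mean_sd(series.abd[mask])
    return SummaryStats(
        d1_mean=d1_mean,
        d1_sd=d1_sd,
        d2_mean=d2_mean,
        d2_sd=d2_sd,
        abd_mean=abd_mean,
        abd_sd=abd_sd,
        reactive_fraction=reactive_fraction(series.reactive),
        improper_fraction=reactive_fraction(series.improper),
        n_frames=series.n_frames,
        n_conditional=int(mask.sum()),
        conditional=conditional,
        conditional_defined=bool(mask.any()),
    )


def reactive_fraction(flags: np.ndarray) -> float:
    """Fraction of true entries in a boolean per-frame series."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("reactive_fraction of an empty series")
    return float(flags.mean())


def selectivity_profile(
    reactive: dict[str, float], improper: dict[str, float] | None = None
) -> pd.DataFrame:
    """Normalised in-silico selectivity profile across chain lengths.

    Each chain length's reactive fraction is divided by the sum over all
    chain lengths and scaled to percent, so the profile sums to 100 and the
    bars are comparable across lengths. An all-zero input yields an
    all-zero profile with a warning.
    """
    labels = list(reactive)
    frac = np.array([reactive[k] for k in labels], dtype=float)
    if frac.size == 0:
        raise ValueError("selectivity_profile needs at least one chain length")
    if np.any(frac < 0):
        raise ValueError("reactive fractions must be non-negative")
    out = pd.DataFrame(index=pd.Index(labels, name="chain"))
    out["reactive_fraction"] = frac
    out["normalized_reactive_pct"] = _normalize_pct(frac)
    if improper is not None:
        imp = np.array([improper[k] for k in labels], dtype=float)
        if np.any(imp < 0):
            raise ValueError("improper fractions must be non-negative")
        out["improper_fraction"] = imp
        out["normalized_improper_pct"] = _normalize_pct(imp)
    return out


def _normalize_pct(fractions: np.ndarray) -> np.ndarray:
    total = fractions.sum()
    if total == 0:
        warnings.warn("all fractions are zero; normalised profile is all zero",
                      stacklevel=3)
        return np.zeros_like(fractions)
    return 100.0 * fractions / total


@dataclass
class Density2D:
    """2D histogram of (D2, αBD) with the high-density mode.

    The mode is the center of the maximal-count bin; ties are broken toward
    the lowest D2, then the lowest αBD.
    """

    d2_edges: np.ndarray
    abd_edges: np.ndarray
    counts: np.ndarray

    @property
    def mode(self) -> tuple[float, float]:
        best = self.counts.max()
        # iterate d2-major, abd-minor so the documented tie-break falls out
        for i in range(self.counts.shape[0]):
            for j in range(self.counts.shape[1]):
                if self.counts[i, j] == best:
                    return (
                        float(0.5 * (self.d2_edges[i] + self.d2_edges[i + 1])),
                        float(0.5 * (self.abd_edges[j] + self.abd_edges[j + 1])),
                    )
        raise AssertionError("unreachable")

    def to_frame(self) -> pd.DataFrame:
        d2c = 0.5 * (self.d2_edges[:-1] + self.d2_edges[1:])
        abdc = 0.5 * (self.abd_edges[:-1] + self.abd_edges[1:])
        return pd.DataFrame(self.counts, index=pd.Index(d2c, name="d2_A"),
                            columns=pd.Index(abdc, name="abd_deg"))


def density2d(
    d2: np.ndarray,
    abd: np.ndarray,
    d2_bin: float = 0.25,
    abd_bin: float = 5.0,
) -> Density2D:
    """2D histogram of the (D2, αBD) reaction coordinates.

    Replicate series may be concatenated before calling to obtain joined
    contours. Bin edges are anchored at multiples of the bin widths so the
    histogram is independent of sample order.
    """
    d2 = np.asarray(d2, dtype=float)
    abd = np.asarray(abd, dtype=float)
    if d2.size == 0:
        raise ValueError("density2d of an empty series")
    if d2.shape != abd.shape:
        raise ValueError("d2 and abd series must have equal length")
    if d2_bin <= 0 or abd_bin <= 0:
        raise ValueError("bin widths must be positive")

    d2_edges = _anchored_edges(d2, d2_bin)
    abd_edges = _anchored_edges(abd, abd_bin)
    counts, _, _ = np.histogram2d(d2, abd, bins=(d2_edges, abd_edges))
    return Density2D(d2_edges=d2_edges, abd_edges=abd_edges, counts=counts)


def _anchored_edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)
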