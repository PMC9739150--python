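"""End-to-end analysis orchestration.

Loads trajectories named in a run configuration, applies membrane framing,
computes the reactivity series, summary statistics, (D2, αBD) densities,
contact/H-bond/π-cation fingerprints and membrane-normal density profiles
per system, assembles the cross-system selectivity profile, and writes
everything as CSV plus a JSON manifest that echoes every threshold used —
so each number in the report traces to a config value or an input file.

Outputs are deterministic: identical inputs and config produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .density import density_profile, terminal_z_level
from .geometry import MembraneFrame, membrane_frame, orient_by_principal_axis
from .interactions import contact_map, filter_hbonds, find_hbonds, pi_cation
from .reactivity import (
    ReactivityCriteria,
    ReactivitySeries,
    compute_abd,
    compute_d1,
    compute_d2,
    density2d,
    selectivity_profile,
    summarize,
)
from .traj_io import Trajectory, read_structure, read_trajectory

__all__ = ["RunConfig", "SystemSpec", "run_analysis", "run_crystal_reference"]

#: Selections every run must resolve before analysis starts.
REQUIRED_SELECTIONS = (
    "ceiling", "nucleophile", "carbonyl_c", "carbonyl_o", "terminal_c",
    "ligand", "protein",
)

DEFAULT_SELECTIONS = {
    "ceiling": "chainID A and resid 29 185 217 and not element H",
    "nucleophile": "chainID A and resid 156 and name SG OG",
    # "auto" resolves to the highest-numbered carbon of the acyl residue
    "terminal_c": "auto",
    "carbonyl_c": "chainID L and resid 1 and name C1",
    "carbonyl_o": "chainID L and resid 1 and name O1",
    "ligand": "chainID L",
    "protein": "chainID A",
    "lipid_P": "resname POPC and name P",
    "hbond_donors": "chainID A and resid 135 140 141 143",
    "hbond_acceptors": "chainID L and resid 2",
    "pi_cation_cation": "chainID A and resid 246 and name CZ",
    "pi_cation_ring": "chainID L and resid 3",
}


@dataclass
class SystemSpec:
    """One trajectory to analyse: a label plus its file(s)."""

    label: str
    trajectory: str
    topology: str | None = None


@dataclass
class RunConfig:
    """Full configuration of an analysis run (one YAML file)."""

    systems: list[SystemSpec]
    selections: dict[str, str] = field(default_factory=dict)
    criteria: ReactivityCriteria = field(default_factory=ReactivityCriteria)
    contact_cutoff: float = 4.0
    hbond_d_max: float = 3.5
    hbond_angle_max: float = 30.0
    hbond_min_lifetime: float = 0.10
    pi_cation_d_max: float = 6.0
    pi_cation_tilt_max: float = 45.0
    density_bin_width: float = 1.0
    d2_bin: float = 0.25
    abd_bin: float = 5.0
    conditional: str = "d2"
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        self.selections = {**DEFAULT_SELECTIONS, **self.selections}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        systems = [SystemSpec(**s) for s in raw.pop("systems")]
        criteria = ReactivityCriteria(**raw.pop("criteria", {}))
        return cls(systems=systems, criteria=criteria, **raw)

    def thresholds(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "contact_cutoff", "hbond_d_max", "hbond_angle_max",
                "hbond_min_lifetime", "pi_cation_d_max", "pi_cation_tilt_max",
                "density_bin_width", "d2_bin", "abd_bin", "conditional", "seed",
            )
        }
        d["criteria"] = dataclasses.asdict(self.criteria)
        return d


def _terminal_selection(traj: Trajectory, selections: dict[str, str]) -> str:
    """The acyl tail's terminal carbon: the highest-numbered C{k} atom."""
    expr = selections.get("terminal_c", "auto")
    if expr != "auto":
        return expr
    lig = traj.select(selections.get("ligand", "chainID L") + " and resid 1")
    best_k, best_atom = -1, None
    for i in lig:
        a = traj.topology[i]
        if a.element == "C" and a.name[0] == "C" and a.name[1:].isdigit():
            k = int(a.name[1:])
            if k > best_k:
                best_k, best_atom = k, a
    if best_atom is None:
        raise ValueError("could not auto-detect the terminal acyl carbon")
    return (f"chainID {best_atom.chain_id} and resid {best_atom.residue_number} "
            f"and name {best_atom.name}")


def _fail_fast_selections(traj: Trajectory, selections: dict[str, str]) -> None:
    for name in REQUIRED_SELECTIONS:
        expr = selections.get(name)
        if expr is None:
            raise ValueError(f"missing required selection {name!r}")
        if name == "terminal_c" and expr == "auto":
            expr = _terminal_selection(traj, selections)
        if traj.select(expr).size == 0:
            raise ValueError(f"selection {name!r} = {expr!r} matches no atoms")


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.6f", lineterminator="\n", **kw)


def analyze_system(
    traj: Trajectory, config: RunConfig
) -> dict:
    """All per-system analyses on an in-memory trajectory."""
    sel = dict(config.selections)
    _fail_fast_selections(traj, sel)
    sel["terminal_c"] = _terminal_selection(traj, sel)

    lipid_idx = traj.select(sel.get("lipid_P", "resname POPC and name P"))
    mframe = (membrane_frame(traj.coordinates[0], lipid_idx)
              if lipid_idx.size else MembraneFrame())

    d1 = compute_d1(traj, sel["terminal_c"], sel["ceiling"], frame=mframe)
    d2 = compute_d2(traj, sel["nucleophile"], sel["carbonyl_c"])
    abd = compute_abd(traj, sel["nucleophile"], sel["carbonyl_c"], sel["carbonyl_o"])
    series = ReactivitySeries.from_measurements(d1, d2, abd, config.criteria)
    stats = summarize(series, config.criteria, conditional=config.conditional)
    dens2d = density2d(d2, abd, d2_bin=config.d2_bin, abd_bin=config.abd_bin)

    contacts = contact_map(traj, sel["ligand"], sel["protein"],
                           cutoff=config.contact_cutoff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hbonds = find_hbonds(traj, sel["hbond_donors"], sel["hbond_acceptors"],
                             d_max=config.hbond_d_max,
                             angle_max=config.hbond_angle_max)
    kept_hbonds = filter_hbonds(hbonds, config.hbond_min_lifetime)
    pc = pi_cation(traj, sel["pi_cation_cation"], sel["pi_cation_ring"],
                   d_max=config.pi_cation_d_max,
                   tilt_max=config.pi_cation_tilt_max)

    profile = None
    if lipid_idx.size and traj.boxes is not None:
        groups = {"acyl": sel["ligand"] + " and resid 1",
                  "lipid": sel.get("lipid_P", "resname POPC and name P")}
        profile = density_profile(traj, groups,
                                  bin_width=config.density_bin_width, frame=mframe)
    tip_mean, tip_sd = terminal_z_level(traj, sel["terminal_c"], frame=mframe)

    return {
        "series": series,
        "stats": stats,
        "density2d": dens2d,
        "contacts": contacts,
        "hbonds": hbonds,
        "hbonds_reported": kept_hbonds,
        "pi_cation": pc,
        "density_profile": profile,
        "terminal_z": (tip_mean, tip_sd),
        "membrane_frame": mframe,
    }


def run_analysis(
    config: RunConfig,
    trajectories: dict[str, Trajectory] | None = None,
) -> dict:
    """Run the full pipeline and write the report bundle.

    ``trajectories`` may supply in-memory systems keyed by label (e.g. the
    synthetic benchmark suite), bypassing file loading; otherwise each
    system's trajectory path is read. Per-system failures are isolated:
    the remaining systems still complete, and failures are recorded in the
    manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results: dict[str, dict] = {}
    failures: dict[str, str] = {}
    summary_rows = {}
    for system in config.systems:
        try:
            if trajectories is not None and system.label in trajectories:
                traj = trajectories[system.label]
            else:
                traj = read_trajectory(system.trajectory, topology=system.topology)
            res = analyze_system(traj, config)
        except Exception as exc:
            failures[system.label] = str(exc)
            continue
        results[system.label] = res

        sysdir = outdir / system.label
        _write_csv(res["series"].to_frame(), sysdir / "reactivity_series.csv",
                   index_label="frame")
        _write_csv(res["density2d"].to_frame(), sysdir / "density2d.csv")
        _write_csv(res["contacts"].table, sysdir / "contact_map.csv")
        hb = pd.DataFrame(
            [dataclasses.asdict(r) for r in res["hbonds"]],
            columns=["donor_residue", "donor_atom", "acceptor_residue",
                     "acceptor_atom", "lifetime", "donor_index",
                     "hydrogen_index", "acceptor_index"],
        )
        _write_csv(hb, sysdir / "hbonds.csv", index=False)
        pc = res["pi_cation"]
        _write_csv(pd.DataFrame([dataclasses.asdict(pc)]),
                   sysdir / "pi_cation.csv", index=False)
        if res["density_profile"] is not None:
            _write_csv(res["density_profile"].table, sysdir / "density_profile.csv")
        summary_rows[system.label] = res["stats"].to_dict()

    summary = pd.DataFrame.from_dict(summary_rows, orient="index")
    summary.index.name = "system"
    _write_csv(summary, outdir / "summary.csv")

    profile = None
    if results:
        profile = selectivity_profile(
            {k: r["stats"].reactive_fraction for k, r in results.items()},
            {k: r["stats"].improper_fraction for k, r in results.items()},
        )
        _write_csv(profile, outdir / "selectivity_profile.csv")

    manifest = {
        "package_version": __version__,
        "thresholds": config.thresholds(),
        "selections": dict(sorted(config.selections.items())),
        "systems": [dataclasses.asdict(s) for s in config.systems],
        "failures": failures,
        "n_systems_completed": len(results),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )

    return {
        "systems": results,
        "summary": summary,
        "selectivity_profile": profile,
        "failures": failures,
        "manifest": manifest,
    }


def run_crystal_reference(
    structure: str | Path | Trajectory,
    selections: dict[str, str] | None = None,
) -> dict[str, float]:
    """D1, D2 and αBD of a single (crystal) structure.

    The structure is oriented by the principal axis of its transmembrane
    Cα set (a crystal carries no bilayer to define the membrane normal),
    with the axis sign chosen so the cavity ceiling lies above the
    catalytic residue. The nucleophile defaults to the Ser156 hydroxyl O
    when residue 156 is a serine (the catalytically dead mutant trapped in
    crystals) and to the Cys156 Sγ otherwise.
    """
    sel = {**DEFAULT_SELECTIONS, **(selections or {})}
    if isinstance(structure, Trajectory):
        traj = structure
    else:
        topology, frame0 = read_structure(structure)
        traj = Trajectory(topology=topology, coordinates=frame0.coordinates[None],
                          boxes=None if frame0.box is None else frame0.box)

    nu_sel = sel["nucleophile"]
    names156 = {a.name for a in traj.topology if a.residue_number == 156}
    resnames156 = {a.residue_name for a in traj.topology if a.residue_number == 156}
    if "SER" in resnames156 and "OG" in names156:
        nu_sel = "resid 156 and name OG"
    elif "CYS" in resnames156 and "SG" in names156:
        nu_sel = "resid 156 and name SG"

    tm_sel = sel.get("tm_ca", "protein and name CA")
    tm_idx = traj.select(tm_sel)
    if tm_idx.size < 3:
        raise ValueError(f"TM Cα selection {tm_sel!r} matched {tm_idx.size} atoms")
    ceiling_idx = traj.select(sel["ceiling"])
    nu_idx = traj.select(nu_sel)
    if ceiling_idx.size == 0 or nu_idx.size != 1:
        raise ValueError("ceiling or nucleophile selection did not resolve")

    oriented = orient_by_principal_axis(
        traj.coordinates, tm_idx, upper_indices=ceiling_idx, lower_indices=nu_idx
    )
    otraj = Trajectory(topology=traj.topology, coordinates=oriented,
                       times=traj.times, boxes=traj.boxes, stride=traj.stride)

    terminal_sel = _terminal_selection(otraj, sel)
    d1 = compute_d1(otraj, terminal_sel, sel["ceiling"])
    d2 = compute_d2(otraj, nu_sel, sel["carbonyl_c"])
    abd = compute_abd(otraj, nu_sel, sel["carbonyl_c"], sel["carbonyl_o"])
    return {"d1": float(d1[0]), "d2": float(d2[0]), "abd": float(abd[0])}
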