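from __future__ import annotations

import numpy as np
import pytest

from _oracles import brute_contact_fractions
from acylsel.interactions import (
    contact_map,
    filter_hbonds,
    find_hbonds,
    HBondRecord,
    pi_cation,
)
from acylsel.synthetic import SyntheticSpec, generate_trajectory


def _hbond_record(lifetime):
    return HBondRecord(0, 1, 2, "A:SER143", "L:PPS2", "OG", "O1P", lifetime)


class TestContactMap:
    def test_cutoff_is_strict_at_4A(self, toy):
        coords = [[0, 0, 0.0], [3.9, 0, 0], [0, 4.1, 0]]
        traj = toy([coords], names=["C1", "CB", "CB"],
                   resnames=["LIG", "SER", "SER"], resids=[1, 29, 30],
                   chains=["L", "A", "A"])
        cm = contact_map(traj, [0], [1, 2])
        assert cm.table.loc["A:SER29", "C1"] == 1.0
        assert cm.table.loc["A:SER30", "C1"] == 0.0

    def test_two_frames_half_occupancy(self, toy):
        frames = [
            [[0, 0, 0.0], [3.0, 0, 0]],
            [[0, 0, 0.0], [6.0, 0, 0]],
        ]
        traj = toy(frames, names=["C1", "CB"], resnames=["LIG", "SER"],
                   resids=[1, 29], chains=["L", "A"])
        cm = contact_map(traj, [0], [1])
        assert cm.table.iloc[0, 0] == 0.5

    def test_hydrogens_are_ignored(self, toy):
        coords = [[0, 0, 0.0], [2.0, 0, 0]]
        traj = toy([coords], names=["C1", "HB1"], elements=["C", "H"],
                   resnames=["LIG", "SER"], resids=[1, 29], chains=["L", "A"])
        with pytest.raises(ValueError, match="non-empty heavy-atom"):
            contact_map(traj, [0], [1])

    def test_terminal_carbon_touches_only_ceiling_triad(self):
        # a frame with the tail tip at its mean depth below the ceiling
        spec = SyntheticSpec(n_frames=1, seed=2, d1_mean=-2.1, d1_sd=0.0)
        traj, _ = generate_trajectory(spec)
        cm = contact_map(traj, "chainID L and resid 1 and name C16", "chainID A")
        touched = {r.split(":")[1] for r in cm.nonzero_residues()}
        assert touched == {"SER29", "VAL185", "SER217"}

    def test_matches_bruteforce_all_pairs(self, small_system):
        traj, _ = small_system
        sub = traj.coordinates[:10]
        lig = traj.select("chainID L and resid 1 and not element H")
        prot = traj.select("chainID A and resid 29 185 217 156 158 and not element H")
        cm_traj = type(traj)(topology=traj.topology, coordinates=sub,
                             boxes=None)
        cm = contact_map(cm_traj, lig, prot, cutoff=4.0)
        labels = []
        residue_of = []
        for i in prot:
            lab = traj.topology[i].residue_label
            if not labels or labels[-1] != lab:
                labels.append(lab)
            residue_of.append(len(labels) - 1)
        brute = brute_contact_fractions(sub, lig, prot, residue_of, len(labels), 4.0)
        assert np.allclose(cm.table.values, brute)

    def test_growing_cutoff_is_monotone(self, small_system):
        traj, _ = small_system
        lig = "chainID L and resid 1"
        small = contact_map(traj, lig, "chainID A", cutoff=3.5).table.values
        large = contact_map(traj, lig, "chainID A", cutoff=4.5).table.values
        assert np.all(large >= small)


class TestHBonds:
    def _linear_hbond_traj(self, toy, da=2.8, frames=4, break_half=False):
        """O-H...O perfectly linear at distance `da`."""
        geoms = []
        for f in range(frames):
            stretch = 5.0 if (break_half and f >= frames // 2) else da
            geoms.append([
                [0.0, 0, 0],          # donor O
                [0.98, 0, 0],         # H
                [stretch, 0, 0],      # acceptor O
            ])
        return toy(geoms, names=["OG", "HG", "O1P"], elements=["O", "H", "O"],
                   resnames=["SER", "SER", "PPS"], resids=[143, 143, 2],
                   chains=["A", "A", "L"])

    def test_ideal_linear_bond_full_lifetime(self, toy):
        traj = self._linear_hbond_traj(toy)
        records = find_hbonds(traj, [0], [2])
        assert len(records) == 1
        assert records[0].lifetime == 1.0

    def test_broken_half_of_frames(self, toy):
        traj = self._linear_hbond_traj(toy, break_half=True)
        records = find_hbonds(traj, [0], [2])
        assert records[0].lifetime == 0.5

    def test_angle_criterion_rejects_bent_geometry(self, toy):
        # acceptor at 3 A but 60 degrees off the O-H direction
        coords = [[0.0, 0, 0], [0.98, 0, 0],
                  [3.0 * np.cos(np.radians(60)), 3.0 * np.sin(np.radians(60)), 0]]
        traj = toy([coords], names=["OG", "HG", "O1P"], elements=["O", "H", "O"],
                   resnames=["SER", "SER", "PPS"], resids=[143, 143, 2],
                   chains=["A", "A", "L"])
        assert find_hbonds(traj, [0], [2]) == []

    def test_donor_without_hydrogen_warns_and_skips(self, toy):
        coords = [[0.0, 0, 0], [2.8, 0, 0]]
        traj = toy([coords], names=["OG", "O1P"], elements=["O", "O"],
                   resnames=["SER", "PPS"], resids=[143, 2], chains=["A", "L"])
        with pytest.warns(UserWarning, match="no bonded hydrogen"):
            assert find_hbonds(traj, [0], [1]) == []

    def test_prescribed_occupancy_recovered_exactly(self):
        spec = SyntheticSpec(n_frames=100, seed=9, hbond_deterministic=True)
        traj, truth = generate_trajectory(spec)
        records = find_hbonds(traj, "chainID A and resid 143",
                              "chainID L and resid 2")
        ser = [r for r in records if r.donor_residue == "A:SER143"]
        assert len(ser) == 1
        assert ser[0].lifetime == pytest.approx(0.30, abs=1e-12)
        assert ser[0].lifetime == pytest.approx(truth.table.hb_SER143.mean())


class TestFilterHBonds:
    def test_strict_threshold(self):
        records = [_hbond_record(x) for x in (0.05, 0.10, 0.11)]
        kept = filter_hbonds(records)
        assert [r.lifetime for r in kept] == [0.11]

    def test_empty_input(self):
        assert filter_hbonds([]) == []

    def test_kept_if_passing_in_any_trajectory(self):
        # pooled records from two trajectories of the same bond
        pooled = [_hbond_record(0.05), _hbond_record(0.4)]
        kept = filter_hbonds(pooled)
        assert len(kept) == 1 and kept[0].lifetime == 0.4


class TestPiCation:
    def _ring_traj(self, toy, cation_xyz):
        ring = [[np.cos(np.radians(60 * k)) * 1.39,
                 np.sin(np.radians(60 * k)) * 1.39, 0.0] for k in range(6)]
        coords = ring + [list(cation_xyz)]
        names = ["N1A", "C2A", "N3A", "C4A", "C5A", "C6A", "CZ"]
        elements = ["N", "C", "N", "C", "C", "C", "C"]
        return toy([coords], names=names, elements=elements,
                   resnames=["ADN"] * 6 + ["ARG"], resids=[3] * 6 + [246],
                   chains=["L"] * 6 + ["A"])

    def test_stacked_cation_counts(self, toy):
        traj = self._ring_traj(toy, (0, 0, 4.0))
        assert pi_cation(traj, [6], list(range(6))).lifetime == 1.0

    def test_in_plane_cation_rejected_by_tilt(self, toy):
        traj = self._ring_traj(toy, (4.0, 0, 0.0))
        assert pi_cation(traj, [6], list(range(6))).lifetime == 0.0

    def test_degenerate_ring_errors(self, toy):
        coords = [[k * 1.0, 0, 0] for k in range(6)] + [[0, 0, 4.0]]
        traj = toy([coords], names=["N1A", "C2A", "N3A", "C4A", "C5A", "C6A", "CZ"],
                   elements=["N", "C", "N", "C", "C", "C", "C"])
        with pytest.raises(ValueError, match="collinear"):
            pi_cation(traj, [6], list(range(6)))

    def test_prescribed_occupancy_recovered_exactly(self):
        spec = SyntheticSpec(n_frames=100, seed=13, pi_cation_deterministic=True)
        traj, truth = generate_trajectory(spec)
        rec = pi_cation(traj, "chainID A and resid 246 and name CZ",
                        "chainID L and resid 3")
        assert rec.lifetime == pytest.approx(0.95, abs=1e-12)
        assert rec.lifetime == pytest.approx(truth.table.pi_cation.mean())

    def test_loosening_criteria_is_monotone(self, small_system):
        traj, _ = small_system
        tight = pi_cation(traj, "chainID A and resid 246 and name CZ",
                          "chainID L and resid 3", d_max=5.0, tilt_max=30.0)
        loose = pi_cation(traj, "chainID A and resid 246 and name CZ",
                          "chainID L and resid 3", d_max=7.0, tilt_max=60.0)
        assert loose.lifetime >= tight.lifetime
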