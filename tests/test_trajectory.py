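"""Ion contacts, salt bridges, RMSF, and hydrogen-bond counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from saltfold import (
    GeneratorSpec,
    RunEnsemble,
    backbone_rmsf,
    charged_group_atoms,
    count_hbonds,
    gen_toy_trajectory,
    ion_contact_stats,
    load_trajectory,
    salt_bridge_fractions,
    write_pdb,
)
from conftest import make_trajectory


class TestChargedGroups:
    def test_group_atom_sets(self):
        atoms = pd.DataFrame([
            {"name": "NZ", "resname": "LYS", "resid": 25, "chain": "A",
             "element": "N"},
            {"name": "CD", "resname": "GLU", "resid": 42, "chain": "A",
             "element": "C"},
            {"name": "OE1", "resname": "GLU", "resid": 42, "chain": "A",
             "element": "O"},
            {"name": "CA", "resname": "GLY", "resid": 50, "chain": "A",
             "element": "C"},
        ])
        groups = charged_group_atoms(atoms)
        assert groups[25] == {"NZ"}
        assert groups[42] == {"CD", "OE1", "OE2"}
        assert 50 not in groups  # glycine carries no charged group

    def test_unknown_residue_rejected(self):
        atoms = pd.DataFrame([{"name": "CA", "resname": "XYZ", "resid": 1,
                               "chain": "A", "element": "C"}])
        with pytest.raises(ValueError, match="unknown residue"):
            charged_group_atoms(atoms)


def two_frame_asp_ion(d1, d2):
    """Asp with one sodium at distance d1 (frame 1) and d2 (frame 2)."""
    rows = [("CG", "ASP", 9), ("OD1", "ASP", 9), ("OD2", "ASP", 9),
            ("NA", "NA", 900)]
    base = [[0, 0, 0], [1.1, 0, 0], [-0.6, 1.0, 0]]
    frames = [base + [[1.1 + d1, 0, 0]], base + [[1.1 + d2, 0, 0]]]
    return make_trajectory(rows, frames)


class TestIonContacts:
    def test_two_frame_half_occupancy(self):
        # ion 3.5 A from OD1 in frame 1, 8 A in frame 2
        ens = RunEnsemble(runs=[two_frame_asp_ion(3.5, 8.0)])
        stats = ion_contact_stats(ens, cutoff=4.0)
        assert stats.per_residue.loc[0, "fraction_mean"] == pytest.approx(0.5)
        assert stats.cations_per_frame == pytest.approx(0.5)

    def test_no_ions_gives_zero_everywhere(self):
        rows = [("CG", "ASP", 9), ("OD1", "ASP", 9), ("OD2", "ASP", 9)]
        base = [[0, 0, 0], [1.1, 0, 0], [-0.6, 1.0, 0]]
        ens = RunEnsemble(runs=[make_trajectory(rows, [base, base])])
        stats = ion_contact_stats(ens)
        assert (stats.per_residue["fraction_mean"] == 0).all()
        assert stats.cations_per_frame == 0.0
        assert stats.anions_per_frame == 0.0

    def test_nonpositive_cutoff_rejected(self):
        ens = RunEnsemble(runs=[two_frame_asp_ion(3.5, 8.0)])
        with pytest.raises(ValueError, match="cutoff"):
            ion_contact_stats(ens, cutoff=0.0)

    def test_occupancy_recovered_within_binomial_error(self):
        ens = gen_toy_trajectory(n_frames=2000, n_runs=1,
                                 spec=GeneratorSpec(seed=7))
        stats = ion_contact_stats(ens)
        from saltfold import ToyTrajectoryLayout

        targets = {(rn, rid): occ
                   for rn, rid, occ in ToyTrajectoryLayout().ion_sites}
        for row in stats.per_residue.itertuples():
            if (row.resname, row.resid) not in targets:
                continue  # salt-bridge partner residues carry no tagged ion
            occ = targets[(row.resname, row.resid)]
            se = np.sqrt(max(occ * (1 - occ), 1e-9) / 2000)
            assert abs(row.fraction_mean - occ) <= 3 * se + 1e-12

    def test_matches_brute_force_oracle_exactly(self):
        """Vectorised contact fractions equal a literal all-pairs loop."""
        ens = gen_toy_trajectory(n_frames=8, n_runs=2,
                                 spec=GeneratorSpec(seed=11))
        stats = ion_contact_stats(ens, cutoff=4.0)

        group_atoms = {"LYS": {"NZ"}, "ASP": {"CG", "OD1", "OD2"},
                       "GLU": {"CD", "OE1", "OE2"}}
        expected = {}
        for run in ens.runs:
            atoms = run.atoms.reset_index(drop=True)
            for (resid, resname), grp in atoms.groupby(["resid", "resname"]):
                rn = str(resname)
                if rn not in group_atoms:
                    continue
                gidx = [i for i in grp.index
                        if atoms.loc[i, "name"] in group_atoms[rn]]
                ion_name = "CL" if rn == "LYS" else "NA"
                iidx = [i for i in atoms.index
                        if atoms.loc[i, "resname"] == ion_name]
                hits = 0
                for f in range(run.n_frames):
                    found = False
                    for g in gidx:
                        for i in iidx:
                            d = np.sqrt(((run.coords[f, g] -
                                          run.coords[f, i]) ** 2).sum())
                            if d <= 4.0:
                                found = True
                    hits += found
                expected.setdefault((int(resid), rn), []).append(
                    hits / run.n_frames)
        for row in stats.per_residue.itertuples():
            mean = np.mean(expected[(row.resid, row.resname)])
            assert row.fraction_mean == pytest.approx(mean, abs=0)

    def test_invariant_to_rigid_motion(self):
        ens = gen_toy_trajectory(n_frames=20, n_runs=1,
                                 spec=GeneratorSpec(seed=13))
        ref = ion_contact_stats(ens).per_residue["fraction_mean"].to_numpy()
        rot = Rotation.from_euler("xyz", [31, -57, 12], degrees=True)
        moved = ens.runs[0]
        coords = rot.apply(
            moved.coords.reshape(-1, 3)).reshape(moved.coords.shape) + 52.0
        from saltfold import Trajectory

        ens2 = RunEnsemble(runs=[Trajectory(atoms=moved.atoms.copy(),
                                            coords=coords)])
        got = ion_contact_stats(ens2).per_residue["fraction_mean"].to_numpy()
        assert np.allclose(ref, got, atol=1e-9)


class TestSaltBridges:
    @staticmethod
    def bridge_traj(distance, n_frames=4):
        rows = [("NZ", "LYS", 25), ("CD", "GLU", 42),
                ("OE1", "GLU", 42), ("OE2", "GLU", 42)]
        frame = [[0, 0, 0], [distance, 0, 0],
                 [distance + 1.1, 0, 0], [distance - 0.6, 1.0, 0]]
        return make_trajectory(rows, [frame] * n_frames)

    def test_inside_cutoff_fully_formed(self):
        res = salt_bridge_fractions(
            RunEnsemble(runs=[self.bridge_traj(3.9)]), [(25, 42)])
        assert res[0].pair == "K25-E42"
        assert res[0].mean == pytest.approx(1.0)

    def test_just_outside_cutoff_never_formed(self):
        res = salt_bridge_fractions(
            RunEnsemble(runs=[self.bridge_traj(4.1)]), [(25, 42)])
        assert res[0].mean == pytest.approx(0.0)

    def test_cross_run_mean_and_sd(self):
        # three runs with per-run fractions 0.4 / 0.5 / 0.6 built from 10
        # frames each
        runs = []
        for formed in (4, 5, 6):
            rows = [("NZ", "LYS", 25), ("CD", "GLU", 42),
                    ("OE1", "GLU", 42), ("OE2", "GLU", 42)]
            frames = []
            for f in range(10):
                d = 3.5 if f < formed else 8.0
                frames.append([[0, 0, 0], [d, 0, 0],
                               [d + 1.1, 0, 0], [d - 0.6, 1.0, 0]])
            runs.append(make_trajectory(rows, frames))
        res = salt_bridge_fractions(RunEnsemble(runs=runs), [(25, 42)])[0]
        assert res.fractions == pytest.approx([0.4, 0.5, 0.6])
        assert res.mean == pytest.approx(0.5)
        assert res.sd == pytest.approx(0.1)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            salt_bridge_fractions(
                RunEnsemble(runs=[self.bridge_traj(3.9)]), [(25, 99)])


class TestRMSF:
    @staticmethod
    def backbone_rows(resid=1):
        return [("N", "ALA", resid), ("CA", "ALA", resid),
                ("C", "ALA", resid), ("O", "ALA", resid)]

    def test_identical_frames_have_zero_rmsf(self):
        frame = [[0, 0, 0], [1.5, 0, 0], [2.9, 0.5, 0], [3.5, 1.5, 0]]
        traj = make_trajectory(self.backbone_rows(), [frame] * 5)
        out = backbone_rmsf(RunEnsemble(runs=[traj]))
        assert out["rmsf_mean"].max() < 1e-9

    def test_rigid_translation_removed_by_superposition(self):
        frame = np.array([[0, 0, 0], [1.5, 0, 0], [2.9, 0.5, 0],
                          [3.5, 1.5, 0]], dtype=float)
        frames = [frame + shift for shift in ([0, 0, 0], [5, -2, 7], [1, 9, 3])]
        traj = make_trajectory(self.backbone_rows(), frames)
        out = backbone_rmsf(RunEnsemble(runs=[traj]))
        assert out["rmsf_mean"].max() < 1e-9

    def test_single_displaced_atom_gives_its_amplitude(self):
        """One atom oscillating +-d about the ensemble mean.

        Anchors sit at cube corners centred on the origin and the moving
        atom is its own residue at the exact centroid, so the optimal
        superposition is a pure translation of d/n and the expected RMSF
        values are exactly d(1-1/n) for the mover and d/n for anchors.
        """
        d = 0.4
        corners = [(sx * 3.0, sy * 3.0, sz * 3.0)
                   for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        rows = (self.backbone_rows(1) + self.backbone_rows(2)
                + [("N", "GLY", 3)])
        base = np.array(corners + [[0.0, 0.0, 0.0]])
        f1, f2 = base.copy(), base.copy()
        f1[8, 2] += d
        f2[8, 2] -= d
        traj = make_trajectory(rows, [f1, f2])
        out = backbone_rmsf(RunEnsemble(runs=[traj])).set_index("resid")
        n = 9
        assert out.loc[3, "rmsf_mean"] == pytest.approx(d * (1 - 1 / n),
                                                        rel=1e-9)
        assert out.loc[1, "rmsf_mean"] == pytest.approx(d / n, rel=1e-9)

    def test_single_frame_rejected(self):
        traj = make_trajectory(self.backbone_rows(),
                               [[[0, 0, 0], [1.5, 0, 0], [2.9, 0.5, 0],
                                 [3.5, 1.5, 0]]])
        with pytest.raises(ValueError, match="2 frames"):
            backbone_rmsf(RunEnsemble(runs=[traj]))

    def test_cross_run_sd_zero_for_identical_runs(self):
        ens = gen_toy_trajectory(n_frames=10, n_runs=1,
                                 spec=GeneratorSpec(seed=3))
        twin = RunEnsemble(runs=[ens.runs[0], ens.runs[0]])
        out = backbone_rmsf(twin)
        assert out["rmsf_sd"].max() < 1e-12


class TestHbonds:
    @staticmethod
    def nh_o_geometry(d_no, angle_deg):
        """Backbone N-H donor and a carbonyl O acceptor at the requested
        N...O distance and N-H...O angle."""
        # N at origin, H on +x at 1.0 A; place O so that angle(N-H-O)=angle
        ang = np.radians(180.0 - angle_deg)
        h = np.array([1.0, 0, 0])
        # distance H->O chosen so |N-O| = d_no
        # law of cosines in triangle N-H-O with NH = 1
        from math import cos, sqrt

        a = 1.0
        # solve |HO| from d_no^2 = a^2 + ho^2 - 2*a*ho*cos(pi - ang_NHO)
        c = cos(np.pi - ang)
        ho = a * c + sqrt(max((a * c) ** 2 + d_no**2 - a**2, 0.0))
        o = h + ho * np.array([np.cos(ang), np.sin(ang), 0.0])
        rows = [("N", "ALA", 1), ("H", "ALA", 1), ("CA", "ALA", 1),
                ("O", "GLY", 2), ("C", "GLY", 2), ("N", "GLY", 2),
                ("H", "GLY", 2)]
        frame = [[0, 0, 0], h.tolist(), [-1.2, -0.8, 0.0],
                 o.tolist(), (o + [0.0, 1.23, 0.0]).tolist(),
                 (o + [8.0, 0.0, 0.0]).tolist(),
                 (o + [9.0, 0.0, 0.0]).tolist()]
        return make_trajectory(rows, [frame, frame])

    def test_good_geometry_counts_one_bond(self):
        mean, sd = count_hbonds(
            RunEnsemble(runs=[self.nh_o_geometry(2.9, 170.0)]))
        assert mean == pytest.approx(1.0)
        assert sd == 0.0

    def test_long_distance_rejected(self):
        mean, _ = count_hbonds(
            RunEnsemble(runs=[self.nh_o_geometry(3.4, 170.0)]))
        assert mean == pytest.approx(0.0)

    def test_bent_angle_rejected(self):
        mean, _ = count_hbonds(
            RunEnsemble(runs=[self.nh_o_geometry(2.9, 100.0)]))
        assert mean == pytest.approx(0.0)

    def test_no_hydrogens_rejected(self):
        rows = [("N", "ALA", 1), ("CA", "ALA", 1), ("O", "ALA", 1)]
        frame = [[0, 0, 0], [1.5, 0, 0], [2.5, 0, 0]]
        with pytest.raises(ValueError, match="hydrogens"):
            count_hbonds(RunEnsemble(runs=[make_trajectory(rows,
                                                           [frame, frame])]))


class TestPdbRoundTrip:
    def test_multi_model_pdb_preserves_statistics(self, tmp_path):
        ens = gen_toy_trajectory(n_frames=6, n_runs=1,
                                 spec=GeneratorSpec(seed=21))
        path = tmp_path / "toy.pdb"
        write_pdb(ens.runs[0], path)
        text = path.read_text()
        assert "MODEL" in text and "ENDMDL" in text
        back = load_trajectory(path)
        assert back.n_frames == 6
        assert back.n_atoms == ens.runs[0].n_atoms
        a = ion_contact_stats(ens).per_residue
        b = ion_contact_stats(RunEnsemble(runs=[back])).per_residue
        merged = a.merge(b, on=["resid", "resname"], suffixes=("_a", "_b"))
        assert np.allclose(merged["fraction_mean_a"],
                           merged["fraction_mean_b"])
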