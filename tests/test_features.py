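"""Trajectory featurization: distances, hydrogen bonds, RMSF/RMSD,
bootstrap histograms."""

import mdtraj as md
import numpy as np
import pytest

from phrelay import features, synthetic as syn
from phrelay.features import HBondSpec

PDB_3ATOMS = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      10.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.000   3.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(PDB_3ATOMS)
    return p


def _traj_from_xyz(xyz, names=("N", "CA", "C")):
    top = md.Topology()
    chain = top.add_chain()
    res = top.add_residue("ALA", chain, resSeq=1)
    elements = {"N": md.element.nitrogen, "C": md.element.carbon,
                "O": md.element.oxygen, "H": md.element.hydrogen}
    for n in names:
        top.add_atom(n, elements.get(n[0], md.element.carbon), res)
    return md.Trajectory(np.asarray(xyz, dtype=np.float32), top)


class TestLoading:
    def test_single_frame_pdb_shape_and_units(self, tiny_pdb):
        """A 10 Angstrom PDB coordinate is stored as 1.0 nm."""
        traj = features.load_trajectory(tiny_pdb)
        assert traj.xyz.shape == (1, 3, 3)
        assert traj.xyz[0, 1, 0] == pytest.approx(1.0, abs=1e-6)

    def test_xtc_round_trip_within_format_precision(self, tiny_pdb, tmp_path):
        ref = features.load_trajectory(tiny_pdb)
        xyz = np.repeat(ref.xyz, 5, axis=0) + np.linspace(
            0, 0.1, 5)[:, None, None].astype(np.float32)
        traj = md.Trajectory(xyz, ref.topology)
        xtc = tmp_path / "t.xtc"
        traj.save_xtc(str(xtc))
        back = features.load_trajectory(tiny_pdb, xtc)
        assert np.abs(back.xyz - xyz).max() < 1e-3


class TestSuperpose:
    def test_identical_frame_zero_rmsd(self, tiny_pdb):
        traj = features.load_trajectory(tiny_pdb)
        two = md.join([traj, traj])
        fitted = features.superpose(two, selection="all")
        # single-precision coordinates bound the attainable zero
        assert md.rmsd(fitted, fitted, 0)[1] == pytest.approx(0.0, abs=1e-3)

    def test_rotated_frame_zero_rmsd_after_fit(self, rng):
        xyz0 = rng.normal(size=(10, 3)).astype(np.float32)
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        traj = _traj_from_xyz(np.stack([xyz0, xyz0 @ rot.T.astype(np.float32)]),
                              names=[f"C{i}" for i in range(1, 11)])
        fitted = features.superpose(traj, selection="all")
        assert md.rmsd(fitted, fitted, 0)[1] == pytest.approx(0.0, abs=1e-5)

    def test_fit_never_increases_rmsd(self, rng):
        frames = rng.normal(size=(6, 8, 3)).astype(np.float32)
        traj = _traj_from_xyz(frames, names=[f"C{i}" for i in range(1, 9)])
        before = np.sqrt(((frames - frames[0]) ** 2).sum(-1).mean(-1))
        fitted = features.superpose(traj, selection="all")
        after = md.rmsd(fitted, fitted, 0)
        assert (after <= before + 1e-6).all()

    def test_degenerate_selection_rejected(self, tiny_pdb):
        traj = features.load_trajectory(tiny_pdb)
        with pytest.raises(ValueError, match=">= 3"):
            features.superpose(traj, selection="name CA")


class TestDistances:
    def test_axis_pair(self):
        traj = _traj_from_xyz([[[0, 0, 0], [0, 0, 0.3], [1, 1, 1]]])
        ft = features.compute_distances(traj, {"d": ("name N", "name CA")})
        assert ft.values[0, 0] == pytest.approx(0.3, abs=1e-6)

    def test_group_min(self):
        traj = _traj_from_xyz([[[0, 0, 0], [0.4, 0, 0], [0.25, 0, 0]]])
        ft = features.compute_min_distances(
            traj, {"m": ("name N", "name CA or name C")})
        assert ft.values[0, 0] == pytest.approx(0.25, abs=1e-6)

    def test_matches_naive_loop(self, rng):
        xyz = rng.normal(size=(200, 4, 3)).astype(np.float32)
        traj = _traj_from_xyz(xyz, names=["C1", "C2", "C3", "C4"])
        ft = features.compute_distances(traj, {"d": ("name C1", "name C3")})
        naive = np.array([np.linalg.norm(f[0] - f[2]) for f in xyz])
        assert np.abs(ft.values[:, 0] - naive).max() < 1e-6

    def test_unresolvable_selector_named_in_error(self):
        traj = _traj_from_xyz([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        with pytest.raises(ValueError, match="name XX"):
            features.compute_distances(traj, {"d": ("name XX", "name CA")})


class TestHbonds:
    def _dha(self, d_on_axis, angle_deg=0.0, d_ha=0.1):
        """Donor at origin, H at 0.1 nm, acceptor at distance/angle."""
        a = np.radians(angle_deg)
        acc = [d_on_axis * np.cos(a), d_on_axis * np.sin(a), 0.0]
        return _traj_from_xyz([[[0, 0, 0], [d_ha, 0, 0], acc]],
                              names=["N", "H", "O"])

    def test_short_aligned_bond_present(self):
        traj = self._dha(0.25, 0.0)
        spec = HBondSpec("name N", "name H", "name O", "b")
        _, occ = features.detect_hbonds(traj, [spec])
        assert occ["b"] == 1.0

    def test_long_bond_absent(self):
        traj = self._dha(0.40, 0.0)
        spec = HBondSpec("name N", "name H", "name O", "b")
        _, occ = features.detect_hbonds(traj, [spec])
        assert occ["b"] == 0.0

    def test_angle_cut_enforced(self):
        traj = self._dha(0.30, 45.0)
        spec = HBondSpec("name N", "name H", "name O", "b")
        _, occ = features.detect_hbonds(traj, [spec])
        assert occ["b"] == 0.0
        _, occ_wide = features.detect_hbonds(traj, [spec], angle_cut=60.0)
        assert occ_wide["b"] == 1.0

    def test_missing_hydrogen_errors(self):
        traj = self._dha(0.25)
        spec = HBondSpec("name N", "name HX", "name O", "b")
        with pytest.raises(ValueError, match="hydrogen"):
            features.detect_hbonds(traj, [spec])

    def test_toy_trajectory_occupancy_recovered(self):
        """Detected occupancy of a planted 12.9%-style bond lies within
        the binomial CI of the scheduled value given the true labels."""
        schedule = {0: {"K257s-D308s": 0.654}, 1: {"K257s-D308s": 0.129}}
        traj, truth = syn.generate_hbond_toy_trajectory(schedule, 4000, seed=6)
        specs = syn.toy_hbond_specs(truth)
        feats, occ = features.detect_hbonds(traj, specs)
        labels = truth.values["labels"]
        col = feats.data["K257s-D308s"].to_numpy()
        for state, p in ((0, 0.654), (1, 0.129)):
            mask = labels == state
            n = mask.sum()
            assert abs(col[mask].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_occupancy_permutation_invariant(self):
        schedule = {0: {"b": 0.5}}
        traj, truth = syn.generate_hbond_toy_trajectory(schedule, 300, seed=1)
        specs = syn.toy_hbond_specs(truth)
        _, occ = features.detect_hbonds(traj, specs)
        shuffled = traj[np.random.default_rng(0).permutation(traj.n_frames)]
        _, occ2 = features.detect_hbonds(shuffled, specs)
        assert occ == occ2


class TestRmsfRmsd:
    def test_static_trajectory_zero_rmsf(self):
        xyz = np.tile(np.arange(9, dtype=np.float32).reshape(1, 3, 3), (5, 1, 1))
        traj = _traj_from_xyz(xyz, names=["CA", "CB", "CG"])
        table = features.rmsf(traj, selection="all")
        assert np.allclose(table["rmsf_nm"], 0.0)

    def test_oscillating_atom_closed_form(self):
        """An atom alternating +/- a along x with equal occupancy has RMSF a."""
        a = 0.2
        xyz = np.zeros((10, 1, 3), dtype=np.float32)
        xyz[::2, 0, 0] = a
        xyz[1::2, 0, 0] = -a
        traj = _traj_from_xyz(xyz, names=["CA"])
        table = features.rmsf(traj, selection="all")
        assert table["rmsf_nm"][0] == pytest.approx(a, rel=1e-6)

    def test_matches_two_pass_formula(self, rng):
        xyz = rng.normal(scale=0.1, size=(50, 3, 3)).astype(np.float32)
        traj = _traj_from_xyz(xyz, names=["CA", "CB", "CG"])
        table = features.rmsf(traj, selection="all")
        mean = xyz.mean(axis=0)
        naive = np.sqrt(((xyz - mean) ** 2).sum(-1).mean(0))
        assert np.abs(table["rmsf_nm"].to_numpy() - naive).max() < 1e-6

    def test_single_frame_rejected(self):
        traj = _traj_from_xyz([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        with pytest.raises(ValueError, match="single-frame"):
            features.rmsf(traj, "all")

    def test_rmsd_zero_for_reference_and_translation(self, rng):
        base = rng.normal(size=(8, 3)).astype(np.float32)
        xyz = np.stack([base, base + np.float32(1.0)])
        traj = _traj_from_xyz(xyz, names=[f"C{i}" for i in range(1, 9)])
        ft = features.rmsd_timeseries(traj, traj, selection="all")
        assert ft.values[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert ft.values[1, 0] == pytest.approx(0.0, abs=1e-5)

    def test_planted_jump_crossing_time(self):
        """A coordinate jump at frame t* pushes the fitted RMSD over
        0.2 nm at that frame."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3)).astype(np.float32)
        xyz = np.tile(base, (40, 1, 1))
        spread = base - base.mean(axis=0)
        xyz[25:] = (base.mean(axis=0) + 1.8 * spread).astype(np.float32)
        traj = _traj_from_xyz(xyz, names=[f"C{i}" for i in range(1, 7)])
        ft = features.rmsd_timeseries(traj, traj, selection="all")
        crossing = int(np.argmax(ft.values[:, 0] > 0.2))
        assert abs(crossing - 25) <= 1


class TestHistograms:
    def test_identical_replicas_zero_band(self, rng):
        s = rng.normal(size=500)
        h = features.histogram_with_bootstrap([s, s.copy(), s.copy()],
                                              bins=20, seed=0)
        assert np.allclose(h.ci_upper - h.ci_lower, 0.0)

    def test_mean_is_arithmetic_mean_and_band_brackets_it(self, rng):
        a, b = rng.normal(size=400), rng.normal(size=400) + 0.5
        h = features.histogram_with_bootstrap([a, b], bins=15, seed=1)
        edges = h.bin_edges
        da = np.histogram(a, bins=edges, density=True)[0]
        db = np.histogram(b, bins=edges, density=True)[0]
        assert np.allclose(h.mean_density, 0.5 * (da + db))
        assert (h.ci_lower <= h.mean_density + 1e-12).all()
        assert (h.ci_upper >= h.mean_density - 1e-12).all()

    def test_density_integrates_to_one(self, rng):
        h = features.histogram_with_bootstrap(
            [rng.normal(size=300) for _ in range(4)], bins=25, seed=2)
        widths = np.diff(h.bin_edges)
        assert (h.mean_density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_replica_flagged_no_ci(self, rng):
        h = features.histogram_with_bootstrap([rng.normal(size=100)], seed=0)
        assert not h.has_ci


class TestPopulationFraction:
    def test_all_below(self):
        assert features.population_fraction([np.array([0.1, 0.2])], 0.5) == 1.0

    def test_none_below(self):
        assert features.population_fraction([np.array([0.6, 0.7])], 0.5) == 0.0

    def test_planted_mixture_weight(self, rng):
        """Pooled fraction below the separatrix recovers a planted 13.2%
        short-distance population."""
        w = 0.132
        n = 20000
        short = rng.normal(0.2, 0.02, size=int(w * n))
        long = rng.normal(0.8, 0.05, size=n - len(short))
        pooled_frac = features.population_fraction(
            [short, long], threshold=0.5, side="below")
        assert abs(pooled_frac - w) < 3 * np.sqrt(w * (1 - w) / n)
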