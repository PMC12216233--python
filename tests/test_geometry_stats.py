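import numpy as np
import pytest

from gapspec.gap_io import GeometryTrajectory
from gapspec.geometry_stats import (
    InternalCoordinateSet,
    circular_mean_deg,
    dihedral_distribution,
    ensemble_deviation,
    ensemble_stats,
    internal_coordinates,
    rdf,
    read_internal_coordinates,
    wrap_angle_difference,
)
from gapspec.synthetic import (
    ChainAtom,
    generate_geometry_ensemble,
    generate_ideal_gas,
)


def _traj(coords, box=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return GeometryTrajectory(atom_names=[f"C{i+1}" for i in range(n)],
                              elements=["C"] * n, coords=coords, box=box)


UNIT_SQUARE = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]


class TestInternalCoordinates:
    def test_unit_square_reference_values(self):
        traj = _traj([UNIT_SQUARE])
        defs = InternalCoordinateSet(bonds=[(0, 1)], angles=[(0, 1, 2)],
                                     dihedrals=[(0, 1, 2, 3)])
        table = internal_coordinates(traj, defs)
        assert table.bonds.iloc[0, 0] == pytest.approx(1.0)
        assert table.angles.iloc[0, 0] == pytest.approx(90.0)
        assert table.dihedrals.iloc[0, 0] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("sign", [+1.0, -1.0])
    def test_staggered_torsion_sign_convention(self, sign):
        """+-60 degree gauche arrangements keep their handedness."""
        phi = np.radians(sign * 60.0)
        # build the fourth atom explicitly from the dihedral definition
        b2 = np.array([1.5, 0, 0])
        u = b2 / np.linalg.norm(b2)
        ref = np.array([0.0, 1.0, 0.0])  # direction of atom0 from atom1
        e1 = ref - (ref @ u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        theta = np.radians(109.5)
        d = (b2 + np.cos(np.pi - theta) * u * 1.1 +
             np.sin(np.pi - theta) * 1.1 *
             (np.cos(phi) * e1 + np.sin(phi) * e2))
        coords = [[0, 1, 0], [0, 0, 0], [1.5, 0, 0], d.tolist()]
        traj = _traj([coords])
        defs = InternalCoordinateSet(dihedrals=[(0, 1, 2, 3)])
        got = internal_coordinates(traj, defs).dihedrals.iloc[0, 0]
        assert got == pytest.approx(sign * 60.0, abs=1e-6)

    def test_identical_frames_zero_spread(self):
        traj = _traj([UNIT_SQUARE] * 7)
        defs = InternalCoordinateSet(bonds=[(0, 1), (1, 2)],
                                     angles=[(0, 1, 2)],
                                     dihedrals=[(0, 1, 2, 3)])
        stats = ensemble_stats(internal_coordinates(traj, defs))
        np.testing.assert_allclose(stats.table["spread"], 0.0, atol=1e-10)

    def test_collinear_atoms_flagged_nan(self):
        coords = [[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]]
        traj = _traj(coords)
        defs = InternalCoordinateSet(dihedrals=[(0, 1, 2, 3)])
        assert np.isnan(internal_coordinates(traj, defs).dihedrals.iloc[0, 0])

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-2, 2, size=(5, 6, 3))
        # random rotation via QR
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = base @ q.T + np.array([10.0, -3.0, 7.0])
        defs = InternalCoordinateSet(bonds=[(0, 1)], angles=[(1, 2, 3)],
                                     dihedrals=[(2, 3, 4, 5)])
        t1 = internal_coordinates(_traj(base), defs)
        t2 = internal_coordinates(_traj(moved), defs)
        np.testing.assert_allclose(t1.bonds, t2.bonds, atol=1e-9)
        np.testing.assert_allclose(t1.angles, t2.angles, atol=1e-9)
        np.testing.assert_allclose(t1.dihedrals, t2.dihedrals, atol=1e-9)

    def test_duplicate_definitions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            InternalCoordinateSet(bonds=[(0, 1), (0, 1)])

    def test_out_of_range_index_rejected(self):
        traj = _traj([UNIT_SQUARE])
        defs = InternalCoordinateSet(bonds=[(0, 9)])
        with pytest.raises(ValueError, match="atom 9"):
            internal_coordinates(traj, defs)

    def test_definition_file_parsing(self, tmp_path):
        p = tmp_path / "defs.txt"
        p.write_text("# 1-based indices\nbond 1 2 CC\nangle 1 2 3\n"
                     "dihedral 1 2 3 4 ring\n")
        defs = read_internal_coordinates(p)
        assert defs.bonds == [(0, 1)]
        assert defs.angles == [(0, 1, 2)]
        assert defs.dihedrals == [(0, 1, 2, 3)]
        assert defs.bond_labels == ["CC"]
        assert defs.dihedral_labels == ["ring"]


class TestCircularStatistics:
    def test_rotation_covariance(self):
        rng = np.random.default_rng(4)
        angles = rng.uniform(-180, 180, 500)
        base = circular_mean_deg(angles)
        for shift in (30.0, 170.0, -120.0):
            shifted = ((angles + shift + 180.0) % 360.0) - 180.0
            got = circular_mean_deg(shifted)
            assert wrap_angle_difference(got, base + shift) < 1e-8

    def test_seam_wraparound_difference(self):
        assert wrap_angle_difference(170.0, -170.0) == pytest.approx(20.0)

    def test_mean_near_seam_not_averaged_through_zero(self):
        angles = np.array([175.0, -175.0, 179.0, -179.0])
        mean = circular_mean_deg(angles)
        assert wrap_angle_difference(mean, 180.0) < 1.0


class TestEnsembleDeviation:
    def _stats_for(self, chain, n_frames, seed):
        traj = generate_geometry_ensemble(chain, n_frames, seed=seed)
        defs = InternalCoordinateSet(bonds=[(0, 1)])
        return ensemble_stats(internal_coordinates(traj, defs))

    def test_identical_ensembles_zero_deviation(self):
        chain = [ChainAtom(), ChainAtom(bond=(1.4, 0.02))]
        s = self._stats_for(chain, 100, seed=5)
        dev = ensemble_deviation(s, s)
        np.testing.assert_array_equal(dev["abs_deviation"], 0.0)

    def test_constructed_bond_offset_recovered(self):
        chain_a = [ChainAtom(), ChainAtom(bond=(1.40, 0.02))]
        chain_b = [ChainAtom(), ChainAtom(bond=(1.45, 0.02))]
        sa = self._stats_for(chain_a, 5000, seed=6)
        sb = self._stats_for(chain_b, 5000, seed=7)
        dev = ensemble_deviation(sa, sb)["abs_deviation"].iloc[0]
        assert dev == pytest.approx(0.05, abs=0.001)

    def test_dihedral_deviation_wraps_at_seam(self):
        import pandas as pd

        from gapspec.geometry_stats import EnsembleStats

        mk = lambda mean: EnsembleStats(
            table=pd.DataFrame({"kind": ["dihedral"], "label": ["d"],
                                "mean": [mean], "spread": [1.0]}),
            n_frames=10)
        dev = ensemble_deviation(mk(170.0), mk(-170.0))
        assert dev["abs_deviation"].iloc[0] == pytest.approx(20.0)

    def test_mismatched_sets_rejected(self):
        import pandas as pd

        from gapspec.geometry_stats import EnsembleStats

        a = EnsembleStats(table=pd.DataFrame(
            {"kind": ["bond"], "label": ["x"], "mean": [1.0],
             "spread": [0.1]}), n_frames=5)
        b = EnsembleStats(table=pd.DataFrame(
            {"kind": ["bond"], "label": ["y"], "mean": [1.0],
             "spread": [0.1]}), n_frames=5)
        with pytest.raises(ValueError, match="different coordinate"):
            ensemble_deviation(a, b)


class TestDihedralDistribution:
    CHAIN = [ChainAtom(), ChainAtom(bond=(1.5, 0.0)),
             ChainAtom(bond=(1.5, 0.0), angle=(109.5, 0.0))]

    def test_threefold_mixture_modes_recovered(self):
        chain = self.CHAIN + [ChainAtom(
            bond=(1.1, 0.0), angle=(109.5, 0.0),
            dihedral=[(-180.0, 80.0, 1.0), (-60.0, 80.0, 1.0),
                      (60.0, 80.0, 1.0)])]
        traj = generate_geometry_ensemble(chain, 3000, seed=8)
        edges, mass = dihedral_distribution(traj, (0, 1, 2, 3), bins=36)
        mids = 0.5 * (edges[:-1] + edges[1:])
        # local maxima of the histogram (periodic neighbourhood)
        peaks = [m for i, m in enumerate(mids)
                 if mass[i] >= mass[(i - 1) % 36] and
                 mass[i] >= mass[(i + 1) % 36] and
                 mass[i] > 2.0 / 36]
        assert len(peaks) == 3
        gaps = np.diff(sorted(peaks))
        np.testing.assert_allclose(gaps, 120.0, atol=15.0)

    def test_uniform_dihedrals_flat_histogram(self):
        chain = self.CHAIN + [ChainAtom(bond=(1.1, 0.0), angle=(109.5, 0.0),
                                        dihedral=[(0.0, 0.0, 1.0)])]
        traj = generate_geometry_ensemble(chain, 8000, seed=9)
        _, mass = dihedral_distribution(traj, (0, 1, 2, 3), bins=18)
        expected = 1.0 / 18
        # multinomial noise: sd ~ sqrt(p(1-p)/n) ~ 2.5e-3
        assert np.abs(mass - expected).max() < 5 * np.sqrt(
            expected * (1 - expected) / 8000)

    def test_single_frame_single_bin(self):
        chain = self.CHAIN + [ChainAtom(bond=(1.1, 0.0), angle=(109.5, 0.0),
                                        dihedral=[(60.0, np.inf, 1.0)])]
        traj = generate_geometry_ensemble(chain, 1, seed=10)
        _, mass = dihedral_distribution(traj, (0, 1, 2, 3), bins=36)
        assert np.count_nonzero(mass) == 1
        assert mass.sum() == pytest.approx(1.0)


class TestRdf:
    def test_ideal_gas_is_unity(self):
        traj = generate_ideal_gas(n_atoms=150, box=20.0, n_frames=40, seed=11)
        idx = np.arange(150)
        r, g = rdf(traj, idx, idx, r_max=9.0, n_bins=45)
        # skip the first few bins (tiny shell volumes, large noise)
        assert np.abs(g[5:] - 1.0).mean() < 0.05
        assert np.abs(g[5:] - 1.0).max() < 0.2

    def test_single_pair_closed_form_height(self):
        d = 3.0
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = d
        traj = _traj(coords)
        n_bins, r_max, vol = 20, 5.0, 1000.0
        r, g = rdf(traj, [0], [1], r_max=r_max, n_bins=n_bins, pbc=False,
                   volume=vol)
        dr = r_max / n_bins
        k = int(d / dr)
        r_mid = (k + 0.5) * dr
        expected = 1.0 / ((1.0 / vol) * 4 * np.pi * r_mid**2 * dr)
        assert g[k] == pytest.approx(expected, rel=1e-4)
        assert np.count_nonzero(g) == 1

    def test_coordination_number_integral(self):
        """sum g rho 4 pi r^2 dr equals the mean in-range target count."""
        traj = generate_ideal_gas(n_atoms=60, box=15.0, n_frames=10, seed=12)
        centers = np.array([0])
        targets = np.arange(1, 60)
        r_max, vol = 6.0, 15.0**3
        r, g = rdf(traj, centers, targets, r_max=r_max, n_bins=40, pbc=False,
                   volume=vol)
        dr = r_max / 40
        integral = np.sum(g * (59 / vol) * 4 * np.pi * r**2 * dr)
        dists = np.linalg.norm(traj.coords[:, 1:, :] - traj.coords[:, :1, :],
                               axis=-1)
        expected = (dists < r_max).sum() / traj.n_frames
        assert integral == pytest.approx(expected, rel=1e-2)

    def test_empty_selection_rejected(self):
        traj = generate_ideal_gas(10, 10.0, 2, seed=13)
        with pytest.raises(ValueError, match="empty"):
            rdf(traj, [], [0], r_max=4.0)

    def test_r_max_beyond_half_box_rejected(self):
        traj = generate_ideal_gas(10, 10.0, 2, seed=14)
        with pytest.raises(ValueError, match="half the shortest box"):
            rdf(traj, [0], [1], r_max=6.0)

    def test_pbc_requires_box(self):
        traj = _traj(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="no box"):
            rdf(traj, [0], [1], r_max=3.0)
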