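"""Tests of the geometric descriptors: C-loop closure and classification,
agonist-anchoring distances, RMSD analyses and series statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from namsite import (
    Atom,
    RangeTable,
    ResidueKey,
    TRP_INDOLE_ATOMS,
    ca_ca_distance,
    cation_pi_distance,
    classify_cloop,
    hbond_distance,
    per_residue_rmsd,
    region_rmsd,
    series_summary,
    sliding_average,
)
from namsite.descriptors import DEFAULT_CLOOP_RANGES
from namsite.structure_io import Chain, Residue, StructureModel, Trajectory


def _two_residue_frame(pos_a, pos_b):
    res_a = Residue(ResidueKey("A", 191), "CYS", [Atom("CA", "C", pos_a)])
    res_b = Residue(ResidueKey("B", 58), "THR", [Atom("CA", "C", pos_b)])
    return StructureModel([Chain("A", [res_a]), Chain("B", [res_b])])


class TestCaCaDistance:
    def test_axis_aligned(self):
        frame = _two_residue_frame([0, 0, 0], [0, 0, 10])
        d = ca_ca_distance(frame, ResidueKey("A", 191), ResidueKey("B", 58))
        assert d == pytest.approx(10.0)

    def test_coincident_positions(self):
        frame = _two_residue_frame([1, 1, 1], [1, 1, 1])
        assert ca_ca_distance(frame, ResidueKey("A", 191), ResidueKey("B", 58)) == 0.0

    def test_matches_closed_form_norm(self, rng):
        for _ in range(50):
            a, b = rng.normal(size=3), rng.normal(size=3)
            frame = _two_residue_frame(a, b)
            d = ca_ca_distance(frame, ResidueKey("A", 191), ResidueKey("B", 58))
            assert d == pytest.approx(float(np.sqrt(((a - b) ** 2).sum())))

    def test_missing_calpha_names_residue(self):
        res = Residue(ResidueKey("A", 191), "CYS", [Atom("CB", "C", [0, 0, 0])])
        frame = StructureModel([Chain("A", [res])])
        with pytest.raises(LookupError, match="A:191"):
            ca_ca_distance(frame, ResidueKey("A", 191), ResidueKey("A", 191))

    def test_rigid_transform_invariance(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=3) + 5
        d0 = ca_ca_distance(_two_residue_frame(a, b),
                            ResidueKey("A", 191), ResidueKey("B", 58))
        rot = Rotation.random(rng=rng)
        shift = rng.normal(size=3) * 10
        d1 = ca_ca_distance(
            _two_residue_frame(rot.apply(a) + shift, rot.apply(b) + shift),
            ResidueKey("A", 191), ResidueKey("B", 58),
        )
        assert d1 == pytest.approx(d0)


class TestClassifyCloop:
    def test_default_table_rows(self):
        rows = {label: (lo, hi) for label, lo, hi in DEFAULT_CLOOP_RANGES.rows}
        assert rows == {
            "agonist": (7.72, 8.19),
            "partial agonist": (9.75, 12.30),
            "antagonist/unbound": (12.88, 16.05),
            "peptidic antagonist": (17.50, 19.24),
        }

    @pytest.mark.parametrize(
        "distance,expected",
        [
            (8.0, "agonist"),
            (18.0, "peptidic antagonist"),
            (11.0, "partial agonist"),
            (14.0, "antagonist/unbound"),
        ],
    )
    def test_in_range_distances(self, distance, expected):
        assert classify_cloop(distance) == expected

    def test_midpoint_of_every_range_returns_that_state(self):
        for label, lo, hi in DEFAULT_CLOOP_RANGES.rows:
            assert classify_cloop((lo + hi) / 2) == label

    def test_gap_value_is_flagged_indeterminate(self):
        assert classify_cloop(9.0) == "indeterminate(agonist, partial agonist)"
        assert classify_cloop(12.5) == "indeterminate(partial agonist, antagonist/unbound)"

    def test_extremes_have_single_flank(self):
        assert classify_cloop(2.0) == "indeterminate(agonist)"
        assert classify_cloop(25.0) == "indeterminate(peptidic antagonist)"

    def test_total_over_nonnegative_axis(self):
        for d in np.linspace(0, 30, 301):
            label = classify_cloop(float(d))
            assert isinstance(label, str) and label

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RangeTable([("a", 0.0, 5.0), ("b", 4.0, 9.0)])
        with pytest.raises(ValueError):
            RangeTable([("a", 5.0, 1.0)])


def _trp_frame(n_pos, ring_center=np.zeros(3), backbone_o=None):
    """A lone tryptophan with its 9 indole heavy atoms on a ring."""
    atoms = []
    if backbone_o is not None:
        atoms.append(Atom("O", "O", backbone_o))
    for i, name in enumerate(TRP_INDOLE_ATOMS):
        angle = 2 * np.pi * i / len(TRP_INDOLE_ATOMS)
        element = "N" if name.startswith("N") else "C"
        atoms.append(Atom(name, element,
                          ring_center + [1.4 * np.cos(angle), 1.4 * np.sin(angle), 0]))
    res = Residue(ResidueKey("A", 148), "TRP", atoms)
    return StructureModel([Chain("A", [res])]), np.asarray(n_pos, dtype=float)


class TestAnchoringDistances:
    def test_hbond_representative_magnitude(self):
        frame, n = _trp_frame([0, 0, 0], backbone_o=np.array([0, 0, 2.88]))
        assert hbond_distance(frame, n, ResidueKey("A", 148)) == pytest.approx(2.88)

    def test_hbond_coincident_atoms(self):
        frame, n = _trp_frame([1, 2, 3], backbone_o=np.array([1, 2, 3]))
        assert hbond_distance(frame, n, ResidueKey("A", 148)) == 0.0

    def test_hbond_missing_backbone_o(self):
        frame, n = _trp_frame([0, 0, 0])
        with pytest.raises(LookupError, match="O"):
            hbond_distance(frame, n, ResidueKey("A", 148))

    def test_cation_pi_equal_mass_symmetric_ring(self):
        # all-carbon ring symmetric about the origin: center of mass at origin
        frame, n = _trp_frame([0, 0, 3.5])
        names = [a for a in TRP_INDOLE_ATOMS if not a.startswith("N")]
        d = cation_pi_distance(frame, n, names, ResidueKey("A", 148))
        center = np.mean(
            [frame.get_residue(ResidueKey("A", 148)).atom(a).coords for a in names],
            axis=0,
        )
        assert d == pytest.approx(float(np.linalg.norm(n - center)))

    def test_cation_at_center_is_zero(self):
        frame, _ = _trp_frame([0, 0, 0])
        names = [a for a in TRP_INDOLE_ATOMS if not a.startswith("N")]
        res = frame.get_residue(ResidueKey("A", 148))
        center = np.mean([res.atom(a).coords for a in names], axis=0)
        assert cation_pi_distance(frame, center, names, ResidueKey("A", 148)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_unequal_masses_match_hand_computation(self):
        frame, n = _trp_frame([0, 0, 3.5])
        res = frame.get_residue(ResidueKey("A", 148))
        coords = np.array([res.atom(a).coords for a in TRP_INDOLE_ATOMS])
        masses = np.array([14.007 if a.startswith("N") else 12.011
                           for a in TRP_INDOLE_ATOMS])
        com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
        expected = float(np.linalg.norm(n - com))
        d = cation_pi_distance(frame, n, TRP_INDOLE_ATOMS, ResidueKey("A", 148))
        assert d == pytest.approx(expected)
        # the nitrogen breaks symmetry: center of mass is not the centroid
        assert not np.allclose(com, coords.mean(axis=0))

    def test_missing_ring_atom_rejected(self):
        frame, n = _trp_frame([0, 0, 3.5])
        with pytest.raises(LookupError, match="CQ9"):
            cation_pi_distance(frame, n, ("CG", "CQ9"), ResidueKey("A", 148))


def _grid_model(n_res=6, spacing=5.0):
    chain = Chain("A")
    for i in range(1, n_res + 1):
        base = np.array([i * spacing, 0.0, 0.0])
        chain.residues.append(
            Residue(ResidueKey("A", i), "ALA", [
                Atom("N", "N", base + [0, 1.2, 0]),
                Atom("CA", "C", base),
                Atom("C", "C", base + [1.2, 0, 0]),
                Atom("O", "O", base + [1.2, 1.0, 0]),
                Atom("CB", "C", base + [0, 0, 1.5]),
            ])
        )
    return StructureModel([chain])


class TestRmsdAnalyses:
    def test_identical_trajectory_is_zero(self):
        ref = _grid_model()
        traj = Trajectory([ref.copy(), ref.copy(), ref.copy()])
        rmsd = per_residue_rmsd(traj, ref)
        assert np.allclose(rmsd.to_numpy(), 0.0, atol=1e-9)

    def test_single_displaced_residue_detected(self):
        ref = _grid_model(n_res=8)
        moved = ref.copy()
        res = moved.get_residue(ResidueKey("A", 4))
        for atom in res.atoms:
            atom.coords = atom.coords + np.array([0.0, 0.0, 2.0])
        traj = Trajectory([moved.copy(), moved.copy()])
        # anchor the superposition on the seven unmoved residues
        anchors = [ResidueKey("A", i) for i in range(1, 9) if i != 4]
        rmsd_anchored = per_residue_rmsd(traj, ref, selection=anchors)
        assert np.allclose(rmsd_anchored.to_numpy(), 0.0, atol=1e-6)
        rmsd_all = per_residue_rmsd(traj, ref, superpose=False)
        assert rmsd_all["A:4"] == pytest.approx(2.0)
        others = rmsd_all.drop("A:4")
        assert np.allclose(others.to_numpy(), 0.0, atol=1e-9)

    def test_gaussian_jitter_matches_chi_expectation(self, rng):
        # E||N(0, sigma^2 I_3)|| has mean sigma*sqrt(8/pi); but RMSD per
        # residue over k atoms concentrates near sigma*sqrt(3) for larger k
        sigma = 0.3
        ref = _grid_model(n_res=40)
        frames = []
        for _ in range(30):
            frame = ref.copy()
            coords = frame.coordinate_array()
            frame.set_coordinates(coords + rng.normal(0, sigma, coords.shape))
            frames.append(frame)
        rmsd = per_residue_rmsd(Trajectory(frames), ref, superpose=False)
        expected = sigma * np.sqrt(3)
        assert abs(rmsd.to_numpy().mean() - expected) / expected < 0.10

    def test_region_rmsd_ignores_excluded_displacement(self):
        ref = _grid_model(n_res=6)
        moved = ref.copy()
        for atom in moved.get_residue(ResidueKey("A", 6)).atoms:
            atom.coords = atom.coords + np.array([0.0, 0.0, 4.0])
        traj = Trajectory([moved])
        series = region_rmsd(traj, ref, exclude=[ResidueKey("A", 6)])
        assert series[0] == pytest.approx(0.0, abs=1e-9)

    def test_region_rmsd_matches_complement_oracle(self, rng):
        ref = _grid_model(n_res=6)
        frame = ref.copy()
        coords = frame.coordinate_array()
        frame.set_coordinates(coords + rng.normal(0, 0.5, coords.shape))
        exclude = [ResidueKey("A", 1)]
        series = region_rmsd(Trajectory([frame]), ref, exclude=exclude, superpose=False)
        keep = [r.key for r in ref.residues() if r.key not in exclude]
        ref_xyz = np.vstack([[a.coords for a in ref.get_residue(k).atoms] for k in keep])
        mov_xyz = np.vstack([[a.coords for a in frame.get_residue(k).atoms] for k in keep])
        expected = np.sqrt(np.mean(np.sum((mov_xyz - ref_xyz) ** 2, axis=1)))
        assert series[0] == pytest.approx(float(expected))

    def test_excluding_everything_rejected(self):
        ref = _grid_model(n_res=2)
        with pytest.raises(ValueError, match="every residue"):
            region_rmsd(Trajectory([ref]), ref,
                        exclude=[ResidueKey("A", 1), ResidueKey("A", 2)])


class TestSlidingAverage:
    def test_constant_series(self):
        means, sds = sliding_average(np.full(10, 3.3), window=4)
        assert np.allclose(means, 3.3)
        assert np.allclose(sds, 0.0)

    def test_small_arithmetic_case(self):
        means, _ = sliding_average([1, 2, 3, 4, 5], window=3)
        assert means == pytest.approx([2.0, 3.0, 4.0])

    def test_linear_series_exact_for_any_window(self):
        n = 60
        series = 2.5 * np.arange(n) + 1.0
        for window in (1, 2, 7, 50, 60):
            means, _ = sliding_average(series, window)
            start = np.arange(n - window + 1)
            expected = 2.5 * (start + (window - 1) / 2) + 1.0
            np.testing.assert_allclose(means, expected)

    def test_white_noise_window_mean_sd(self, rng):
        series = rng.normal(0, 1, size=200_000)
        means, _ = sliding_average(series, window=200)
        # overlapping windows are correlated but marginal SD is sigma/sqrt(w)
        assert abs(np.std(means[::200]) - 1 / np.sqrt(200)) < 0.15 / np.sqrt(200)

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(ValueError):
            sliding_average([1.0, 2.0], window=3)


class TestSeriesSummary:
    def test_constant_series_formatting(self):
        assert str(series_summary([2.88, 2.88, 2.88])) == "2.88 (0.00)"

    def test_population_sd(self):
        summary = series_summary([1, 2, 3])
        assert str(summary) == "2.00 (0.82)"
        assert summary.sd == pytest.approx(np.sqrt(2 / 3))

    def test_minimum_reported_when_requested(self):
        summary = series_summary([12.97, 10.58, 14.2], with_min=True)
        assert summary.minimum == pytest.approx(10.58)
        assert "min 10.58" in str(summary)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            series_summary([])
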