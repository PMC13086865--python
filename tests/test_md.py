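"""COM distance, inter-chain angle, binding states, QT clustering, lifetimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from pepscreen.md import (
    analysis_window,
    classify_binding,
    com_distance,
    contact_lifetimes,
    density_2d,
    descriptor_table,
    interchain_angle,
    qt_cluster,
    read_trajectory_pdb,
    read_trajectory_table,
    write_trajectory_pdb,
    write_trajectory_table,
)
from pepscreen.synthetic import (
    _ca_chain,
    make_conformer_trajectory,
    make_trajectory,
)


def _frame(coords, chains, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    arr = _ca_chain("A", np.arange(1, n + 1), coords)
    arr.chain_id = np.asarray(chains)
    if elements is not None:
        arr.element = np.asarray(elements)
    return arr


class TestComDistance:
    def test_two_point_masses_at_distance_seven(self):
        f = _frame([[0, 0, 0], [7, 0, 0]], ["A", "B"])
        a, b = f.chain_id == "A", f.chain_id == "B"
        assert com_distance(f, a, b) == pytest.approx(7.0)

    def test_coincident_selections_zero(self):
        f = _frame([[1, 2, 3], [1, 2, 3]], ["A", "B"])
        assert com_distance(f, f.chain_id == "A", f.chain_id == "B") == 0.0

    def test_matches_hand_computed_weighted_centroids(self):
        coords = [[0, 0, 0], [2, 0, 0], [10, 0, 0]]
        f = _frame(coords, ["A", "A", "B"], elements=["C", "O", "N"])
        a, b = f.chain_id == "A", f.chain_id == "B"
        ca = (12.011 * np.array([0, 0, 0]) + 15.999 * np.array([2, 0, 0])) / (12.011 + 15.999)
        expected = np.linalg.norm(ca - [10, 0, 0])
        assert com_distance(f, a, b) == pytest.approx(expected, abs=1e-5)
        # geometric centroid option
        assert com_distance(f, a, b, mass_weighted=False) == pytest.approx(9.0)

    def test_empty_selection_raises(self):
        f = _frame([[0, 0, 0]], ["A"])
        with pytest.raises(ValueError, match="empty"):
            com_distance(f, f.chain_id == "A", f.chain_id == "Z")


class TestInterchainAngle:
    def test_right_angle_arms(self):
        f = _frame([[1, 0, 0], [0, 0, 0], [0, 1, 0]], ["A", "A", "B"])
        assert interchain_angle(f, 0, 1, 2) == pytest.approx(90.0)

    def test_collinear_through_vertex(self):
        f = _frame([[-1, 0, 0], [0, 0, 0], [5, 0, 0]], ["A", "A", "B"])
        assert interchain_angle(f, 0, 1, 2) == pytest.approx(180.0)

    def test_zero_length_arm_raises(self):
        f = _frame([[0, 0, 0], [0, 0, 0], [1, 0, 0]], ["A", "A", "B"])
        with pytest.raises(ValueError, match="zero-length"):
            interchain_angle(f, 0, 1, 2)

    def test_atom_triples_resolved_by_chain_res_name(self):
        f = _frame([[1, 0, 0], [0, 0, 0], [0, 2, 0]], ["A", "A", "B"])
        f.res_id = np.array([95, 214, 95])
        angle = interchain_angle(
            f, ("A", 95, "CA"), ("A", 214, "CA"), ("B", 95, "CA")
        )
        assert angle == pytest.approx(90.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_invariance_to_1e9(self, seed):
        """d and theta change by <= 1e-9 (relative) under joint rigid motion."""
        from types import SimpleNamespace

        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=10.0, size=(3, 3))
        if min(np.linalg.norm(coords[0] - coords[1]),
               np.linalg.norm(coords[2] - coords[1])) < 1e-3:
            return
        chains = np.array(["A", "A", "B"])
        elements = np.array(["C", "C", "C"])
        f = SimpleNamespace(coord=coords, chain_id=chains, element=elements)
        before = interchain_angle(f, 0, 1, 2)
        before_d = com_distance(f, chains == "A", chains == "B")
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(scale=50.0, size=3)
        g = SimpleNamespace(coord=coords @ R.T + t, chain_id=chains,
                            element=elements)
        after = interchain_angle(g, 0, 1, 2)
        after_d = com_distance(g, chains == "A", chains == "B")
        assert after == pytest.approx(before, abs=1e-9 * max(1.0, before))
        assert after_d == pytest.approx(before_d, rel=1e-9)


class TestBindingClassification:
    @pytest.mark.parametrize(
        "d,state",
        [(40.0, "bound"), (45.0, "bound"), (47.0, "intermediate"),
         (50.0, "intermediate"), (50.001, "unbound"), (55.0, "unbound"),
         (0.0, "bound")],
    )
    def test_threshold_semantics(self, d, state):
        assert classify_binding(d) == state

    @given(d=st.floats(0.0, 200.0))
    @settings(max_examples=100, deadline=None)
    def test_every_distance_maps_to_exactly_one_state(self, d):
        assert classify_binding(d) in {"bound", "intermediate", "unbound"}

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_binding(10.0, bound_max=60.0, unbound_min=50.0)


class TestDensity2d:
    def test_single_frame_occupies_one_bin(self):
        counts, _, _ = density_2d([42.0], [120.0], bins=151,
                                  ranges=((0, 100), (0, 180)))
        assert counts.sum() == 1 and counts.max() == 1
        assert counts.shape == (151, 151)

    def test_total_count_conserved_for_random_data(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(30, 70, size=5000)
        th = rng.uniform(60, 160, size=5000)
        counts, _, _ = density_2d(d, th, bins=151)
        assert counts.sum() == 5000

    def test_uniform_points_are_flat_within_tolerance(self):
        rng = np.random.default_rng(1)
        n, bins = 200_000, 10
        counts, _, _ = density_2d(
            rng.uniform(0, 1, n), rng.uniform(0, 1, n), bins=bins,
            ranges=((0, 1), (0, 1)),
        )
        from scipy.stats import chisquare

        _, p = chisquare(counts.ravel())
        assert p > 1e-4

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            density_2d([1.0], [1.0], ranges=((5, 5), (0, 1)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            density_2d([], [])


class TestAnalysisWindow:
    def test_default_discards_first_thirty_percent(self):
        w = analysis_window(100)
        assert (w.start, w.stop) == (30, 100)

    def test_full_window_at_zero_discard(self):
        assert analysis_window(10, 0.0) == slice(0, 10)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            analysis_window(1, 0.99)


class TestPlantedTrajectories:
    def test_states_and_angles_recovered_exactly(self):
        traj, truth = make_trajectory(
            seed=0,
            segments=[("bound", 30), ("intermediate", 10), ("unbound", 30)],
            theta_deg=[95.0, 110.0, 140.0],
        )
        table = descriptor_table(
            traj, truth.protein_mask, truth.peptide_mask,
            angle_atoms=truth.angle_atoms,
        )
        assert list(table["state"]) == truth.states
        assert np.allclose(table["theta_deg"], truth.theta_deg, atol=1e-4)
        assert np.allclose(table["d_A"], truth.d_A, atol=1e-4)

    def test_planted_lifetimes_recovered(self):
        traj, truth = make_trajectory(
            seed=1, segments=[("bound", 100)],
            planted_contacts=[(3, 95, 0.40), (7, 214, 0.75)],
        )
        cm = contact_lifetimes(traj, truth.peptide_mask, truth.protein_mask)
        assert cm.lifetimes == pytest.approx(truth.contact_lifetimes)
        persistent = {pair for pair, _ in cm.persistent}
        assert persistent == {(("P", 7), ("A", 214))}   # 0.75 >= 0.5; 0.40 < 0.5

    def test_lifetime_one_when_always_in_contact(self):
        traj, truth = make_trajectory(
            seed=2, segments=[("bound", 40)], planted_contacts=[(5, 95, 1.0)],
        )
        cm = contact_lifetimes(traj, truth.peptide_mask, truth.protein_mask)
        assert cm.lifetimes[(("P", 5), ("A", 95))] == 1.0

    def test_boundary_lifetime_half_is_persistent(self):
        traj, truth = make_trajectory(
            seed=3, segments=[("bound", 100)], planted_contacts=[(5, 95, 0.5)],
        )
        cm = contact_lifetimes(traj, truth.peptide_mask, truth.protein_mask)
        assert any(lam == 0.5 for _, lam in cm.persistent)

    def test_lifetime_monotone_in_cutoff(self):
        traj, truth = make_trajectory(
            seed=4, segments=[("bound", 50)], planted_contacts=[(5, 95, 0.6)],
        )
        lams = []
        for cutoff in (3.5, 5.0, 8.0):
            cm = contact_lifetimes(
                traj, truth.peptide_mask, truth.protein_mask,
                heavy_cutoff_A=cutoff,
            )
            lams.append(cm.lifetimes.get((("P", 5), ("A", 95)), 0.0))
        assert lams == sorted(lams)

    def test_frame_window_restricts_analysis(self):
        traj, truth = make_trajectory(
            seed=5, segments=[("bound", 100)], planted_contacts=[(5, 95, 0.3)],
        )
        # the contact is ON in the first 30 frames; the trailing window
        # of 70 frames therefore never sees it
        cm = contact_lifetimes(
            traj, truth.peptide_mask, truth.protein_mask,
            frames=analysis_window(100, 0.3),
        )
        assert (("P", 5), ("A", 95)) not in cm.lifetimes

    def test_empty_frame_range_rejected(self):
        traj, truth = make_trajectory(seed=6, segments=[("bound", 5)])
        with pytest.raises(ValueError):
            contact_lifetimes(
                traj, truth.peptide_mask, truth.protein_mask,
                frames=slice(5, 5),
            )


class TestQtClustering:
    def test_identical_frames_form_one_cluster(self):
        traj, _ = make_conformer_trajectory(
            seed=0, family_sizes=(20,), spread_A=0.0
        )
        fc = qt_cluster(traj, traj[0].chain_id == "P", rmsd_cutoff_A=5.0)
        assert fc.sizes == [20]

    def test_two_planted_families_recovered(self):
        traj, labels = make_conformer_trajectory(
            seed=1, family_sizes=(30, 20), separation_A=100.0, spread_A=1.0
        )
        fc = qt_cluster(
            traj, traj[0].chain_id == "P", rmsd_cutoff_A=20.0,
            align_selection=traj[0].chain_id == "A",
        )
        assert fc.sizes == [30, 20]
        for cluster in fc.clusters:
            assert len(set(labels[cluster])) == 1

    def test_infinite_cutoff_gives_single_cluster(self):
        traj, _ = make_conformer_trajectory(seed=2, family_sizes=(10, 10, 5))
        fc = qt_cluster(traj, traj[0].chain_id == "P", rmsd_cutoff_A=np.inf)
        assert fc.sizes == [25]

    def test_partition_properties(self):
        traj, _ = make_conformer_trajectory(
            seed=3, family_sizes=(12, 9, 4), separation_A=60.0
        )
        fc = qt_cluster(traj, traj[0].chain_id == "P", rmsd_cutoff_A=20.0)
        assert fc.sizes == sorted(fc.sizes, reverse=True)
        all_frames = np.concatenate(fc.clusters)
        assert sorted(all_frames) == list(range(25))   # disjoint cover

    def test_empty_trajectory_rejected(self):
        traj, _ = make_conformer_trajectory(seed=4, family_sizes=(3,))
        with pytest.raises(ValueError):
            qt_cluster(traj[:0], traj[0].chain_id == "P")


class TestTrajectoryIO:
    def test_pdb_round_trip(self, tmp_path):
        traj, _ = make_trajectory(seed=7, segments=[("bound", 4)])
        path = tmp_path / "traj.pdb"
        write_trajectory_pdb(traj, path)
        back = read_trajectory_pdb(path)
        assert back.stack_depth() == 4
        assert np.allclose(back.coord, traj.coord, atol=1e-2)

    def test_plain_table_round_trip(self, tmp_path):
        traj, truth = make_trajectory(seed=8, segments=[("bound", 3)])
        path = tmp_path / "traj.tsv"
        write_trajectory_table(traj, path)
        back = read_trajectory_table(path)
        assert back.stack_depth() == 3
        assert np.allclose(back.coord, traj.coord, atol=1e-3)
        assert (back[0].chain_id == traj[0].chain_id).all()

    def test_table_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("frame\tx\ty\tz\n0\t0\t0\t0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_trajectory_table(path)
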