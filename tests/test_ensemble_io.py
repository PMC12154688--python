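"""Ensemble containers, file round-trips, homolog merging, snapshot resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromhet import (
    CellConformation,
    ConformationEnsemble,
    ReferenceEnsembleSpec,
    SchemaError,
    TrajectorySet,
    compute_rs_profile,
    SeparationGrid,
    generate_reference_ensemble,
    merge_homolog_chains,
    read_ensemble,
    sample_trajectory_snapshots,
    segment_boundaries,
    write_ensemble,
)

from conftest import make_cell, random_rigid_motion


class TestRoundTrip:
    def test_tsv_round_trip_identity(self, two_cell_ensemble, tmp_path):
        path = str(tmp_path / "ens.tsv")
        write_ensemble(two_cell_ensemble, path)
        back = read_ensemble(path)
        assert back.n_cells == 2 and back.n_beads == 5
        assert back.length_unit == "micron"
        assert back.avg_bead_genomic_size == 10_000
        for a, b in zip(two_cell_ensemble.cells, back.cells):
            assert a.cell_id == b.cell_id
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-6)
            np.testing.assert_array_equal(a.genomic_sizes, b.genomic_sizes)
            np.testing.assert_allclose(a.radii, b.radii, rtol=0, atol=0)

    def test_xyz_round_trip_with_sidecar(self, two_cell_ensemble, tmp_path):
        xyz = str(tmp_path / "ens.xyz")
        side = str(tmp_path / "side.tsv")
        write_ensemble(two_cell_ensemble, xyz, format="xyz")
        with open(side, "w") as fh:
            fh.write("#unit=micron\n#avg_bead_genomic_size_bp=10000\n")
            fh.write("bead_index\tradius\tgenomic_size_bp\n")
            for i in range(5):
                fh.write(f"{i}\t0.05\t10000\n")
        back = read_ensemble(xyz, sidecar=side)
        np.testing.assert_allclose(
            back.cells[0].positions, two_cell_ensemble.cells[0].positions,
            atol=1e-6)

    def test_generated_ensemble_round_trips(self, tmp_path):
        spec = ReferenceEnsembleSpec(kind="fjc", n_replicas=3, n_segments=64,
                                     seed=11)
        ens = generate_reference_ensemble(spec)
        path = str(tmp_path / "fjc.tsv")
        write_ensemble(ens, path)
        back = read_ensemble(path)
        assert back.n_cells == 3 and back.n_beads == 65
        for a, b in zip(ens.cells, back.cells):
            np.testing.assert_allclose(a.positions, b.positions, rtol=1e-9)

    def test_adapter_maps_external_column_layout(self, tmp_path):
        # a deposited file with its own column names and no headers
        path = tmp_path / "deposit.csv"
        path.write_text(
            "cell,bead,X,Y,Z,r,bp\n"
            "n1,0,0,0,0,0.1,118000\n"
            "n1,1,1,0,0,0.1,118000\n")
        ens = read_ensemble(str(path), format="tsv", adapter={
            "sep": ",",
            "unit": "micron",
            "avg_bead_genomic_size_bp": 118_000,
            "columns": {"cell_id": "cell", "bead_index": "bead",
                        "x": "X", "y": "Y", "z": "Z", "radius": "r",
                        "genomic_size_bp": "bp"},
        })
        assert ens.n_cells == 1 and ens.n_beads == 2
        assert ens.length_unit == "micron"

    def test_round_trip_preserves_rs_curve(self, tmp_path):
        spec = ReferenceEnsembleSpec(kind="hilbert", p=3, n_replicas=1, seed=4)
        ens = generate_reference_ensemble(spec)
        grid = SeparationGrid.for_ensemble(ens)
        before = compute_rs_profile(ens.cells[0], grid).values
        path = str(tmp_path / "h.tsv")
        write_ensemble(ens, path)
        after = compute_rs_profile(read_ensemble(path).cells[0], grid).values
        np.testing.assert_allclose(before, after, rtol=1e-8)


class TestSchemaValidation:
    def test_unequal_bead_counts_rejected(self):
        c1 = make_cell("c1", [[0, 0, 0], [1, 0, 0]])
        c2 = make_cell("c2", [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(SchemaError, match="beads"):
            ConformationEnsemble(cells=[c1, c2])

    def test_missing_unit_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#avg_bead_genomic_size_bp=10000\n"
            "cell_id\tchain_id\tbead_index\tx\ty\tz\tradius\tgenomic_size_bp\n"
            "c1\t0\t0\t0\t0\t0\t0.1\t10000\n"
            "c1\t0\t1\t1\t0\t0\t0.1\t10000\n")
        with pytest.raises(SchemaError, match="unit"):
            read_ensemble(str(path))

    @pytest.mark.parametrize("bad", [
        {"positions": [[0, 0, 0]]},                      # single bead
        {"genomic_size": -1},                            # invalid genomic size
        {"radius": -0.5},                                # negative radius
    ])
    def test_cell_invariants(self, bad):
        kwargs = dict(positions=[[0, 0, 0], [1, 0, 0]])
        kwargs.update(bad)
        with pytest.raises(SchemaError):
            make_cell("c", **kwargs)

    def test_nonfinite_positions_rejected(self):
        with pytest.raises(SchemaError, match="finite"):
            make_cell("c", [[0, 0, 0], [np.inf, 0, 0]])


class TestMergeHomologs:
    def test_identical_chains_merge_to_themselves(self):
        c = make_cell("c", [[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        merged = merge_homolog_chains(c, c)
        np.testing.assert_array_equal(merged.positions, c.positions)
        np.testing.assert_array_equal(merged.radii, c.radii)

    def test_symmetric_pair_merges_to_origin(self):
        d = 3.0
        a = make_cell("a", [[+d / 2, 0, 0], [+d / 2, 1, 0]])
        b = make_cell("b", [[-d / 2, 0, 0], [-d / 2, 1, 0]])
        merged = merge_homolog_chains(a, b)
        np.testing.assert_allclose(merged.positions[:, 0], 0.0)

    def test_unequal_lengths_rejected(self):
        a = make_cell("a", [[0, 0, 0], [1, 0, 0]])
        b = make_cell("b", [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(SchemaError, match="unequal"):
            merge_homolog_chains(a, b)

    @given(st.integers(0, 10_000))
    def test_merge_commutes_with_rigid_motions(self, seed):
        rng = np.random.default_rng(seed)
        pos_a = rng.normal(size=(6, 3))
        pos_b = rng.normal(size=(6, 3))
        a, b = make_cell("a", pos_a), make_cell("b", pos_b)
        Q, t = random_rigid_motion(rng)
        a2 = make_cell("a", pos_a @ Q.T + t)
        b2 = make_cell("b", pos_b @ Q.T + t)
        moved_then_merged = merge_homolog_chains(a2, b2).positions
        merged_then_moved = merge_homolog_chains(a, b).positions @ Q.T + t
        np.testing.assert_allclose(moved_then_merged, merged_then_moved,
                                   atol=1e-10)


def _tiny_trajectories(n_traj, n_snap, seed=0):
    rng = np.random.default_rng(seed)
    return [
        [make_cell(f"t{t}s{s}", rng.normal(size=(3, 3))) for s in range(n_snap)]
        for t in range(n_traj)
    ]


class TestTrajectoryResampling:
    def test_boundaries_include_endpoints(self):
        b = segment_boundaries(400_000, 50)
        assert b[0] == 0 and b[-1] == 399_999 and len(b) == 50
        assert np.all(np.diff(b) > 0)

    def test_one_resample_gives_one_cell_per_trajectory(self):
        traj = TrajectorySet(_tiny_trajectories(18, 50), n_segments=50,
                             n_resamples=1, seed=7)
        (ens,) = sample_trajectory_snapshots(traj)
        assert ens.n_cells == 18

    def test_same_seed_reproduces_resamples(self):
        trajs = _tiny_trajectories(4, 10)
        a = sample_trajectory_snapshots(
            TrajectorySet(trajs, n_segments=5, n_resamples=3, seed=42))
        b = sample_trajectory_snapshots(
            TrajectorySet(trajs, n_segments=5, n_resamples=3, seed=42))
        for ea, eb in zip(a, b):
            for ca, cb in zip(ea.cells, eb.cells):
                np.testing.assert_array_equal(ca.positions, cb.positions)

    def test_every_draw_is_a_segment_boundary(self):
        # brute force: 2 trajectories x 4 snapshots, 2 segments -> boundaries
        # are snapshots {0, 3}; sweep many seeds and check all draws land there
        trajs = _tiny_trajectories(2, 4, seed=5)
        boundary_positions = {
            tuple(map(tuple, trajs[t][i].positions.round(12)))
            for t in range(2) for i in (0, 3)
        }
        for seed in range(60):
            out = sample_trajectory_snapshots(
                TrajectorySet(trajs, n_segments=2, n_resamples=2, seed=seed))
            for ens in out:
                for cell in ens.cells:
                    key = tuple(map(tuple, cell.positions.round(12)))
                    assert key in boundary_positions

    def test_too_few_snapshots_rejected(self):
        with pytest.raises(SchemaError, match="fewer"):
            TrajectorySet(_tiny_trajectories(1, 4), n_segments=10)
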