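"""File formats: trajectories, pose tables, FES grids, angle series."""
import numpy as np
import pytest

from torsionfes import (AngleSeries, PeriodicGrid2D, TrajectoryFormatError,
                        boltzmann_invert, extract_series, read_angle_series,
                        read_fes, read_pose_table, read_trajectory,
                        realize_coordinates, write_angle_series, write_fes,
                        write_pdb, write_xyz)
from tests.conftest import POSE_TABLE_TEXT


@pytest.fixture
def small_traj():
    rng = np.random.default_rng(77)
    return realize_coordinates(AngleSeries(rng.uniform(-180, 180, (3, 2))))


def test_pdb_round_trip(tmp_path, small_traj):
    path = tmp_path / "traj.pdb"
    write_pdb(path, small_traj)
    back = read_trajectory(path)
    assert back.n_frames == 3 and back.n_atoms == 5
    assert back.atom_names == small_traj.atom_names
    # PDB stores 3 decimals
    np.testing.assert_allclose(back.coordinates, small_traj.coordinates,
                               atol=5e-4)


def test_xyz_round_trip(tmp_path, small_traj):
    path = tmp_path / "traj.xyz"
    write_xyz(path, small_traj)
    back = read_trajectory(path)
    assert back.n_frames == 3 and back.atom_names == small_traj.atom_names
    np.testing.assert_allclose(back.coordinates, small_traj.coordinates,
                               atol=1e-6)


def test_pdb_and_xyz_agree_within_pdb_precision(tmp_path, small_traj):
    write_pdb(tmp_path / "t.pdb", small_traj)
    write_xyz(tmp_path / "t.xyz", small_traj)
    a = read_trajectory(tmp_path / "t.pdb")
    b = read_trajectory(tmp_path / "t.xyz")
    assert np.max(np.abs(a.coordinates - b.coordinates)) < 1e-3


def test_torsions_survive_pdb_round_trip(tmp_path):
    rng = np.random.default_rng(78)
    requested = AngleSeries(rng.uniform(-180, 180, (20, 2)))
    write_pdb(tmp_path / "t.pdb", realize_coordinates(requested))
    recovered = extract_series(read_trajectory(tmp_path / "t.pdb"))
    # 1e-3 A coordinate rounding moves a torsion by < 0.15 degrees here
    assert np.max(np.abs(recovered.values - requested.values)) < 0.2


def test_empty_file_is_an_error_not_an_empty_trajectory(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(TrajectoryFormatError):
        read_trajectory(path)
    (tmp_path / "empty.xyz").write_text("")
    with pytest.raises(TrajectoryFormatError):
        read_trajectory(tmp_path / "empty.xyz")


def test_inconsistent_atom_count_names_the_frame(tmp_path, small_traj):
    path = tmp_path / "bad.pdb"
    write_pdb(path, small_traj)
    lines = path.read_text().splitlines()
    # drop one ATOM record from the second MODEL block
    second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
    del lines[second_model + 2]
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(TrajectoryFormatError, match="frame 1"):
        read_trajectory(path)


def test_truncated_xyz_frame_reports_line(tmp_path, small_traj):
    path = tmp_path / "bad.xyz"
    write_xyz(path, small_traj)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:-2]) + "\n")
    with pytest.raises(TrajectoryFormatError, match="line"):
        read_trajectory(path)


def test_unparsable_xyz_coordinate_reports_line(tmp_path, small_traj):
    path = tmp_path / "bad.xyz"
    write_xyz(path, small_traj)
    text = path.read_text().replace("N ", "N x", 1)
    path.write_text(text)
    with pytest.raises(TrajectoryFormatError, match="line 3"):
        read_trajectory(path)


def test_single_frame_pdb_without_model_records(tmp_path, small_traj):
    path = tmp_path / "one.pdb"
    write_pdb(path, small_traj)
    body = [l for l in path.read_text().splitlines()
            if l.startswith("ATOM")][:5]
    path.write_text("\n".join(body) + "\nEND\n")
    traj = read_trajectory(path)
    assert traj.n_frames == 1 and traj.n_atoms == 5


# --- pose tables ---------------------------------------------------------


def test_printed_pose_table_parses_exactly(pose_table_file):
    records = read_pose_table(pose_table_file)
    assert len(records) == 6
    first = records[0]
    assert (first.ranking, first.receptor) == (1, "EphA2")
    assert (first.chi1, first.chi2, first.score) == (-57.0, -15.0, -5.5)
    assert [r.receptor for r in records[3:]] == ["EphB2"] * 3
    assert records[3].chi1 == 60.0 and records[3].score == -7.4


def test_pose_angles_wrap_on_ingestion(tmp_path):
    path = tmp_path / "wrap.csv"
    path.write_text("ranking,receptor,chi1,chi2,score\n1,EphA2,185,-15,-5.5\n")
    rec = read_pose_table(path)[0]
    assert rec.chi1 == -175.0


def test_duplicate_ranking_within_receptor_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text("ranking,receptor,chi1,chi2,score\n"
                    "1,EphA2,0,0,-5\n1,EphA2,10,10,-4\n")
    with pytest.raises(TrajectoryFormatError, match="duplicate ranking"):
        read_pose_table(path)


def test_same_ranking_on_different_receptors_allowed(tmp_path):
    path = tmp_path / "ok.csv"
    path.write_text("ranking,receptor,chi1,chi2,score\n"
                    "1,EphA2,0,0,-5\n1,EphB2,10,10,-4\n")
    assert len(read_pose_table(path)) == 2


def test_missing_column_and_bad_value_errors(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text("ranking,receptor,chi1,score\n1,EphA2,0,-5\n")
    with pytest.raises(TrajectoryFormatError, match="chi2"):
        read_pose_table(path)
    path.write_text("ranking,receptor,chi1,chi2,score\n1,EphA2,abc,0,-5\n")
    with pytest.raises(TrajectoryFormatError, match="row 0"):
        read_pose_table(path)


# --- FES text grid -------------------------------------------------------


def test_fes_round_trip_preserves_values_and_mask(tmp_path):
    rng = np.random.default_rng(55)
    counts = rng.integers(0, 500, size=(24, 24))
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    path = tmp_path / "fes.txt"
    write_fes(path, fes)
    back = read_fes(path)
    assert np.array_equal(back.empty_mask, fes.empty_mask)
    pop = ~fes.empty_mask
    assert np.max(np.abs(back.delta_g[pop] - fes.delta_g[pop])) < 1e-6
    assert back.bin_width == fes.bin_width
    assert back.n_frames == fes.n_frames


def test_fes_row_with_wrong_length_rejected(tmp_path):
    counts = np.ones((24, 24), dtype=int)
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    path = tmp_path / "fes.txt"
    write_fes(path, fes)
    lines = path.read_text().splitlines()
    lines[5] = " ".join(lines[5].split()[:23])
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(TrajectoryFormatError, match="24x24"):
        read_fes(path)


def test_single_populated_bin_serializes_as_one_zero(tmp_path):
    counts = np.zeros((24, 24), dtype=int)
    counts[3, 17] = 42
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    path = tmp_path / "fes.txt"
    write_fes(path, fes)
    body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    tokens = " ".join(body).split()
    assert tokens.count("NA") == 575
    assert sum(t == "0.000000" for t in tokens) == 1


# --- angle series --------------------------------------------------------


def test_angle_series_round_trip(tmp_path):
    rng = np.random.default_rng(66)
    series = AngleSeries(rng.uniform(-180, 180, (200, 2)), names=("chi1", "chi2"))
    path = tmp_path / "angles.tsv"
    write_angle_series(path, series)
    assert path.read_text().startswith("# chi1 chi2")
    back = read_angle_series(path)
    assert back.names == ("chi1", "chi2")
    np.testing.assert_allclose(back.values, series.values, atol=1e-7)
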