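"""Minima detection, basin assignment and docking-pose projection."""
import numpy as np
import pytest

from torsionfes import (PeriodicGrid2D, PoseRecord, boltzmann_invert,
                        build_potential, find_minima, histogram2d_periodic,
                        local_minimum_mask, project_poses, sample_torus)
from torsionfes.landscape import projections_to_text
from tests.conftest import WELL1_BIN, WELL2_BIN, random_fes


def brute_force_minima(fes):
    """Exhaustive 8-neighbor periodic test of every populated bin."""
    n = fes.n_bins
    g = np.where(fes.empty_mask, np.inf, fes.delta_g)
    out = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if fes.empty_mask[i, j]:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    if g[i, j] > g[(i + di) % n, (j + dj) % n]:
                        ok = False
            out[i, j] = ok
    return out


def test_minima_mask_matches_brute_force_on_random_surfaces():
    rng = np.random.default_rng(11)
    for k in range(50):
        fes = random_fes(rng, n_empty=rng.integers(0, 200))
        assert np.array_equal(local_minimum_mask(fes), brute_force_minima(fes))


def test_single_well_recovery_one_minimum_at_center():
    pot = build_potential([((-52.5, -7.5), 8.0, 12.0)])
    s = sample_torus(pot, n_frames=25_000, seed=21)
    basins = find_minima(boltzmann_invert(histogram2d_periodic(s)))
    assert basins.minima[0].bin == WELL1_BIN
    assert basins.minima[0].delta_g == 0.0
    assert len(basins.minima) == 1


def test_two_well_recovery_ranks_and_energies(two_well_fes):
    basins = find_minima(two_well_fes)
    assert basins.minima[0].bin == WELL1_BIN
    assert basins.minima[1].bin == WELL2_BIN
    assert basins.minima[1].delta_g == pytest.approx(1.0, abs=0.15)
    fractions = [m.population_fraction for m in basins.minima]
    assert sum(fractions) == pytest.approx(1.0, abs=1e-12)
    assert fractions[0] > fractions[1]


def test_uniform_surface_collapses_to_one_plateau_minimum():
    fes = boltzmann_invert(PeriodicGrid2D(np.full((24, 24), 3)))
    basins = find_minima(fes)
    assert len(basins.minima) == 1
    assert basins.minima[0].population_fraction == 1.0
    assert np.all(basins.basin_map == 0)


def test_equal_plateau_merges_at_circular_mean_center():
    counts = np.full((24, 24), 1, dtype=int)
    counts[4, 6] = counts[4, 7] = 500  # adjacent equal-count plateau
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    basins = find_minima(fes, min_population=0)
    assert basins.minima[0].delta_g == 0.0
    # circular mean of bin centers -82.5 and -67.5 on chi2
    assert basins.minima[0].center[1] == pytest.approx(-75.0, abs=1e-9)


def test_minima_and_basins_roll_with_the_surface():
    rng = np.random.default_rng(13)
    # continuous-valued counts: ties have probability zero
    counts = rng.integers(10, 100_000, size=(24, 24))
    base = find_minima(boltzmann_invert(PeriodicGrid2D(counts)), min_population=0)
    for shift in [(3, 0), (0, 5), (7, 11)]:
        rolled = find_minima(
            boltzmann_invert(PeriodicGrid2D(np.roll(counts, shift, axis=(0, 1)))),
            min_population=0)
        expect = sorted(((m.bin[0] + shift[0]) % 24, (m.bin[1] + shift[1]) % 24)
                        for m in base.minima)
        assert sorted(m.bin for m in rolled.minima) == expect
        assert np.array_equal(rolled.basin_map > -1,
                              np.roll(base.basin_map > -1, shift, axis=(0, 1)))


def test_noise_floor_absorbs_small_basins(two_well_fes):
    strict = find_minima(two_well_fes, min_population=0)
    default = find_minima(two_well_fes, min_population=10)
    assert len(default.minima) <= len(strict.minima)
    # total population is conserved by absorption
    assert sum(m.population_fraction for m in default.minima) == pytest.approx(1.0)


# --- pose projection -----------------------------------------------------


def test_table1_pose_maps_to_forced_bin(two_well_fes):
    basins = find_minima(two_well_fes)
    pose = PoseRecord(1, "EphA2", -57.0, -15.0, -5.5)
    proj = project_poses(two_well_fes, basins, [pose])[0]
    assert proj.bin == (8, 11)  # floor((-57+180)/15), floor((-15+180)/15)
    assert proj.classification == "global-min-basin"


def test_pose_on_bin_edge_uses_left_closed_convention(two_well_fes):
    basins = find_minima(two_well_fes)
    proj = project_poses(two_well_fes, basins,
                         [PoseRecord(1, "X", -45.0, 0.0, -1.0)])[0]
    assert proj.bin[0] == 9  # the bin starting at -45


def test_projection_invariant_to_adding_360(two_well_fes):
    basins = find_minima(two_well_fes)
    a = project_poses(two_well_fes, basins,
                      [PoseRecord(1, "X", -57.0, -15.0, -1.0)])[0]
    b = project_poses(two_well_fes, basins,
                      [PoseRecord(1, "X", -57.0 + 360.0, -15.0 - 360.0, -1.0)])[0]
    assert a.bin == b.bin and a.classification == b.classification


def test_pose_in_empty_bin_is_unpopulated():
    counts = np.zeros((24, 24), dtype=int)
    counts[0, 0] = 100
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    basins = find_minima(fes)
    proj = project_poses(fes, basins, [PoseRecord(1, "X", 100.0, 100.0, -1.0)])[0]
    assert proj.classification == "unpopulated"
    assert np.isnan(proj.delta_g)


def test_high_energy_threshold_classification():
    counts = np.zeros((24, 24), dtype=int)
    counts[0, 0] = 100_000
    counts[12, 12] = 100  # about RT*ln(1000) = 4.1 kcal/mol up
    fes = boltzmann_invert(PeriodicGrid2D(counts))
    basins = find_minima(fes)
    pose = PoseRecord(2, "X", 7.5, 7.5, -1.0)
    hi = project_poses(fes, basins, [pose], high_energy_threshold=3.0)[0]
    lo = project_poses(fes, basins, [pose], high_energy_threshold=5.0)[0]
    assert hi.classification == "high-energy"
    assert lo.classification != "high-energy"


def test_projection_report_has_appended_columns(two_well_fes):
    basins = find_minima(two_well_fes)
    text = projections_to_text(project_poses(
        two_well_fes, basins, [PoseRecord(1, "EphA2", -57.0, -15.0, -5.5)]))
    header = text.splitlines()[0].split("\t")
    assert header[:5] == ["ranking", "receptor", "chi1", "chi2", "score"]
    assert header[5:] == ["bin_chi1", "bin_chi2", "ddG_kcal_mol", "classification"]
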