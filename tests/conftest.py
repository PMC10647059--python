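"""Shared fixtures: the standard synthetic fixtures and the printed pose table."""
import numpy as np
import pytest

from torsionfes import (boltzmann_invert, build_potential,
                        histogram2d_periodic, sample_torus)

# Two-well reference potential: depths 3.0 and 2.0 kcal/mol give a
# well-center free-energy difference of exactly 1.0 kcal/mol by
# construction; centers sit on bin centers 180 deg apart on both axes so
# the wells are effectively isolated (cross-talk < 1e-4 kcal/mol).
TWO_WELL_SPEC = [((-52.5, -7.5), 6.0, 3.0), ((127.5, 172.5), 6.0, 2.0)]
WELL1_BIN = (8, 11)
WELL2_BIN = (20, 23)

# The six top-ranked docking poses as printed (tab-delimited, en-dash
# minus signs as in the journal typography).
POSE_TABLE_TEXT = (
    "ranking\treceptor\tχ_1_ (degrees)\tχ_2_ (degrees)\tscore (kcal/mol)\n"
    "1\tEphA2\t–57\t–15\t–5.5\n"
    "2\tEphA2\t–171\t58\t–5.0\n"
    "3\tEphA2\t–62\t155\t–4.8\n"
    "1\tEphB2\t60\t–91\t–7.4\n"
    "2\tEphB2\t63\t–176\t–6.5\n"
    "3\tEphB2\t120\t72\t–6.3\n"
)


@pytest.fixture(scope="session")
def two_well_potential():
    return build_potential(TWO_WELL_SPEC)


@pytest.fixture(scope="session")
def two_well_series(two_well_potential):
    """A long stationary sample of the two-well potential."""
    return sample_torus(two_well_potential, n_frames=500_000, seed=20_250)


@pytest.fixture(scope="session")
def two_well_fes(two_well_series):
    return boltzmann_invert(histogram2d_periodic(two_well_series))


@pytest.fixture
def pose_table_file(tmp_path):
    path = tmp_path / "poses.tsv"
    path.write_text(POSE_TABLE_TEXT, encoding="utf-8")
    return path


def random_fes(rng, n_empty=0, bin_width=15.0):
    """A surface from random counts, optionally with empty bins."""
    n = int(round(360.0 / bin_width))
    counts = rng.integers(1, 1000, size=(n, n))
    if n_empty:
        flat = rng.choice(n * n, size=n_empty, replace=False)
        counts.reshape(-1)[flat] = 0
    from torsionfes import PeriodicGrid2D
    return boltzmann_invert(PeriodicGrid2D(counts, bin_width))
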