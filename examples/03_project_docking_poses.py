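"""Project a table of docking poses onto a reconstructed free-energy surface.

Each pose's (chi1, chi2) pair maps to a 15-degree bin on the surface; the
report gives that bin's free energy relative to the global minimum and a
classification: inside the global-minimum basin, inside an alternative
basin, a high-energy state (>= 3 kcal/mol up by default), or in a bin the
trajectory never visited.
"""
import tempfile
from pathlib import Path

from torsionfes import (boltzmann_invert, build_potential, find_minima,
                        histogram2d_periodic, project_poses, read_pose_table,
                        sample_torus)

POSES = """ranking,receptor,chi1 (degrees),chi2 (degrees),score (kcal/mol)
1,EphA2,-57,-15,-5.5
2,EphA2,-171,58,-5.0
3,EphA2,-62,155,-4.8
"""

potential = build_potential([((-52.5, -7.5), 6.0, 3.0),
                             ((127.5, 172.5), 6.0, 2.0)])
series = sample_torus(potential, n_frames=200_000, seed=3)
fes = boltzmann_invert(histogram2d_periodic(series))
basins = find_minima(fes)

with tempfile.TemporaryDirectory() as tmp:
    table = Path(tmp) / "poses.csv"
    table.write_text(POSES)
    poses = read_pose_table(table)

for proj in project_poses(fes, basins, poses, high_energy_threshold=3.0):
    dg = "   undefined" if proj.delta_g != proj.delta_g else f"{proj.delta_g:7.2f}"
    print(f"pose {proj.pose.ranking} ({proj.pose.receptor}): "
          f"chi1={proj.pose.chi1:7.1f} chi2={proj.pose.chi2:7.1f} deg "
          f"-> bin {proj.bin}, ddG {dg} kcal/mol, {proj.classification}")
# pose 1 sits in the deep well's bin and lands in the global-minimum
# basin; poses in sparsely visited regions read as high-energy states
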