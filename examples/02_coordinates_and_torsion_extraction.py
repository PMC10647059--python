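"""Round-trip torsions through Cartesian coordinates and trajectory files.

Realizes a (chi1, chi2) series as 3D coordinates of a five-atom
tryptophan-like fragment (N, CA, CB, CG, CD1), writes it as multi-model PDB
and XYZ, reads both back and re-extracts the torsions.  Each file round
trip is exact to its coordinate precision (6 decimals for XYZ, 3 for PDB:
a torsion moves by well under a tenth of a degree); the in-memory
realization is invertible to machine precision.
"""
import tempfile
from pathlib import Path

import numpy as np

from torsionfes import (AngleSeries, extract_series, read_trajectory,
                        realize_coordinates, write_pdb, write_xyz)

rng = np.random.default_rng(7)
requested = AngleSeries(rng.uniform(-180.0, 180.0, size=(25, 2)))
traj = realize_coordinates(requested)
print(f"frames: {traj.n_frames}, atoms: {traj.atom_names}")

with tempfile.TemporaryDirectory() as tmp:
    pdb, xyz = Path(tmp) / "traj.pdb", Path(tmp) / "traj.xyz"
    write_pdb(pdb, traj)
    write_xyz(xyz, traj)
    for path in (pdb, xyz):
        recovered = extract_series(read_trajectory(path))
        err = np.max(np.abs(recovered.values - requested.values))
        print(f"{path.suffix[1:]} round trip: max |requested - recovered| "
              f"= {err:.2e} degrees")
# in-memory realization is invertible to < 1e-6 degrees; file formats add
# only their documented coordinate-precision error
direct = extract_series(traj)
print(f"in-memory round trip     : "
      f"{np.max(np.abs(direct.values - requested.values)):.2e} degrees")
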