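"""Readers and writers for trajectories and tabular analysis inputs.

Formats handled here:

* multi-model PDB (``MODEL``/``ENDMDL`` frames, read through Biopython);
* XYZ frame blocks (atom count, comment, label x y z);
* docking-pose tables (delimited text with ranking, receptor, chi1, chi2,
  score columns);
* the package's own free-energy-surface text grid;
* two-column angle-series text.

All readers reject malformed input rather than silently repairing it, and
every error message carries a location (frame, line or row).
"""
from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .angles import AngleSeries, wrap_angle
from .constants import thermal_energy
from .fes import FreeEnergySurface, PeriodicGrid2D

__all__ = [
    "TrajectoryFormatError", "Trajectory", "PoseRecord",
    "read_trajectory", "write_pdb", "write_xyz",
    "read_pose_table", "write_fes", "read_fes",
    "write_angle_series", "read_angle_series",
]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory or table input; the message locates the problem."""


@dataclass
class Trajectory:
    """Cartesian coordinates for a fixed set of atoms over frames.

    coordinates : (n_frames, n_atoms, 3) array, angstrom.
    atom_names : PDB-style atom names (N, CA, CB, CG, CD1, ...).
    res_seq : residue sequence number per atom.
    res_names : residue name per atom.
    """

    coordinates: np.ndarray
    atom_names: list[str]
    res_seq: list[int]
    res_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}")
        if self.n_frames < 1:
            raise ValueError("a trajectory needs at least one frame")
        if len(self.atom_names) != self.n_atoms:
            raise ValueError("atom_names length does not match coordinates")
        if not self.res_names:
            self.res_names = ["UNK"] * self.n_atoms

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def labels(self) -> list[str]:
        """Qualified atom labels, ``resseq:name``."""
        return [f"{r}:{n}" for r, n in zip(self.res_seq, self.atom_names)]

    def index_of(self, identifier: str) -> int:
        """Resolve an atom identifier (``name`` or ``resseq:name``) to its index.

        Bare names must be unique in the trajectory; ambiguity and absence
        both raise KeyError naming the identifier.
        """
        labels = self.labels
        if identifier in labels:
            return labels.index(identifier)
        hits = [i for i, n in enumerate(self.atom_names) if n == identifier]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise KeyError(f"atom {identifier!r} not found among {labels}")
        raise KeyError(f"atom name {identifier!r} is ambiguous "
                       f"({len(hits)} matches); qualify it as resseq:name")


@dataclass(frozen=True)
class PoseRecord:
    """One docking pose: rank, receptor tag, torsions (deg) and score (kcal/mol)."""

    ranking: int
    receptor: str
    chi1: float
    chi2: float
    score: float

    def __post_init__(self):
        object.__setattr__(self, "chi1", float(wrap_angle(self.chi1)))
        object.__setattr__(self, "chi2", float(wrap_angle(self.chi2)))


# ---------------------------------------------------------------------------
# coordinate trajectories


def _element_of(name: str) -> str:
    return name.strip()[0] if name.strip() else "X"


def write_pdb(path, trajectory: Trajectory) -> None:
    """Write a multi-model PDB (one MODEL/ENDMDL block per frame)."""
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory.coordinates, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (xyz, name, resseq, resname) in enumerate(
                    zip(frame, trajectory.atom_names, trajectory.res_seq,
                        trajectory.res_names), start=1):
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i:5d} {pdb_name:4s} {resname:<3s} A{resseq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {_element_of(name):>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_xyz(path, trajectory: Trajectory, precision: int = 6) -> None:
    """Write XYZ frame blocks; the symbol column carries the atom name."""
    with open(path, "w") as fh:
        for m, frame in enumerate(trajectory.coordinates):
            fh.write(f"{trajectory.n_atoms}\n")
            fh.write(f"frame {m}\n")
            for xyz, name in zip(frame, trajectory.atom_names):
                fh.write(f"{name:<4s} {xyz[0]:14.{precision}f} "
                         f"{xyz[1]:14.{precision}f} {xyz[2]:14.{precision}f}\n")


def _read_pdb(path) -> Trajectory:
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except PDBConstructionException as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise TrajectoryFormatError(
            f"{path}: unparsable numeric field ({exc})") from exc

    frames, names, res_seq, res_names = [], None, None, None
    for model in structure:
        f_names, f_seq, f_resnames, coords = [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue.get_list():
                    if atom.is_disordered():
                        atom = atom.disordered_get_list()[0]
                        warnings.warn(
                            f"{path}: keeping first altloc of "
                            f"{residue.id[1]}:{atom.get_name()}")
                    f_names.append(atom.get_name())
                    f_seq.append(residue.id[1])
                    f_resnames.append(residue.get_resname())
                    coords.append(atom.get_coord())
        if names is None:
            names, res_seq, res_names = f_names, f_seq, f_resnames
        elif f_names != names:
            raise TrajectoryFormatError(
                f"{path}: frame {len(frames)} has atoms {f_names}, "
                f"expected {names}")
        frames.append(np.asarray(coords, dtype=float))
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames (empty or headerless file)")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        bad = next(i for i, f in enumerate(frames) if f.shape != frames[0].shape)
        raise TrajectoryFormatError(
            f"{path}: frame {bad} has {frames[bad].shape[0]} atoms, "
            f"expected {frames[0].shape[0]}")
    return Trajectory(np.stack(frames), names, res_seq, res_names)


def _read_xyz(path) -> Trajectory:
    frames, names = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: line {pos + 1}: expected atom count, "
                f"got {lines[pos]!r}") from exc
        if pos + 2 + n_atoms > len(lines):
            raise TrajectoryFormatError(
                f"{path}: line {pos + 1}: frame truncated "
                f"({n_atoms} atoms declared)")
        f_names, coords = [], []
        for j in range(n_atoms):
            ln = pos + 2 + j
            parts = lines[ln].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}: line {ln + 1}: expected 'label x y z', "
                    f"got {lines[ln]!r}")
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}: line {ln + 1}: unparsable coordinate "
                    f"in {lines[ln]!r}") from exc
            f_names.append(parts[0])
        if names is None:
            names = f_names
        elif f_names != names:
            raise TrajectoryFormatError(
                f"{path}: frame {len(frames)} has atoms {f_names}, "
                f"expected {names}")
        frames.append(coords)
        pos += 2 + n_atoms
    if not frames:
        raise TrajectoryFormatError(f"{path}: empty XYZ file")
    return Trajectory(np.asarray(frames, dtype=float), names,
                      list(range(1, len(names) + 1)))


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a coordinate trajectory from a multi-model PDB or XYZ file.

    ``format`` is ``"pdb"`` or ``"xyz"``; when omitted it is inferred from
    the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "pdb":
        return _read_pdb(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory format {format!r} (use pdb or xyz)")


# ---------------------------------------------------------------------------
# docking-pose tables


_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})


def _norm_col(name: str) -> str:
    flat = name.replace("χ", "chi").lower()
    flat = "".join(c for c in flat if c.isalnum())
    for key in ("ranking", "rank", "receptor", "chi1", "chi2", "score"):
        if flat.startswith(key):
            return "ranking" if key == "rank" else key
    return flat


def read_pose_table(path) -> list[PoseRecord]:
    """Parse a delimited docking-pose table into :class:`PoseRecord` rows.

    The header must name ranking, receptor, chi1, chi2 and score columns
    (decorations such as units are ignored); the delimiter (comma or tab)
    is auto-detected from the header line.  Angles wrap onto [-180, 180);
    unicode minus and dash characters are normalized.  Rows keep file
    order.  A duplicate ranking within one receptor is an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [_norm_col(c) for c in df.columns]
    required = {"ranking", "receptor", "chi1", "chi2", "score"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryFormatError(
            f"{path}: missing column(s) {sorted(missing)}; header was {header!r}")

    records: list[PoseRecord] = []
    seen: set[tuple[str, int]] = set()
    for row_idx, row in df.iterrows():
        try:
            ranking = int(str(row["ranking"]).translate(_DASHES))
            chi1 = float(str(row["chi1"]).translate(_DASHES))
            chi2 = float(str(row["chi2"]).translate(_DASHES))
            score = float(str(row["score"]).translate(_DASHES))
        except (TypeError, ValueError) as exc:
            raise TrajectoryFormatError(
                f"{path}: row {row_idx}: non-numeric field ({exc})") from exc
        receptor = str(row["receptor"]).strip()
        key = (receptor, ranking)
        if key in seen:
            raise TrajectoryFormatError(
                f"{path}: row {row_idx}: duplicate ranking {ranking} "
                f"for receptor {receptor}")
        seen.add(key)
        records.append(PoseRecord(ranking, receptor, chi1, chi2, score))
    return records


# ---------------------------------------------------------------------------
# free-energy-surface text grid


def write_fes(path, fes: FreeEnergySurface) -> None:
    """Write a free-energy surface as a commented text grid.

    Header lines record the bin width, temperature, frame count and RT;
    the body has one row per chi1 bin with one Delta-G value (kcal/mol)
    per chi2 bin.  Empty bins are serialized as the token ``NA``.
    """
    with open(path, "w") as fh:
        fh.write(f"# bin_width_deg {fes.bin_width:g}\n")
        fh.write(f"# temperature_K {fes.temperature:g}\n")
        fh.write(f"# n_frames {fes.n_frames}\n")
        fh.write(f"# rt_kcal_mol {fes.rt:.12g}\n")
        for row, empty_row in zip(fes.delta_g, fes.empty_mask):
            fh.write(" ".join(
                "NA" if empty else f"{g:.6f}"
                for g, empty in zip(row, empty_row)) + "\n")


def read_fes(path) -> FreeEnergySurface:
    """Read a surface written by :func:`write_fes` (lossless to 6 decimals)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2:
                    header[parts[0]] = float(parts[1])
                continue
            try:
                rows.append([math.nan if tok == "NA" else float(tok)
                             for tok in line.split()])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}: line {lineno}: unparsable value ({exc})") from exc
    for key in ("bin_width_deg", "temperature_K", "n_frames"):
        if key not in header:
            raise TrajectoryFormatError(f"{path}: missing header line '# {key} ...'")
    bin_width = header["bin_width_deg"]
    n_bins = int(round(360.0 / bin_width))
    if len(rows) != n_bins or any(len(r) != n_bins for r in rows):
        raise TrajectoryFormatError(
            f"{path}: expected a {n_bins}x{n_bins} grid for "
            f"{bin_width:g} deg bins, got {len(rows)} rows of lengths "
            f"{sorted({len(r) for r in rows})}")
    delta_g = np.asarray(rows, dtype=float)
    return FreeEnergySurface(
        delta_g=delta_g,
        empty_mask=np.isnan(delta_g),
        bin_width=bin_width,
        temperature=header["temperature_K"],
        n_frames=int(header["n_frames"]),
        grid=None,
    )


# ---------------------------------------------------------------------------
# angle-series text


def write_angle_series(path, series: AngleSeries, precision: int = 8) -> None:
    """Write a two-column whitespace-delimited angle series with a name header."""
    with open(path, "w") as fh:
        fh.write(f"# {series.names[0]} {series.names[1]}\n")
        np.savetxt(fh, series.values, fmt=f"%.{precision}f")


def read_angle_series(path) -> AngleSeries:
    """Read a two-column angle series written by :func:`write_angle_series`."""
    path = Path(path)
    names = ("chi1", "chi2")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        toks = first[1:].split()
        if len(toks) >= 2:
            names = (toks[0], toks[1])
    values = np.loadtxt(path, comments="#")
    values = np.atleast_2d(values)
    if values.shape[1] != 2:
        raise TrajectoryFormatError(
            f"{path}: expected two columns, got {values.shape[1]}")
    return AngleSeries(values, names=names)
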