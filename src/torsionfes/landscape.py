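"""Minima and basins on the periodic free-energy surface; pose projection.

The surface lives on a torus, so every neighborhood computation wraps at
+-180 degrees.  A populated bin is a local minimum when its free energy is
less than or equal to that of every populated bin in its 8-neighborhood;
basins are assigned by steepest descent from every populated bin, with
ties broken toward the lower flat bin index so the assignment is
deterministic.  Plateaus -- connected sets of equal-energy minima -- merge
into a single minimum located at their population-weighted circular-mean
center.  Basins whose population falls below a noise floor are absorbed
into the lowest adjacent basin: with 25,000 frames a single-frame bin
would read about 6 kcal/mol of spurious depth purely from sampling noise.

Docking poses are projected onto the surface by pure geometry (the bin
containing their (chi1, chi2) pair) and classified against the basin
structure and a configurable high-energy threshold.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fes import FreeEnergySurface, bin_index
from .trajio import PoseRecord

__all__ = ["Minimum", "BasinSet", "PoseProjection", "local_minimum_mask",
           "find_minima", "project_poses", "projections_to_text"]

_NEIGHBOR_SHIFTS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0)]


@dataclass(frozen=True)
class Minimum:
    """One free-energy minimum (possibly a merged plateau)."""

    bin: tuple[int, int]
    center: tuple[float, float]  # degrees
    delta_g: float  # kcal/mol relative to the global minimum
    population_fraction: float


@dataclass(frozen=True)
class BasinSet:
    """Minima plus the per-bin basin labeling of a surface.

    ``minima`` are sorted by Delta-Delta-G ascending (ties by bin index),
    so ``minima[0]`` is the global minimum; ``basin_map[i, j]`` is the
    index into ``minima`` of the basin owning bin (i, j), or -1 for empty
    bins.
    """

    minima: tuple[Minimum, ...]
    basin_map: np.ndarray
    bin_width: float

    @property
    def global_minimum(self) -> Minimum:
        return self.minima[0]

    def to_text(self) -> str:
        lines = ["rank\tchi1_center_deg\tchi2_center_deg\tddG_kcal_mol\tbasin_fraction"]
        for rank, m in enumerate(self.minima, start=1):
            lines.append(f"{rank}\t{m.center[0]:.2f}\t{m.center[1]:.2f}"
                         f"\t{m.delta_g:.4f}\t{m.population_fraction:.6f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PoseProjection:
    """A docking pose mapped onto the surface."""

    pose: PoseRecord
    bin: tuple[int, int]
    delta_g: float  # NaN when the bin is unpopulated
    basin: int | None  # index into BasinSet.minima, None when unpopulated
    classification: str  # global-min-basin | alternative-minimum-basin | high-energy | unpopulated


def _masked_values(fes: FreeEnergySurface) -> np.ndarray:
    """Delta-G with empty bins set to +inf so they never win a comparison."""
    return np.where(fes.empty_mask, np.inf, fes.delta_g)


def local_minimum_mask(fes: FreeEnergySurface) -> np.ndarray:
    """Boolean mask of populated bins that are <= all populated 8-neighbors.

    This is the raw minimum test, before plateau merging and the basin
    population filter applied by :func:`find_minima`.
    """
    g = _masked_values(fes)
    mask = ~fes.empty_mask
    for di, dj in _NEIGHBOR_SHIFTS:
        mask &= g <= np.roll(g, (di, dj), axis=(0, 1))
    return mask


def _neighbors(i: int, j: int, n: int):
    for di, dj in _NEIGHBOR_SHIFTS:
        yield (i + di) % n, (j + dj) % n


def _circular_mean_center(bins, weights, centers, fallback):
    """Population-weighted circular mean of bin-center angles, per axis."""
    out = []
    for axis in range(2):
        ang = np.deg2rad([centers[b[axis]] for b in bins])
        c = float(np.sum(weights * np.cos(ang)))
        s = float(np.sum(weights * np.sin(ang)))
        if np.hypot(c, s) < 1e-9:  # perfectly balanced plateau: no mean direction
            out.append(fallback[axis])
        else:
            out.append(((np.degrees(np.arctan2(s, c)) + 180.0) % 360.0) - 180.0)
    return tuple(out)


def find_minima(
    fes: FreeEnergySurface,
    min_population: int = 10,
    plateau_merge: bool = True,
) -> BasinSet:
    """Identify minima and basins of a periodic free-energy surface.

    Parameters
    ----------
    fes : the surface; must have at least one populated bin.
    min_population : noise floor in frames -- basins holding fewer frames
        are absorbed into the lowest-energy adjacent basin.
    plateau_merge : report a merged plateau of equal-energy minima as one
        minimum at its population-weighted circular-mean center (otherwise
        at the plateau's lowest-index bin).
    """
    n = fes.n_bins
    g = _masked_values(fes)
    counts = fes.counts()
    populated = [(g[i, j], i * n + j) for i in range(n) for j in range(n)
                 if not fes.empty_mask[i, j]]
    if not populated:
        raise ValueError("surface has no populated bins")
    populated.sort()

    # Steepest-descent watershed: each bin drains to the neighbor (or
    # itself) with the smallest (Delta-G, flat index) key.
    sink_of: dict[int, int] = {}
    for val, flat in populated:
        i, j = divmod(flat, n)
        best = (val, flat)
        for ni, nj in _neighbors(i, j, n):
            if not fes.empty_mask[ni, nj]:
                key = (g[ni, nj], ni * n + nj)
                if key < best:
                    best = key
        sink_of[flat] = flat if best[1] == flat else sink_of[best[1]]

    basins: dict[int, list[int]] = {}
    for flat, sink in sink_of.items():
        basins.setdefault(sink, []).append(flat)

    def basin_pop(members):
        return int(sum(counts[divmod(f, n)] for f in members))

    # Absorb sub-threshold basins into the lowest adjacent basin.  An
    # isolated island (no populated neighbor outside itself) cannot be
    # absorbed and is kept.
    isolated: set[int] = set()
    while len(basins) - len(isolated) > 1:
        pops = {s: basin_pop(m) for s, m in basins.items()}
        small = sorted(s for s in basins
                       if pops[s] < min_population and s not in isolated)
        if not small:
            break
        s = small[0]
        member_set = set(basins[s])
        boundary = []
        for flat in basins[s]:
            i, j = divmod(flat, n)
            for ni, nj in _neighbors(i, j, n):
                nf = ni * n + nj
                if nf not in member_set and not fes.empty_mask[ni, nj]:
                    boundary.append((g[ni, nj], nf))
        if not boundary:
            isolated.add(s)
            continue
        target_sink = sink_of[min(boundary)[1]]
        basins[target_sink].extend(basins.pop(s))
        isolated.discard(target_sink)
        for flat in basins[target_sink]:
            sink_of[flat] = target_sink

    # Re-derive each basin's minimum as its lowest (Delta-G, index) bin.
    total = counts.sum()
    centers = -180.0 + (np.arange(n) + 0.5) * fes.bin_width
    entries = []
    for sink, members in basins.items():
        best = min((g[divmod(f, n)], f) for f in members)
        min_val, min_flat = best
        mi, mj = divmod(min_flat, n)
        # Plateau: connected equal-energy minima bins around the minimum.
        lmins = {f for f in members
                 if g[divmod(f, n)] == min_val}
        plateau = {min_flat}
        stack = [min_flat]
        while stack:
            f = stack.pop()
            fi, fj = divmod(f, n)
            for ni, nj in _neighbors(fi, fj, n):
                nf = ni * n + nj
                if nf in lmins and nf not in plateau:
                    plateau.add(nf)
                    stack.append(nf)
        if plateau_merge and len(plateau) > 1:
            pbins = sorted(divmod(f, n) for f in plateau)
            w = np.array([counts[b] for b in pbins], dtype=float)
            if w.sum() == 0:
                w = np.ones(len(pbins))
            center = _circular_mean_center(
                pbins, w / w.sum(), centers,
                (centers[mi], centers[mj]))
        else:
            center = (float(centers[mi]), float(centers[mj]))
        entries.append(((min_val, (mi, mj)), sink, center,
                        basin_pop(members) / total, members))

    entries.sort(key=lambda e: e[0])
    shift = entries[0][0][0]
    minima = []
    basin_map = np.full((n, n), -1, dtype=np.int64)
    for label, ((val, b), sink, center, frac, members) in enumerate(entries):
        minima.append(Minimum(bin=b, center=center,
                              delta_g=float(val - shift),
                              population_fraction=float(frac)))
        for f in members:
            basin_map[divmod(f, n)] = label
    return BasinSet(tuple(minima), basin_map, fes.bin_width)


def project_poses(
    fes: FreeEnergySurface,
    basins: BasinSet,
    poses: Sequence[PoseRecord],
    high_energy_threshold: float = 3.0,
) -> list[PoseProjection]:
    """Project docking poses onto the surface and classify them.

    Each pose maps to the bin containing its (chi1, chi2) pair (pure
    geometry, independent of the surface values).  Classification:
    ``unpopulated`` if the bin was never visited; ``high-energy`` if its
    free energy is at or above ``high_energy_threshold`` (kcal/mol above
    the global minimum); otherwise the pose is labeled by whether its
    basin is the global-minimum basin or an alternative one.
    """
    if basins.bin_width != fes.bin_width:
        raise ValueError("surface and basins use different bin widths")
    out = []
    for pose in poses:
        i = int(bin_index(pose.chi1, fes.bin_width))
        j = int(bin_index(pose.chi2, fes.bin_width))
        if fes.empty_mask[i, j]:
            out.append(PoseProjection(pose, (i, j), float("nan"), None,
                                      "unpopulated"))
            continue
        dg = float(fes.delta_g[i, j])
        label = int(basins.basin_map[i, j])
        if dg >= high_energy_threshold:
            cls = "high-energy"
        elif label == 0:
            cls = "global-min-basin"
        else:
            cls = "alternative-minimum-basin"
        out.append(PoseProjection(pose, (i, j), dg, label, cls))
    return out


def projections_to_text(projections: Sequence[PoseProjection]) -> str:
    """Pose table with bin, Delta-G and classification columns appended."""
    lines = ["ranking\treceptor\tchi1\tchi2\tscore\tbin_chi1\tbin_chi2"
             "\tddG_kcal_mol\tclassification"]
    for p in projections:
        dg = "NA" if np.isnan(p.delta_g) else f"{p.delta_g:.4f}"
        lines.append(f"{p.pose.ranking}\t{p.pose.receptor}\t{p.pose.chi1:g}"
                     f"\t{p.pose.chi2:g}\t{p.pose.score:g}"
                     f"\t{p.bin[0]}\t{p.bin[1]}\t{dg}\t{p.classification}")
    return "\n".join(lines) + "\n"
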