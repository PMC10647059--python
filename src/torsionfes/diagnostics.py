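"""Convergence and replica-agreement diagnostics for torsional surfaces.

Convergence is assessed the way one watches a running simulation: the
surface is recomputed on growing prefixes of the series (cumulative, not
sliding-window) and consecutive surfaces are compared.  "No significant
variation" is made operational as: the maximum absolute Delta-Delta-G
difference over co-populated bins stays within a tolerance (default
0.5 kcal/mol) AND no minimum moves by more than one bin between
checkpoints.  The run is declared converged at the first checkpoint after
which every subsequent step satisfies both conditions.

Replica agreement compares independently sampled surfaces pairwise over
bins populated in both, against an uncertainty threshold (default
1.5 kcal/mol); free energies are undefined on empty bins, so bins seen by
only one replica are counted and reported but never folded into the
metric.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .angles import AngleSeries
from .fes import FreeEnergySurface, boltzmann_invert, histogram2d_periodic
from .landscape import find_minima

__all__ = ["ConvergenceReport", "ReplicaComparison", "fes_difference",
           "convergence_trace", "compare_replicas"]


def fes_difference(a: FreeEnergySurface, b: FreeEnergySurface,
                   min_count: int = 1) -> tuple[float, int]:
    """Max |Delta-G difference| over co-populated bins, plus the number of
    bins populated in exactly one surface.

    Both surfaces are already zeroed at their own global minima, so this
    compares relative free energies.  ``min_count`` restricts the metric
    to bins holding at least that many frames in both surfaces.
    Symmetric in its arguments; zero for identical surfaces.
    """
    if a.bin_width != b.bin_width:
        raise ValueError(f"bin widths differ: {a.bin_width} vs {b.bin_width}")
    both = ~a.empty_mask & ~b.empty_mask
    exclusive = int(np.sum(a.empty_mask ^ b.empty_mask))
    if min_count > 1:
        both &= (a.counts() >= min_count) & (b.counts() >= min_count)
    if not both.any():
        return float("inf"), exclusive
    metric = float(np.max(np.abs(a.delta_g[both] - b.delta_g[both])))
    return metric, exclusive


def _minima_hausdorff_bins(mins_a, mins_b, n_bins: int) -> int:
    """Symmetric worst-case periodic Chebyshev bin distance between two
    minima sets (how far any minimum moved, appeared or disappeared)."""

    def chebyshev(p, q):
        d = []
        for axis in range(2):
            raw = abs(p[axis] - q[axis])
            d.append(min(raw, n_bins - raw))
        return max(d)

    def directed(src, dst):
        return max(min(chebyshev(s.bin, d.bin) for d in dst) for s in src)

    return max(directed(mins_a, mins_b), directed(mins_b, mins_a))


@dataclass(frozen=True)
class ConvergenceReport:
    """Evolution of the surface over trajectory prefixes."""

    checkpoints: tuple[int, ...]  # frame counts, strictly increasing
    surfaces: tuple[FreeEnergySurface, ...]
    metrics: tuple[float, ...]  # per consecutive pair, kcal/mol
    minima_drift: tuple[int, ...]  # per consecutive pair, bins
    tolerance: float
    drift_tolerance_bins: int
    converged_at: int | None  # frames, or None if never converged

    @property
    def converged(self) -> bool:
        return self.converged_at is not None

    def to_text(self) -> str:
        lines = ["checkpoint_frames\tmetric_kcal_mol\tminima_drift_bins\tconverged"]
        for k, cp in enumerate(self.checkpoints):
            metric = "NA" if k == 0 else f"{self.metrics[k - 1]:.4f}"
            drift = "NA" if k == 0 else str(self.minima_drift[k - 1])
            flag = str(self.converged_at is not None
                       and cp >= self.converged_at).lower()
            lines.append(f"{cp}\t{metric}\t{drift}\t{flag}")
        lines.append(f"# converged_at {self.converged_at}"
                     if self.converged_at is not None
                     else "# converged_at not_converged")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ReplicaComparison:
    """Pairwise agreement of independently sampled surfaces."""

    metric_matrix: np.ndarray  # (m, m) max |Delta-G diff|, kcal/mol
    exclusive_bins: np.ndarray  # (m, m) bins populated in exactly one replica
    threshold: float
    agreement: bool

    @property
    def max_metric(self) -> float:
        m = self.metric_matrix
        return float(np.max(m[~np.eye(len(m), dtype=bool)])) if len(m) > 1 else 0.0

    def to_text(self) -> str:
        m = self.metric_matrix
        lines = [f"# threshold_kcal_mol {self.threshold:g}",
                 f"# agreement {str(self.agreement).lower()}"]
        for row in m:
            lines.append("\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


def convergence_trace(
    series: AngleSeries,
    n_checkpoints: int = 10,
    tolerance: float = 0.5,
    drift_tolerance_bins: int = 1,
    bin_width: float = 15.0,
    temperature: float = 300.0,
    min_population: int = 10,
    track_below: float = 2.0,
) -> ConvergenceReport:
    """Recompute the surface on growing prefixes and test for stationarity.

    Checkpoints are equally spaced prefix lengths ending at the full
    series.  Consecutive surfaces are each zeroed at their own minimum
    before differencing.  The run is converged at the first checkpoint
    after which every later step has metric <= ``tolerance`` and no
    tracked minimum moves by more than ``drift_tolerance_bins``.

    Only thermally significant minima are tracked for drift: those within
    ``track_below`` kcal/mol of the global minimum (default 2.0, about
    3.3 RT at 300 K).  Shallow sampling-noise minima far up the surface
    appear and vanish between prefixes without saying anything about
    stationarity of the landscape.
    """
    n = len(series)
    if n < n_checkpoints:
        raise ValueError(f"series of {n} frames is shorter than "
                         f"{n_checkpoints} checkpoints")
    if n_checkpoints < 2:
        raise ValueError("need at least 2 checkpoints")
    checkpoints = tuple(int(round(n * (k + 1) / n_checkpoints))
                        for k in range(n_checkpoints))
    surfaces = tuple(
        boltzmann_invert(histogram2d_periodic(series.prefix(cp), bin_width),
                         temperature)
        for cp in checkpoints)
    minima = []
    for s in surfaces:
        all_minima = find_minima(s, min_population=min_population).minima
        tracked = tuple(m for m in all_minima if m.delta_g <= track_below)
        minima.append(tracked or all_minima[:1])
    metrics, drifts = [], []
    for k in range(1, n_checkpoints):
        metric, _ = fes_difference(surfaces[k - 1], surfaces[k])
        metrics.append(metric)
        drifts.append(_minima_hausdorff_bins(minima[k - 1], minima[k],
                                             surfaces[k].n_bins))
    bad = [k for k in range(len(metrics))
           if metrics[k] > tolerance or drifts[k] > drift_tolerance_bins]
    if bad and bad[-1] == len(metrics) - 1:
        converged_at = None
    elif bad:
        converged_at = checkpoints[bad[-1] + 1]
    else:
        converged_at = checkpoints[0]
    return ConvergenceReport(checkpoints, surfaces, tuple(metrics),
                             tuple(drifts), tolerance, drift_tolerance_bins,
                             converged_at)


def compare_replicas(
    replicas: Sequence[AngleSeries | FreeEnergySurface],
    threshold: float = 1.5,
    bin_width: float = 15.0,
    temperature: float = 300.0,
    min_count: int = 1,
) -> ReplicaComparison:
    """Pairwise surface agreement across independent replicas.

    ``replicas`` may mix angle series (converted to surfaces here) and
    ready surfaces on the same grid.  Agreement requires every pairwise
    metric to be at or below ``threshold`` kcal/mol.  Permutation
    invariant and symmetric.
    """
    if len(replicas) < 2:
        raise ValueError("need at least two replicas to compare")
    surfaces = []
    for rep in replicas:
        if isinstance(rep, AngleSeries):
            surfaces.append(boltzmann_invert(
                histogram2d_periodic(rep, bin_width), temperature))
        else:
            surfaces.append(rep)
    widths = {s.bin_width for s in surfaces}
    if len(widths) != 1:
        raise ValueError(f"replicas use different bin widths: {sorted(widths)}")
    m = len(surfaces)
    metric = np.zeros((m, m))
    excl = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i + 1, m):
            d, e = fes_difference(surfaces[i], surfaces[j], min_count=min_count)
            metric[i, j] = metric[j, i] = d
            excl[i, j] = excl[j, i] = e
    off = metric[~np.eye(m, dtype=bool)]
    return ReplicaComparison(metric, excl, threshold,
                             bool(np.all(off <= threshold)))
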