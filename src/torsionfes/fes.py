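"""Periodic 2D histogramming of torsion pairs and Boltzmann inversion.

The conformational space spanned by two torsions, each on [-180, 180), is
divided into square bins (15 degrees by default, giving a 24x24 grid that
wraps at the edges).  The occurrence N_i of each bin over N frames turns
into a relative free energy by Boltzmann inversion::

    Delta-G_i = -RT ln(N_i / N)

with RT the molar gas constant times the temperature (0.59616 kcal/mol at
300 K).  The minimum over populated bins is subtracted so the global
minimum reads exactly 0; bins never visited carry no finite free energy
and are flagged instead of being assigned a pseudo-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import AngleSeries, wrap_angle
from .constants import thermal_energy

__all__ = ["PeriodicGrid2D", "FreeEnergySurface",
           "histogram2d_periodic", "boltzmann_invert"]


@dataclass(frozen=True)
class PeriodicGrid2D:
    """Bin counts on the wrap-around torsion grid.

    ``counts[i, j]`` is the number of frames with chi1 in bin i and chi2 in
    bin j, where bin j covers ``[-180 + j*w, -180 + (j+1)*w)``.
    """

    counts: np.ndarray
    bin_width: float = 15.0

    def __post_init__(self):
        counts = np.asarray(self.counts)
        n_bins = _n_bins(self.bin_width)
        if counts.shape != (n_bins, n_bins):
            raise ValueError(f"counts must be {n_bins}x{n_bins} for "
                             f"{self.bin_width:g} deg bins, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("bin counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        """N, the total number of frames histogrammed."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class FreeEnergySurface:
    """Relative free energy per bin, kcal/mol, with empty bins masked.

    ``delta_g`` is NaN wherever ``empty_mask`` is True; over populated bins
    its minimum is exactly 0.
    """

    delta_g: np.ndarray
    empty_mask: np.ndarray
    bin_width: float
    temperature: float
    n_frames: int
    grid: PeriodicGrid2D | None = None

    @property
    def rt(self) -> float:
        return thermal_energy(self.temperature)

    @property
    def n_bins(self) -> int:
        return self.delta_g.shape[0]

    def counts(self) -> np.ndarray:
        """Bin counts: exact when the source grid is attached, otherwise
        reconstructed from the surface by re-exponentiation (rounded)."""
        if self.grid is not None:
            return self.grid.counts
        w = np.where(self.empty_mask, 0.0, np.exp(-np.nan_to_num(self.delta_g) / self.rt))
        return np.rint(self.n_frames * w / w.sum()).astype(np.int64)


def _n_bins(bin_width: float) -> int:
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin width {bin_width:g} deg does not divide 360")
    return int(round(360.0 / bin_width))


def bin_index(angles, bin_width: float = 15.0) -> np.ndarray:
    """Map angles in degrees to bin indices by floor((wrap(a) + 180) / w).

    +180 wraps to -180 before binning, so a value at the upper edge lands
    in bin 0, and a value exactly on an interior edge lands in the bin that
    starts there (left-closed convention).
    """
    n_bins = _n_bins(bin_width)
    idx = np.floor((wrap_angle(angles) + 180.0) / bin_width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def histogram2d_periodic(series, bin_width: float = 15.0) -> PeriodicGrid2D:
    """Histogram a (chi1, chi2) series on the periodic grid.

    ``series`` may be an :class:`AngleSeries` or any (n, 2) array of
    degrees.  Every frame lands in exactly one bin; the grid total equals
    the number of frames.
    """
    values = series.values if isinstance(series, AngleSeries) else np.asarray(series, float)
    if values.ndim != 2 or values.shape[1] != 2 or values.shape[0] < 1:
        raise ValueError(f"need a non-empty (n, 2) series, got shape {values.shape}")
    n_bins = _n_bins(bin_width)
    i = bin_index(values[:, 0], bin_width)
    j = bin_index(values[:, 1], bin_width)
    counts = np.bincount(i * n_bins + j, minlength=n_bins * n_bins)
    return PeriodicGrid2D(counts.reshape(n_bins, n_bins), bin_width)


def boltzmann_invert(
    grid: PeriodicGrid2D,
    temperature: float = 300.0,
    pseudocount: float = 0.0,
) -> FreeEnergySurface:
    """Invert bin occupancies into a relative free-energy surface.

    For every populated bin, ``Delta-G_i = -RT ln(N_i / N)`` with RT from
    ``temperature``; the surface is then shifted so its minimum over
    populated bins is 0.  Empty bins are flagged, not assigned a number,
    unless ``pseudocount`` > 0 adds that many virtual counts to every bin
    (off by default).
    """
    rt = thermal_energy(temperature)
    if grid.total < 1:
        raise ValueError("cannot invert an empty histogram")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    counts = grid.counts + pseudocount
    total = counts.sum()
    empty = counts == 0
    with np.errstate(divide="ignore"):
        delta_g = -rt * np.log(counts / total)
    delta_g = np.where(empty, np.nan, delta_g)
    delta_g -= np.nanmin(delta_g)
    return FreeEnergySurface(
        delta_g=delta_g, empty_mask=empty, bin_width=grid.bin_width,
        temperature=temperature, n_frames=grid.total, grid=grid)
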