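"""Shared angle conventions and the per-frame torsion time series container.

All angles are exchanged in degrees on the half-open interval [-180, 180):
-180 is included, +180 is excluded, so every torsion has exactly one
representation and 15-degree bins tile the circle exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["wrap_angle", "AngleSeries"]


def wrap_angle(angle):
    """Wrap angle(s) in degrees onto [-180, 180).

    Accepts scalars or arrays; +180 maps to -180.
    """
    return ((np.asarray(angle, dtype=float) + 180.0) % 360.0) - 180.0


@dataclass
class AngleSeries:
    """Per-frame (chi1, chi2) torsion values in degrees.

    Attributes
    ----------
    values : (n_frames, 2) float array on [-180, 180); column 0 is chi1,
        column 1 is chi2.
    names : labels of the two torsions, default ``("chi1", "chi2")``.
    frame_spacing : spacing between stored frames in arbitrary time units;
        metadata only, never used in computation.
    """

    values: np.ndarray
    names: tuple[str, str] = ("chi1", "chi2")
    frame_spacing: float = 1.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ValueError(f"values must have shape (n, 2), got {values.shape}")
        if values.shape[0] < 1:
            raise ValueError("an AngleSeries needs at least one frame")
        object.__setattr__(self, "values", wrap_angle(values))

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def chi1(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def chi2(self) -> np.ndarray:
        return self.values[:, 1]

    def prefix(self, n_frames: int) -> "AngleSeries":
        """First ``n_frames`` frames as a new series (shares no state)."""
        if not 1 <= n_frames <= len(self):
            raise ValueError(f"prefix length {n_frames} outside [1, {len(self)}]")
        return AngleSeries(self.values[:n_frames].copy(), self.names, self.frame_spacing)
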