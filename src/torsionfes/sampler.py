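"""Metropolis sampling of torsion pairs on the flat torus.

The sampler draws a single Markov chain whose stationary density is the
Boltzmann distribution ``p(chi1, chi2) proportional to exp(-U/RT)`` of a
:class:`~torsionfes.potential.SyntheticPotential`.  Proposals are uniform
offsets in ``[-step, step]^2`` wrapped onto the torus, accepted with the
standard Metropolis probability ``min(1, exp(-dU/RT))`` -- the simplest
scheme with a provable stationary law, standing in statistically for the
molecular-dynamics engine that produced the original trajectories.

A ``drift`` option translates all well centers linearly over the run,
yielding a deliberately non-stationary chain used as the negative control
in convergence diagnostics.

The inner loop is compiled with numba when available; the pure-Python
fallback runs the identical algorithm on the identical pre-generated
random streams.
"""
from __future__ import annotations

import math

import numpy as np

from .angles import AngleSeries, wrap_angle
from .potential import SyntheticPotential

__all__ = ["sample_torus"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _metropolis_kernel(n_frames, x1, x2, centers, kappas, depths, rt,
                       drift1, drift2, prop, urand, out):  # pragma: no cover
    n_wells = depths.shape[0]
    deg = math.pi / 180.0
    for i in range(n_frames):
        y1 = ((x1 + prop[i, 0] + 180.0) % 360.0) - 180.0
        y2 = ((x2 + prop[i, 1] + 180.0) % 360.0) - 180.0
        du = 0.0
        for k in range(n_wells):
            c1 = centers[k, 0] + drift1 * i
            c2 = centers[k, 1] + drift2 * i
            wx = math.exp(kappas[k, 0] * (math.cos((x1 - c1) * deg) - 1.0)
                          + kappas[k, 1] * (math.cos((x2 - c2) * deg) - 1.0))
            wy = math.exp(kappas[k, 0] * (math.cos((y1 - c1) * deg) - 1.0)
                          + kappas[k, 1] * (math.cos((y2 - c2) * deg) - 1.0))
            du -= depths[k] * (wy - wx)
        if du <= 0.0 or urand[i] < math.exp(-du / rt):
            x1 = y1
            x2 = y2
        out[i, 0] = x1
        out[i, 1] = x2


def sample_torus(
    potential: SyntheticPotential,
    n_frames: int = 25_000,
    step_deg: float = 60.0,
    seed: int | None = None,
    drift: tuple[float, float] | None = None,
) -> AngleSeries:
    """Sample ``n_frames`` (chi1, chi2) frames from the potential's Boltzmann law.

    Parameters
    ----------
    potential : the target potential; its ``temperature`` sets RT.
    n_frames : number of stored frames (every Metropolis step is stored).
        Default 25,000, the frame count of the trajectories this sampler
        emulates.
    step_deg : half-width of the uniform proposal, degrees.
    seed : fixes the chain exactly; the same seed reproduces the series
        bit for bit.
    drift : optional (deg/frame, deg/frame) linear translation applied to
        every well center over the run; makes the chain non-stationary.

    Returns
    -------
    AngleSeries of length ``n_frames`` on [-180, 180).
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    if step_deg <= 0:
        raise ValueError(f"step_deg must be > 0, got {step_deg}")
    rt = potential.rt

    rng = np.random.default_rng(seed)
    if potential.wells:
        # start in the deepest well, as a simulation started from a docked
        # configuration would: no burn-in transient through the flat field
        deepest = max(potential.wells, key=lambda w: w.depth)
        start = np.asarray(wrap_angle(deepest.center), dtype=float)
    else:
        start = rng.uniform(-180.0, 180.0, size=2)
    prop = rng.uniform(-step_deg, step_deg, size=(n_frames, 2))
    urand = rng.uniform(0.0, 1.0, size=n_frames)

    n_wells = len(potential.wells)
    centers = np.zeros((n_wells, 2))
    kappas = np.zeros((n_wells, 2))
    depths = np.zeros(n_wells)
    for k, well in enumerate(potential.wells):
        centers[k] = well.center
        kappas[k] = well.kappa
        depths[k] = well.depth
    d1, d2 = (0.0, 0.0) if drift is None else (float(drift[0]), float(drift[1]))

    out = np.empty((n_frames, 2))
    _metropolis_kernel(n_frames, float(start[0]), float(start[1]),
                       centers, kappas, depths, rt, d1, d2, prop, urand, out)
    return AngleSeries(out)
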