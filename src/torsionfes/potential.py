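"""Analytic multi-well periodic potentials on the (chi1, chi2) torus.

These potentials play the role of a ground truth: their Boltzmann weights
define a stationary distribution that the Metropolis sampler targets, and
their tabulated values on the histogram grid give a reference free-energy
surface against which the reconstruction pipeline can be validated
bin-for-bin.

Each well is a periodic bump -- a product of von-Mises-shaped factors, one
per axis::

    w_k(chi1, chi2) = exp(kappa1 * (cos(chi1 - c1) - 1))
                    * exp(kappa2 * (cos(chi2 - c2) - 1))

which equals 1 exactly at the well center (c1, c2), decays with angular
distance at a rate set by the concentrations kappa, and is 360-degree
periodic by construction (no truncation of wrapped Gaussian tails).  The
full potential is ``U = baseline - sum_k depth_k * w_k``, so ``depth`` is
the energy gained at the center of an isolated well, in kcal/mol.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import thermal_energy

__all__ = ["Well", "SyntheticPotential", "build_potential", "bin_centers",
           "load_potential_config"]


def bin_centers(bin_width: float = 15.0) -> np.ndarray:
    """Centers of the periodic bins on [-180, 180) for the given width."""
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360")
    n = int(round(360.0 / bin_width))
    return -180.0 + (np.arange(n) + 0.5) * bin_width


@dataclass(frozen=True)
class Well:
    """One periodic attractive well.

    center : (chi1, chi2) in degrees.
    kappa : per-axis concentration (unitless, >= 0); larger is narrower.
    depth : well depth in kcal/mol (>= 0).
    """

    center: tuple[float, float]
    kappa: tuple[float, float]
    depth: float

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError(f"well depth must be >= 0 kcal/mol, got {self.depth}")
        if any(k < 0 for k in self.kappa):
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")

    def weight(self, chi1, chi2) -> np.ndarray:
        d1 = np.deg2rad(np.asarray(chi1, dtype=float) - self.center[0])
        d2 = np.deg2rad(np.asarray(chi2, dtype=float) - self.center[1])
        return np.exp(self.kappa[0] * (np.cos(d1) - 1.0)
                      + self.kappa[1] * (np.cos(d2) - 1.0))


@dataclass(frozen=True)
class SyntheticPotential:
    """Multi-well periodic potential with a known reference FES.

    The potential is exactly 360-degree periodic in both torsions.  Its
    stationary Boltzmann density at ``temperature`` is
    ``p(chi1, chi2) proportional to exp(-U/RT)``.
    """

    wells: tuple[Well, ...]
    baseline: float = 0.0
    temperature: float = 300.0

    def __post_init__(self):
        thermal_energy(self.temperature)  # validates > 0

    @property
    def rt(self) -> float:
        return thermal_energy(self.temperature)

    def energy(self, chi1, chi2) -> np.ndarray:
        """U(chi1, chi2) in kcal/mol; broadcasts over array inputs."""
        u = np.full(np.broadcast(np.asarray(chi1, float),
                                 np.asarray(chi2, float)).shape,
                    self.baseline, dtype=float)
        for well in self.wells:
            u -= well.depth * well.weight(chi1, chi2)
        return u

    __call__ = energy

    def tabulate(self, bin_width: float = 15.0) -> np.ndarray:
        """U evaluated at every bin center; shape (n_bins, n_bins), axis 0 chi1."""
        c = bin_centers(bin_width)
        return self.energy(c[:, None], c[None, :])

    def reference_fes(self, bin_width: float = 15.0) -> np.ndarray:
        """Tabulated potential minus its grid minimum (non-negative everywhere).

        This is the analytic surface the histogram/Boltzmann-inversion
        pipeline should recover in the limit of exhaustive sampling, up to
        the within-bin averaging of the Boltzmann weight.
        """
        u = self.tabulate(bin_width)
        return u - u.min()

    def bin_probabilities(self, bin_width: float = 15.0) -> np.ndarray:
        """Stationary bin probabilities from the bin-center Boltzmann weights."""
        u = self.tabulate(bin_width)
        w = np.exp(-(u - u.min()) / self.rt)
        return w / w.sum()


def build_potential(
    wells: Sequence[tuple],
    baseline: float = 0.0,
    temperature: float = 300.0,
) -> SyntheticPotential:
    """Construct a :class:`SyntheticPotential` from plain well tuples.

    Parameters
    ----------
    wells : sequence of ``(center, kappa, depth)`` where ``center`` is a
        (chi1, chi2) pair in degrees, ``kappa`` a scalar (isotropic) or a
        per-axis pair of concentrations, and ``depth`` the well depth in
        kcal/mol.  An empty sequence gives a flat potential.
    baseline : constant offset in kcal/mol (irrelevant to sampling).
    temperature : simulation temperature in kelvin.
    """
    parsed = []
    for spec in wells:
        center, kappa, depth = spec
        if np.isscalar(kappa):
            kappa = (float(kappa), float(kappa))
        parsed.append(Well(center=(float(center[0]), float(center[1])),
                           kappa=(float(kappa[0]), float(kappa[1])),
                           depth=float(depth)))
    return SyntheticPotential(wells=tuple(parsed), baseline=float(baseline),
                              temperature=float(temperature))


def load_potential_config(path) -> tuple[SyntheticPotential, dict]:
    """Read a flat key-value potential configuration file.

    Lines are ``key = value``; ``#`` starts a comment.  The ``well`` key
    may repeat; its value is ``chi1, chi2, kappa, depth`` (isotropic) or
    ``chi1, chi2, kappa1, kappa2, depth``.  Recognized scalar keys are
    ``temperature``, ``baseline``, ``seed``, ``frames``, ``step``,
    ``drift_chi1``, ``drift_chi2``.

    Returns the potential and a dict of the sampler-related extras
    (``seed``, ``frames``, ``step``, ``drift``).
    """
    wells, scalars = [], {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value', "
                                 f"got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip().lower()
            if key == "well":
                parts = [float(v) for v in value.replace(",", " ").split()]
                if len(parts) == 4:
                    wells.append(((parts[0], parts[1]), parts[2], parts[3]))
                elif len(parts) == 5:
                    wells.append(((parts[0], parts[1]),
                                  (parts[2], parts[3]), parts[4]))
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: well needs 4 or 5 numbers, "
                        f"got {len(parts)}")
            else:
                scalars[key] = float(value)
    potential = build_potential(
        wells,
        baseline=scalars.get("baseline", 0.0),
        temperature=scalars.get("temperature", 300.0))
    drift = None
    if "drift_chi1" in scalars or "drift_chi2" in scalars:
        drift = (scalars.get("drift_chi1", 0.0), scalars.get("drift_chi2", 0.0))
    extras = {
        "seed": int(scalars["seed"]) if "seed" in scalars else None,
        "frames": int(scalars.get("frames", 25_000)),
        "step": scalars.get("step", 60.0),
        "drift": drift,
    }
    return potential, extras
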