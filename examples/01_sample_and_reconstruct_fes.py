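"""Sample a two-well torsional potential and reconstruct its free-energy surface.

Builds a potential whose two well minima differ by exactly 1.0 kcal/mol,
draws 200,000 Metropolis frames from its Boltzmann distribution, histograms
them on the 15-degree periodic grid and Boltzmann-inverts the counts.  The
recovered minima should sit in the well-center bins with a free-energy gap
close to the constructed 1.0 kcal/mol.
"""
import numpy as np

from torsionfes import (boltzmann_invert, build_potential, find_minima,
                        histogram2d_periodic, sample_torus)

potential = build_potential(
    wells=[((-52.5, -7.5), 6.0, 3.0),   # deep well: 3.0 kcal/mol
           ((127.5, 172.5), 6.0, 2.0)],  # shallow well: 2.0 kcal/mol
    temperature=300.0)

series = sample_torus(potential, n_frames=200_000, seed=42)
fes = boltzmann_invert(histogram2d_periodic(series, bin_width=15.0),
                       temperature=300.0)
basins = find_minima(fes, min_population=10)

print(f"sampled frames           : {len(series)}")
print(f"populated bins           : {int((~fes.empty_mask).sum())} / 576")
for rank, m in enumerate(basins.minima[:3], start=1):
    print(f"minimum {rank}: bin {m.bin}  center ({m.center[0]:7.1f}, "
          f"{m.center[1]:7.1f}) deg  ddG = {m.delta_g:5.2f} kcal/mol  "
          f"basin fraction {m.population_fraction:.3f}")
gap = basins.minima[1].delta_g
print(f"\nrecovered well gap {gap:.3f} kcal/mol vs 1.0 constructed "
      f"(|error| = {abs(gap - 1.0):.3f})")
# The gap is the Boltzmann-inverted population ratio of the two basins'
# lowest bins; at 2e5 frames it fluctuates by a few hundredths of kcal/mol.
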