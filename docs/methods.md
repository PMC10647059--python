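# Methods

## The estimator

The observable is a per-frame pair of side-chain torsions (χ1, χ2), each
on the half-open interval [−180°, 180°); +180° is identified with −180°
so every angle has one representation and bins tile the circle exactly.
The conformational space is a flat torus: all neighborhood and distance
computations wrap at the edges.

Frames are histogrammed on a square periodic grid.  The default bin width
is 15° (24×24 = 576 bins); any width dividing 360° is accepted.  Binning
is left-closed/right-open anchored at −180°: a frame at an interior bin
edge belongs to the bin that starts there, and a frame at ±180° lands in
bin 0.  Bin counts N_i over N frames are Boltzmann-inverted into a
relative free energy per bin,

    ΔG_i = −RT ln(N_i / N),    RT = R·T,  R = 1.987204259×10⁻³ kcal/(mol·K),

and the minimum over populated bins is subtracted, so the global minimum
reads exactly 0 and only relative energies (ΔΔG) are ever reported.  At
the default T = 300 K, RT = 0.59616 kcal/mol.

Empty bins are flagged as undefined rather than given a capped or
pseudo-count value: −RT ln 0 is not a measurement, and every downstream
comparison is restricted to populated bins.  A `pseudocount` option (add ε
frames to every bin) exists for users who want a fully populated surface,
but it is off by default and nothing in the package depends on it.

This is the plain histogram estimator for unbiased sampling.  No kernel
smoothing, reweighting, or biased-sampling correction is applied anywhere.

## Minima, basins, poses

A populated bin is a local minimum when its ΔG is less than or equal to
that of every populated bin in its 8-neighborhood with periodic wrap.
Basins are assigned by a steepest-descent watershed: bins are processed in
ascending (ΔG, flat-index) order and each drains to the neighbor (or
itself) with the smallest such key.  The flat-index component makes every
tie-break deterministic and lets connected equal-ΔG plateaus coalesce into
a single basin whose reported minimum, when plateau merging is on, sits at
the population-weighted circular mean of the plateau's bin centers (for a
perfectly balanced plateau with no mean direction, at the plateau's
lowest-index bin; a uniform surface therefore collapses to one basin
covering everything).

Sampling noise creates shallow spurious minima: with N = 25,000 frames a
single-frame bin reads about RT·ln(25,000) ≈ 6 kcal/mol above the global
minimum purely from counting statistics.  Basins holding fewer than
`min_population` frames (default 10) are therefore absorbed into the basin
of the lowest-ΔG populated bin adjacent to them, repeating until every
remaining basin passes or only one remains; a sub-threshold basin with no
populated neighbor at all (an isolated island) cannot be absorbed and is
kept.  The default floor is calibrated to the 25,000-frame scale and is
deliberately conservative — at much larger N, clusters of moderately
populated bins in rarely visited regions can still appear as shallow
minima several kcal/mol up; consumers that only care about the principal
minima should filter on ΔΔG or population fraction.

Docking poses are projected by pure geometry: the pose's wrapped (χ1, χ2)
maps to its containing bin, independent of the surface values and
invariant to adding 360°.  The projection reports that bin's ΔΔG and basin
and one of four labels: `global-min-basin`, `alternative-minimum-basin`,
`high-energy` (ΔΔG at or above a configurable threshold, default
3.0 kcal/mol), or `unpopulated`.  Energy barriers between basins are not
computed; the basin map says which minimum a state drains to, not how
high the ridge between basins is.

## Convergence and replicas

Convergence is tested prefix-wise, mirroring how one watches a running
simulation: the FES is recomputed on 10 equally spaced cumulative
prefixes, each independently re-zeroed, and consecutive surfaces are
compared by the maximum |ΔΔG difference| over co-populated bins.  "No
significant variation" is operationalized as that metric staying at or
below a tolerance (default 0.5 kcal/mol) while no tracked minimum moves by
more than one bin (symmetric worst-case periodic Chebyshev distance
between the consecutive minima sets); the run is declared converged at the
first checkpoint after which every later step satisfies both.  Tracked
minima are those within `track_below` = 2.0 kcal/mol (≈ 3.3 RT) of the
global minimum: shallow noise minima high up the surface appear and vanish
between prefixes without bearing on stationarity of the landscape, and
including them makes the drift term pure noise.

Replica agreement compares surfaces pairwise by the same co-populated
maximum-difference metric against a threshold, default 1.5 kcal/mol, the
conventional uncertainty limit for this kind of analysis; the threshold is
user-configurable since it is a convention, not a derived quantity.  Bins
populated in only one replica are counted and reported but never folded
into the metric, because ΔG is undefined where a replica has no frames.
Comparisons optionally restrict to bins with at least `min_count` frames
in both surfaces; diagnostics-grade comparisons here use 200 counts, at
which per-bin noise is RT/√200 ≈ 0.04 kcal/mol.

## The synthetic generator

The generator provides ground truth, not physics.  A potential is a sum of
attractive periodic wells on the torus,

    U(χ1, χ2) = baseline − Σ_k depth_k · exp(κ₁ₖ(cos(χ1−c₁ₖ)−1)) · exp(κ₂ₖ(cos(χ2−c₂ₖ)−1)),

a product of von-Mises-shaped bumps per axis: exactly 360°-periodic with
no wrapped-Gaussian truncation, equal to 1 at the well center, with
per-axis concentrations κ (unitless; larger is narrower) and depths in
kcal/mol.  Tabulating U at the 576 bin centers and subtracting the minimum
gives the analytic reference FES that the reconstruction should recover.

Sampling is a single-chain Metropolis random walk: uniform proposals in
[−step, step]² wrapped onto the torus, accepted with min(1, e^(−ΔU/RT)).
This is the simplest sampler with a provably correct stationary law — it
stands in statistically for a molecular-dynamics engine, with no force
field, solvent, thermostat or inertia.  Defaults: 25,000 frames (the frame
count of the trajectories this emulates; "frame" is the time unit, as no
physical save interval is modelled), step 60° (a few bins per move, enough
to cross between basins regularly), T = 300 K.  The chain starts at the
deepest well center — as a simulation started from a docked configuration
would — so there is no burn-in transient scattering stray frames across
the empty field; for a flat (well-free) potential the start is uniform
random.  A fixed seed reproduces a series bit for bit.  The inner loop is
numba-compiled, with a pure-Python fallback running the identical
algorithm on the identical pre-generated random streams.

Two deliberate caveats about what passing tests show.  First, successive
Metropolis frames are correlated (as are saved MD frames); the flat-
potential uniformity check therefore uses step = 180°, which makes
proposals globally uniform and the flat-potential chain i.i.d. — the exact
multinomial regime that check assumes.  Second, the reconstructed bin
value estimates −RT ln of the bin-integrated Boltzmann weight, while the
reference is U at the bin center; for the default well shapes this
within-bin averaging biases recovered gaps by a few hundredths of a
kcal/mol, well inside the tolerances used.  Real trajectories additionally
feature multi-state kinetics, anisotropic wells and slow orthogonal
degrees of freedom that this generator does not emulate: passing the
synthetic suite validates the estimator and diagnostics, not any claim
about a particular molecular system.

The drifting-well variant translates all well centers linearly over the
run (configurable deg/frame per axis).  It is the non-stationary negative
control: its cumulative-prefix FES keeps changing, so convergence must
not be declared.

Coordinate realization places the five atoms N, CA, CB, CG, CD1 of a
minimal tryptophan-like fragment by standard internal-to-Cartesian
construction (natural-extension reference frame).  Bond lengths (1.5 Å)
and angles (111°) are arbitrary but fixed — only the torsions carry
information — and re-extracting the torsions from the coordinates
reproduces the requested series to better than 1e−6°, also after a file
round trip up to the documented coordinate precision (3 decimals for PDB,
6 for XYZ).

## Numerical conventions and degenerate inputs

- Dihedrals use the atan2 formulation (stable near ±90°) with the IUPAC
  sign convention; reversing the atom order preserves the angle, mirroring
  the geometry negates it.  A cross-product norm below 1e−10 (collinear
  triple) is a geometry error, never a silent 0.
- Angles are degrees everywhere in APIs and files; radians exist only
  inside trig calls.
- All readers reject malformed input with a located error (frame, line or
  row); none repairs silently.  First altloc wins in PDB input, with a
  warning.
- An all-empty histogram cannot be inverted; a single populated bin yields
  a surface that is 0 there and masked elsewhere.
- FES text files store 6 decimals; write-then-read agrees to 1e−6 and
  preserves the empty-bin mask (token `NA`).

## Problem sizes

The validation suite samples 5×10⁵ frames where recovery accuracy is
asserted (max |ΔΔG| deviation < 0.25 kcal/mol over bins with ≥ 200
counts), 2×10⁵ frames for the drifting-well controls, and 25,000 — the
emulated trajectories' own frame count — where the defaults are the point.
The full test suite runs in well under a minute on one CPU after JIT
warm-up; `scripts/acceptance.py` takes about 15 seconds.
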