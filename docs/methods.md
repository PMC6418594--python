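# Methods

This note documents the models, estimators, conventions and numerical
choices behind each analysis stage, and what the synthetic fixtures do and
do not demonstrate.

## Units, geometry and conventions

Lengths are Å, times ns, angles degrees. Diffusion coefficients are
reported in 10⁻¹² m²/s; the single conversion constant
1 × 10⁻¹² m²/s = 0.01 Å²/ns lives in `synthetic.D_UNIT_IN_A2_PER_NS` and is
applied in exactly two places (the Brownian generator and the Einstein-fit
reporter), so no double conversion is possible.

Boxes are orthorhombic only; triclinic input raises an explicit
unsupported-format error. Indices are 0-based internally; group files
declare an `index_base` (default 0) so 1-based lists can be imported
without silent off-by-one errors. Centers of mass are mass-weighted when
masses are available and uniform otherwise.

The bilayer normal is fixed to +z — the planar-bilayer convention — rather
than estimated from lipid positions. The bilayer center is z = 0 in every
axial observable.

Unwrapping accumulates per-frame minimum-image displacements, the standard
convention, valid while particles move less than half a box length between
stored frames; a displacement reaching half the box emits an
`UnwrapAmbiguityWarning` naming frame and particle. Unwrap/re-wrap
round-trips are exact to ~1e-9 Å (floating-point accumulation over frames),
not bitwise.

## Lateral diffusion

The MSD uses all time origins (an FFT-based algorithm, verified in the
tests against a brute-force double loop to 1e-10 Å²) and subtracts the
reference-group COM motion first, which removes collective drift exactly in
real arithmetic and to ≲1e-9 Å² in floats. The reference for additive
molecules is the lipid ensemble — the same reference used for the lipids
themselves — so both species are measured in the same frame.

The Einstein fit is ordinary least squares on MSD(t) over a window of
10–50% of the maximum lag by default. The short-lag region is excluded
because it is not yet diffusive in real systems; the long-lag half is
excluded because few origin pairs make it noisy. Uncertainty is quoted as
three times the standard error of the mean over 5 contiguous trajectory
blocks. (Three standard deviations of a raw per-molecule spread would be
far larger than any useful band at these ensemble sizes; the block
convention is recorded in the estimate's metadata.)

Self-referencing a group of N walkers biases its MSD slope by the factor
(1 − 1/N): subtracting the ensemble's own COM removes one collective degree
of freedom. For 288 lipids this is 0.35% and invisible; for the 6-walker
additive ensemble it would be 17%, which is why the additive branch uses
the lipid COM as reference.

## Pair correlation

g(r) histograms minimum-image pair distances and normalizes per frame by
the ideal-gas expectation — shell volume 4πr²dr and number density per Å³
in 3D, shell area 2πr·dr and density per Å² in lateral mode (xy distances
only). COR–COR analyses default to lateral: trans-bilayer molecules share a
z-band, and in-plane clustering is the observable of interest. Terminal
contact analyses default to 3D, since contacts are genuinely
three-dimensional. Defaults: dr = 0.2 Å, r_max = 30 Å, covering the
expected trimer structure (~7 and ~12 Å spacings) with margin.

Intra-molecular pairs are excluded whenever both point sets index the same
molecules (self-pairs always; same-index cross pairs on request), because a
molecule's own CH3–CF3 separation would contaminate the intermolecular
structure.

Peak detection smooths g(r) with a 5-bin moving average and scans for local
maxima above a prominence floor (default 0.1). An optional minimum
pair-count support (`min_count`) discards peaks whose smoothed raw count is
below a floor: at small r the shell measure is tiny, so a single chance
pair among few molecules produces a spurious g spike of arbitrary height.
The recovery studies use min_count = 50, i.e. a reported peak must be
supported by at least ~50 observed pairs; the genuine structural peaks in
those fixtures carry hundreds. The first-shell boundary (`first_minimum`)
is the lowest smoothed value between the first two peaks.

## Orientation and axial structure

Backbone angles use v1 = end_a − COR and v2 = end_b − COR with minimum
image applied to both vectors. α1 and α2 are both measured against +z, so a
straight trans-bilayer rod gives α1 = 0°, α2 = 180°, and the bending angle
β = 180° means unbent; this sign convention is what makes β a true bend
angle. Side-chain angles are measured between (COR − terminal) and +z:
0° puts the terminal straight below its ring, 90° in the bilayer plane.

Angle histograms are normalized to unit area over [0, 180]° (2° bins by
default); z-profiles to unit area over ±34 Å (1 Å bins, centers at integer
multiples of the bin width so a plane at an exact multiple lands mid-bin).
Profiles are referenced to the COM of a chosen group — the whole system by
default, the lipid set as an option. Bilayer thickness is the peak-to-peak
distance between the upper- and lower-leaflet density maxima. Flip events
of a terminal's z-series require reaching the opposite band beyond
±threshold (default 10 Å, midway between the bilayer center and the
headgroup planes at ±20 Å); midplane excursions that return do not count.

## Cluster kinetics

Molecules are adjacent when their COR minimum-image distance (lateral by
default, matching the RDF convention) is within the cutoff; clusters are
connected components, labelled deterministically by lowest member index.
The default cutoff is the first minimum of the trajectory's own COR–COR
g(r), with 9.5 Å — the midpoint between the ~7 Å nearest-neighbor and
~12 Å second-neighbor trimer spacings — as fallback.

The characteristic timescale of the trimer indicator is the lag at which
its normalized autocovariance first crosses 1/e, with linear interpolation
between the bracketing lags. The published "characteristic timescale" of
such transient aggregates rarely comes with a stated estimator; the
e-folding definition was chosen because it is parameter-free, matches the
exact exponential autocorrelation of a two-state Markov process, and is
validated here against that ground truth. Mean on/off dwell times are
available as secondary outputs (`dwell_times`), and membership-exchange
events of the large cluster as `exchange_events`.

## Synthetic fixtures: what they emulate

* **Brownian walkers** — ideal 2D diffusion at the published lipid and
  additive diffusivities (13.9 and 10.7 × 10⁻¹² m²/s at 335 K), 288 + 6
  particles in a 98 Å cell, 9800 frames × 0.1 ns (≈ 1 μs observed at the
  analysis frame rate). No interactions, no subdiffusive short-time regime,
  no hydrodynamics — so recovery demonstrates estimator correctness, not
  force-field physics.
* **Trimer triangles** — an isosceles 7/7/12 Å triangle per frame with
  0.5 Å Gaussian jitter plus dispersed molecules, reproducing the two-peak
  structure of a clustered g(r).
* **Contact pairs** — point pairs at the CH3 (3 Å) and CF3 (5 Å) contact
  spacings with 0.3 Å jitter plus uniform background, giving the
  single-contact-peak g(r) of terminal groups.
* **Rods** — three-point backbones at prescribed tilts with Gaussian polar
  noise (not full spherical diffusion; adequate for distribution-recovery
  tests).
* **Bilayer slab** — headgroup planes at ±20 Å with Gaussian roughness,
  144 per leaflet, plus optional terminal particles from a Gaussian
  z-mixture.
* **Telegraph process** — a stationary two-state Markov chain with exact
  autocorrelation e^{−t/τ} (τ = 100 ns default), simulated by geometric
  holding times, standing in for the trimer present/absent indicator.

All generators take an explicit seed and are bit-reproducible. Passing
recovery on these fixtures shows the estimators are correct under their own
model assumptions; it cannot validate force fields, sampling convergence of
a real MD run, or non-Markovian cluster kinetics.

## Problem sizes and statistical expectations

The recovery studies use 9800-frame diffusion ensembles, 500-frame
structural fixtures and a 10⁶-step indicator series; the full study set
completes in a few seconds. At these sizes the 288-walker diffusivity is
recovered to ~1%, the structural observables to within one histogram bin,
and the 100 ns timescale to well within 15%. The 6-walker diffusivity is
unbiased but carries ~10% relative standard deviation across seeds — the
honest price of estimating D from six molecules over this window, and the
reason its 3-sigma band in the worked example spans ±2.8.

## Known limitations

No triclinic cells, no trajectory alignment or leaflet auto-detection, no
anomalous-diffusion exponents, rotational diffusion or finite-size
hydrodynamic corrections, no lipid order parameters or area-per-lipid, and
no orientational pair correlations. The equilibration cut is a plain
`skip_time` (set it to 20 ns to discard a typical equilibration transient);
no automatic equilibration detection is attempted.
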