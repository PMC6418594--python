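# bilayerlab

Trajectory analysis for small polyphilic (bolapolyphile-type) additive
molecules solvated in a phospholipid bilayer — the kind of system where a
handful of rigid trans-bilayer molecules with mixed alkyl/perfluoroalkyl
side chains sit in a DPPC membrane and slowly self-associate. The package
computes, from an MD trajectory (or from its own synthetic fixtures):

* **Lateral self-diffusion** — multiple-time-origin mean squared
  displacement with the collective motion of a reference group (typically
  all lipids) subtracted, and the 2D Einstein relation
  `D = (1/2d) lim_{t→∞} d⟨|r(t) − r(0)|²⟩/dt` with `d = 2`. Uncertainties
  are three times the standard error over contiguous trajectory blocks.
* **Pair correlation functions** `g(r)` of molecular ring centers (COR) and
  CH3/CF3 terminal carbons, in lateral (in-plane) or full 3D normalization,
  with minimum-image distances, peak detection and first-shell minima.
* **Orientation** — backbone tilt angles α1, α2 against the bilayer normal,
  the bending angle β at the central ring (180° = unbent), and side-chain
  angles (90° = lying in the bilayer plane between the leaflets).
* **Axial structure** — z-density profiles relative to the system COM,
  peak-to-peak bilayer thickness, midplane occupancy ratios, and
  trans-leaflet flip events of terminal groups.
* **Cluster kinetics** — distance-cutoff clustering of additive molecules
  (default cutoff: the first minimum of the COR–COR g(r)), the per-frame
  trimer indicator, membership-exchange events, and the characteristic
  timescale of transient trimer formation as the autocorrelation e-folding
  time of the indicator.

Every stage is validated by parameter recovery against a seeded
synthetic-trajectory generator (2D Brownian walkers, trimer triangles,
terminal contact pairs, tilted rods, bilayer slabs, and a two-state
telegraph process), so the whole pipeline is testable without any MD run.

## Worked example

Generate a mixed Brownian ensemble — 288 lipid-like walkers at
13.9 × 10⁻¹² m²/s and 6 additive-like walkers at 10.7 × 10⁻¹² m²/s in a
98 Å lateral cell, 9800 frames at 0.1 ns — and recover both diffusivities
with the block-MSD pipeline:

```python
import bilayerlab as bl
from bilayerlab.synthetic import BrownianSpec, gen_brownian2d

spec = BrownianSpec(n_walkers=288, d_true=13.9, n_additives=6,
                    d_additive=10.7, dt=0.1, n_steps=9800, seed=1)
traj, groups = gen_brownian2d(spec)
traj = bl.unwrap(traj)

lip = groups.group("lipids")
add = groups.group("additives")
for name, grp in [("lipids", lip), ("additives", add)]:
    est = bl.block_diffusion(traj, grp, lip, n_blocks=5,
                             fit_window=(10.0, 50.0), max_lag=100.0)
    print(f"{name}: D = {est.d_value:.2f} ± {est.d_uncertainty:.2f} x 10^-12 m^2/s")
```

Output:

```
lipids: D = 13.81 ± 0.50 x 10^-12 m^2/s
additives: D = 9.02 ± 2.84 x 10^-12 m^2/s
```

Both generator inputs are recovered within the quoted 3-sigma bands; the
6-molecule ensemble carries the much larger statistical uncertainty one
expects from so few independent walkers.

The same analyses are available from the shell:

```sh
bilayerlab gen brownian2d --n-walkers 288 --d-true 13.9 --seed 1 --out brownian.xyz
bilayerlab diffusion --traj brownian.xyz --groups brownian.groups.yaml \
    --max-lag 100 --fit-window 10:50 --blocks 5
bilayerlab run --config analysis.yaml     # full multi-stage pipeline
```

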