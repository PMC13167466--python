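# blinkkit

Simulation and analysis of **spontaneously blinking fluorophores** for
super-resolution microscopy.  Spontaneously blinking dyes (spirocyclizing
Si-rhodamines and their relatives) toggle between a dark, closed form and a
fluorescent, open form through a pH-dependent intramolecular equilibrium —
no activation laser or redox buffer needed.  Their usefulness for
single-molecule localization microscopy (SMLM) and super-resolution optical
fluctuation imaging (SOFI) is governed by a handful of photophysical
numbers: the mean on-time, the mean off-time, their quotient (the **on:off
ratio**, or duty cycle, typically 10⁻² to 10⁻⁴), the photon rate while on,
and the apparent **pKa** of the dark/fluorescent equilibrium.

`blinkkit` is a toolbox for measuring exactly these quantities — and the
imaging metrics that follow from them — from localization tables and raw
movies, together with a fully specified synthetic-data generator so every
stage can be validated without experimental data.

## What it does

| stage | module | core quantity |
|---|---|---|
| synthetic ground truth | `blinkkit.simulate` | telegraph switching traces, EMCCD movies, structures, titrations |
| pKa fitting | `blinkkit.titration` | 4-parameter logistic fit `A(pH) = a_min + (a_max−a_min)/(1+10^{h(pH−pKa)})`, 95% CI, complex-titration guard |
| localization | `blinkkit.localize` | DoG detection, Poisson-MLE integrated-Gaussian fits, Mortensen precision, <40 nm / >N-photon filters, fiducial drift correction, rendering |
| blink kinetics | `blinkkit.kinetics` | gap-closed on-events, DBSCAN molecule grouping, on/off-time distributions, blinks per molecule, pooled on:off ratio |
| SOFI | `blinkkit.sofi` | second-order cumulant `G₂(p,τ) = ⟨δI(p,t)·δI(p,t+τ)⟩`, decorrelation-τ from `A·e^{−lag/τ}+c`, SNR, % useful pixels, kymographs |
| resolution | `blinkkit.frc` | Fourier ring correlation with the 1/7 threshold, sequential-window time-courses |
| condensate statistics | `blinkkit.spatial` | 3D density maps, thin slices, Monte-Carlo test against complete spatial randomness |

The model at the centre is a two-state telegraph process: exponential on
dwells with rate `k_off = 1/mean_on` and off dwells with rate
`k_on = duty · k_off`.  Its lagged autocovariance,
`G₂(lag) = A²ρ(1−ρ)·e^{−k·lag·Δt}` with `k = k_on + k_off`, links the
blink kinetics to the SOFI decorrelation time `τ ≈ 1/(k·Δt)` frames, which
floors at ~1 frame when the camera clock matches the on-time.

## Worked example

Estimate an on:off ratio from a simulated sparse-labeling acquisition
(60 molecules, duty 10⁻³, 10-ms mean on-time, 33,333 frames at a 27-ms
cycle — a 15-minute acquisition):

```python
import numpy as np
from blinkkit.camera import CameraModel
from blinkkit.simulate import (rates_for_duty, simulate_switching,
                               traces_to_localizations)
from blinkkit.kinetics import group_molecules, summarize_kinetics

cam = CameraModel(pixel_size=100.0, exposure=0.025, cycle=0.027)
rng = np.random.default_rng(42)
r_on, r_off = rates_for_duty(1e-3, mean_on=0.01)
g = np.arange(60)
pos = np.column_stack([(g % 8) * 3000.0, (g // 8) * 3000.0])
traces = [simulate_switching(r_on, r_off, 33_333 * 0.027, seed=rng)
          for _ in g]
table = traces_to_localizations(pos, traces, cam, 33_333, seed=rng)
groups = group_molecules(table, eps=100.0, gap=0)
s = summarize_kinetics(groups, cycle=0.027, n_frames=33_333)
print(f"{s.n_molecules} molecules, {s.n_events} on-events")
print(f"mean on-time  {s.mean_on*1e3:.1f} ms "
      f"(corrected {s.mean_on_corrected*1e3:.1f} ms)")
print(f"mean off-time {s.mean_off:.2f} s")
print(f"on:off ratio  {s.on_off_ratio:.2e} "
      f"(corrected {s.on_off_ratio_corrected:.2e})")
```

prints

```
60 molecules, 5385 on-events
mean on-time  35.4 ms (corrected 8.4 ms)
mean off-time 9.86 s
on:off ratio  3.63e-03 (corrected 8.55e-04)
```

The raw span-based on-time (35 ms) overstates the true 10-ms on-time
because a short burst always lights up at least one whole 27-ms frame;
subtracting one frame cycle (the expected quantization excess) recovers
8.4 ms, and the corrected pooled ratio lands within 15% of the true 10⁻³.
The pKa fitter behaves the same way: a noiseless synthetic titration at
pKa 5.15 is recovered to <10⁻⁴ pH units, and at 2% absorbance noise a
typical fit reads `pKa 5.114, 95% CI (5.056, 5.172)`.

A command-line surface wraps the same stages:

```sh
blinkkit simulate --config run.json
blinkkit localize movie.tif --out locs.csv --min-photons 100
blinkkit kinetics locs.csv --out kinetics.json --radius 100 --gap 5
blinkkit sofi movie.tif --out sofi.json --max-lag 20
blinkkit frc locs.csv --out frc.json --window 1470 --pixel 20
blinkkit spatial locs3d.csv --out csr.json --voxel 100
blinkkit fit-pka titration.csv --out pka.json
```

## Layout

```
src/blinkkit/      library (one module per stage, see table above)
tests/             pytest suite incl. brute-force oracle cross-checks
scripts/           acceptance script
docs/methods.md    models, estimators, numerical choices, limitations
```
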