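# tactoidlab

Biophysical analysis of filamentous-phage tactoids — spindle-shaped nematic
droplets of rod-like bacteriophages (such as fd and Pf4) that assemble under
depletion crowding, wrap around bacterial cells, and act as diffusion
barriers against antibiotics.  The package is aimed at microscopists and
soft-matter biophysicists who have tactoid morphometry tables, FRAP traces,
two-channel cell/tactoid images or tomogram filament counts and want the
quantitative readouts that link phage geometry to tactoid behaviour.

## What it computes

**Shape scaling.** A tactoid of major axis $R$, minor axis $r$ and volume
$V$ is modelled with the free energy

$$F = \gamma A + \frac{KV}{R^2}, \qquad A \sim Rr,\; V \sim Rr^2,$$

with surface tension $\gamma$ and one-constant Frank elastic constant $K$.
Minimising $F$ at fixed volume gives

$$\frac{R}{r} = \left(\frac{4K}{\gamma}\right)^{3/5} V^{-1/5},$$

so the aspect ratio falls as the $-1/5$ power of volume.  Approximating the
material constants from the rod geometry (length $b$, width $a$, in-tactoid
packing fraction $\rho$) via $K \sim \rho b/a^2$ and $\gamma \sim 1/(ab)$
yields $R/r \sim (\rho b^2/a)^{3/5} V^{-1/5}$, so two phage species'
prefactors compare as $(\rho_A b_A^2 / \rho_B b_B^2)^{3/5}$ at equal width.

**Population fits.** `ScalingLawModel` fits $R/r = C\,V^{-1/5}$ to a
measured population in log space (fixed or free exponent), with analytic
log-space standard errors, case-resampling bootstrap intervals, and
delta-method errors on between-species prefactor ratios.

**Packing.** Naive cylinder occupancy $n \pi r_f^2 / E^2$ of filaments
spanning a cubic tomogram box, from a manual count or from a
Fourier-transform lattice spacing, with a flag when the configuration is
geometrically impossible for hard cylinders.

**FRAP.** Trace normalisation (pre-bleach mean to 100%, first post-bleach
frame to 0%), trace averaging, and the exponential recovery fit
$I(t) = A(1-e^{-t/T})$ giving half-life $T\ln 2$, mobile fraction $A$ and
immobile fraction $1-A$.

**Morphometry.** Active-contour segmentation of cells and tactoids,
moment-ellipse axes and axial orientations, cell–tactoid association by
mask overlap/proximity, encapsulation scores, size excess, prolate-spheroid
volumes, and per-cell intensity in an antibiotic-uptake channel.

**Synthetic data.** Seeded generators for all of the above, with ground
truth, so every analysis stage can be validated end to end.

## Worked example

```python
from tactoidlab import PhageGeometry, predict_prefactor_ratio
from tactoidlab.scaling import ScalingLawModel
from tactoidlab.synthetic import gen_tactoid_population

pf4 = PhageGeometry(length=3.8, width=0.006, packing_fraction=0.25)
fd = PhageGeometry(length=0.9, width=0.006, packing_fraction=0.9)
print(f"predicted C_Pf4/C_fd = {predict_prefactor_ratio(pf4, fd):.2f}")

pop = gen_tactoid_population(seed=1, n=150, prefactor=5.88, sigma_log=0.1)
print(ScalingLawModel(pop).fit().summary())
```

prints

```
predicted C_Pf4/C_fd = 2.61
Tactoid scaling-law fit: R/r = C * V**exponent
  population: synthetic  (n = 150)
  C          = 5.804 +/- 0.046
  exponent   = -0.2 (fixed)
  residual SD (log space) = 0.09699
```

The first line is the geometry-and-packing prediction for how much more
elongated Pf4 tactoids are than fd tactoids at equal volume; the fit then
recovers the planted prefactor (5.88 µm³ᐟ⁵, within two standard errors)
from a noisy synthetic population.

The same analyses are available from the shell:

```sh
tactoidlab packing --edge-nm 89.72 --radius-nm 3.1 --count 69
tactoidlab simulate frap --seed 3 --out out/ && tactoidlab frap fit --input out/frap_trace.csv
```

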