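# geldiff

Transport modelling for solute and vesicle delivery from hydrogel scaffolds.

Collagen and similar fibrous hydrogels are used as depots for therapeutic
payloads — here extracellular vesicles (EVs), ~50–150 nm lipid particles —
that must diffuse out through the polymer mesh. `geldiff` implements the
quantitative toolkit needed to characterise such a system from standard
bench measurements:

* **Release kinetics** (`geldiff.release`). Cumulative release from a gel
  slab of thickness *l* into a perfect sink follows the Fickian series

  $$\frac{M_t}{M_\infty} = 1 - \sum_{n=0}^{\infty}
    \frac{8}{(2n+1)^2\pi^2}
    \exp\!\left\{-\frac{D(2n+1)^2\pi^2 t}{4l^2}\right\}$$

  With part of the payload trapped by the network, the observed profile is
  $f_\mathrm{mob}\,M_t/M_\infty$, plateauing at the mobile fraction
  $f_\mathrm{mob}$. `fit_release` estimates $(D, f_\mathrm{mob})$ jointly;
  `fluorescence_to_fraction` converts raw supernatant fluorescence via a
  linear calibration curve.

* **Network structure** (`geldiff.gel_network`). The in-gel diffusivity of
  a spherical probe of hydrodynamic radius $R_h$ in a random fiber network
  (fiber radius $R_f$, volume fraction $\varphi$, mesh radius
  $\bar r = R_f\sqrt{\pi/\varphi}$) follows Ogston–Amsden obstruction
  theory,

  $$D_g/D_0 = \exp\!\left\{-\frac{\pi}{4}
    \left(\frac{R_h+R_f}{\bar r+R_f}\right)^{2}\right\},$$

  or the Clague–Phillips hindered-diffusion model
  $D_g/D_0 = (1+2\alpha/3)^{-1}\exp\{-\pi\varphi^{0.174\ln(59.6R_f/R_s)}\}$
  with $\alpha=\varphi((R_s+R_f)/R_f)^2$, with $D_0$ from Stokes–Einstein.
  The module estimates the mesh radius from a probe panel, tabulates model
  curves $D_g(R_h)$, and inverts a measured diffusivity to a solute radius.

* **FRAP** (`geldiff.frap`). ROI-averaged recovery after an instantaneous
  rectangular bleach of depth $K$ in an infinite 2-D medium:
  $F(t) = 1 - K\,g(t;L_x)\,g(t;L_y)$ with
  $g = \operatorname{erf}(w) + (e^{-w^2}-1)/(w\sqrt{\pi})$,
  $w = L/(2\sqrt{Dt})$; `fit_frap` recovers $(D, K)$.

* **Particle tracking** (`geldiff.tracking`). Per-track maximum distance to
  the start point, path length and time-averaged MSD, plus a histogram and
  two-component Gaussian-mixture split (EM on log-distances) separating
  mobile from network-immobilized particles.

* **Synthetic data** (`geldiff.synthetic`). Seeded generators reproduce the
  statistical structure of each measurement (replicate release curves,
  noisy FRAP recoveries, two-population Brownian track ensembles, probe
  panels) together with ground-truth sidecars, so every stage can be
  validated in a closed loop.

## Worked example

Simulate a 35-day release experiment (4 replicates, sampling on days
0, 1, 2, 10, 14, 20, 30, 35; truth $D = 2.5\ \mu m^2/s$,
$f_\mathrm{mob} = 0.36$, $l = 1.26$ mm, replicate noise sd 0.05) and refit
it:

```console
$ geldiff simulate release --seed 7 --outdir .
wrote release_seed7.csv and release_seed7.truth.json
$ geldiff fit-release release_seed7.csv --out fit.json
D: 1.69178 um2/s  f_mob: 0.347597
```

The fitted mobile fraction (0.348 ± 0.011, from `fit.json`) sits close to
the true 0.36 — the plateau is well determined by the late time points —
while the diffusivity (1.69 ± 0.32 μm²/s against a truth of 2.5) is noisier
because only the first few samples constrain the rising phase; this
asymmetry is quantified in the test suite's 100-seed recovery study.

Network geometry from the gel composition (2.06% collagen by mass →
volume fraction 0.016):

```console
$ geldiff mesh --rf-nm 1 --phi 0.016
mesh_radius_nm: 14.01247804
$ geldiff mesh --rf-nm 10 --phi 0.016
mesh_radius_nm: 140.1247804
```

i.e. mesh radii of 14 nm and 140 nm for fiber radii of 1 and 10 nm. Placing
the empirical release diffusivity on the R_f = 10 nm Ogston–Amsden curve
gives the radius of the solute that could diffuse at that rate:

```console
$ geldiff invert --target-dg 2.5 --model ogston_amsden --rf-nm 10 --phi 0.016
solute_radius_nm: 87.80384882
```

so only particles well below ~90 nm move at the observed release rate —
consistent with a picture in which the smaller tail of the vesicle
population diffuses out while larger vesicles stay obstructed until the
matrix is degraded.

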