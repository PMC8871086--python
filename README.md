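# histoscar

Quantitative characterization of scar tissue in H&E-stained histology images.

Scar formation after dermal injury replaces the normal architecture of the
dermis — hair follicles, glands, scattered nuclei, loosely woven collagen —
with dense, aligned collagen. `histoscar` turns an RGB histology ROI into the
four numbers a histologist uses to describe that change:

* **FS%** — foreground fraction: hematoxylin-dark structures (hair follicles,
  glands, nuclei) as a percentage of ROI pixels;
* **CAS%** — collagen area fraction: eosin-pink collagen pixels as a
  percentage of ROI pixels;
* **CDM%** — mean of the collagen density map, the collagen mask convolved
  with an airy-disk kernel (local collagen fraction m ∈ [0, 1]);
* **DV%** — mean directional variance of the fiber orientation field,

      V(x, y) = 1 − R(x, y) / m(x, y)

  where θ(x, y) is the per-pixel axial fiber angle, the doubled-angle
  components (cos 2θ, sin 2θ) are convolved with the same airy-disk kernel,
  and R = √(X² + Y²) is the resultant magnitude. Doubling the angles
  identifies θ with θ + 180° (a fiber has no head or tail), making V a local
  circular variance: 0 for perfectly aligned fibers, 1 for an isotropic mix.

The pipeline is: sRGB → CIE L\*a\*b\* conversion; K-means (k = 3) on the
chromatic (a\*, b\*) coordinates; cluster-role assignment by mean lightness
(background = lightest, foreground = darkest, collagen = remaining); density,
orientation, and variance maps from the collagen mask; Student's t-test /
one-way ANOVA over groups of ROIs.

Because no public H&E scar dataset accompanies the method, the package ships
a synthetic generator (`histoscar.synthetic`) that renders H&E-like dermis
scenes — pink fibers with a controllable axial von Mises orientation
distribution, purple follicle/gland ellipses and nuclei, near-white
background — together with per-pixel ground-truth class and orientation maps,
so every stage is testable against known truth.

## Worked example

Generate synthetic scar and normal ROIs, characterize them, and compare:

```bash
histoscar generate --preset scar   --height 256 --width 256 --seed 0 --outdir scenes
histoscar generate --preset normal --height 256 --width 256 --seed 0 --outdir scenes
histoscar characterize --image scenes/scar_0000.png   --group scar   --seed 0 --outdir scar_out
histoscar characterize --image scenes/normal_0000.png --group normal --seed 0 --outdir normal_out
```

The two `characterize` runs print:

```
fs_pct=1.15 cas_pct=88.42 cdm_pct=88.42 dv_pct=45.37
fs_pct=2.78 cas_pct=53.87 cdm_pct=53.87 dv_pct=54.73
```

The scar ROI (first line) has ~88% collagen at high density and low
directional variance — dense, aligned fibers — while the normal ROI has ~54%
collagen, more foreground structures, and higher variance — sparse, isotropic
fibers. Each output directory also holds the CAS/FS/BS masks, a color
overlay, the density / orientation / variance maps (float TIFF + rendered
PNG), a one-row `metrics.csv`, and a `manifest.json` recording the exact
parameters, so re-running with them reproduces byte-identical metrics.

With three ROIs per group (seeds 0–2), `histoscar compare` prints:

```
metric: cdm_pct  test: student_t
  scar: 88.611 ± 1.451
  normal: 52.414 ± 1.865
  t = 26.5256, p = 1.201e-05

metric: dv_pct  test: student_t
  scar: 34.033 ± 12.001
  normal: 53.876 ± 3.794
  t = -2.7306, p = 0.05241
```

i.e. collagen density separates the groups decisively even at n = 3, while
the directional-variance difference points the right way but needs more ROIs
at this sample size.

The same operations are available as library functions
(`histoscar.characterize`, `histoscar.preset`, `histoscar.compare_regions`,
…); the CLI is a thin wrapper over them.

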