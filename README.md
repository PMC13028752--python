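# rbcdeform

Quantification of red-blood-cell (RBC) deformability from microfluidic
brightfield images, for hemorheology labs measuring how RBCs elongate
under controlled shear flow — e.g. when comparing healthy donors with
patients whose erythrocytes are mechanically altered (such as chronic
lymphocytic leukemia, CLL).

In a shear-flow assay, RBCs adhere to the wall of a microfluidic channel
and are exposed to a stepwise increasing wall shear stress
τ = 1…7 dyn/cm² (wall shear rate γ̇ = τ/μ ≈ 89…625 s⁻¹ at suspension
viscosity μ = 1.12 mPa·s). Each cell's elongation in an image is
summarized by the **deformability index**

```
DI = (L_X − L_Y) / (L_X + L_Y)
```

where `L_X` is the cell's extent along the flow axis and `L_Y` the
transverse extent: DI = 0 for a circle, → 1 for extreme elongation.
Per image, the accepted-cell DIs are summed (`DI_Total`) and averaged
(`DI_Mean`); per donor, cells are pooled per shear condition into a
7-point shear-response profile.

The package implements **two independent image pipelines** and the
statistics used to compare them and to compare donor groups:

* **sine-window pipeline** (`rbcdeform.sinewin`) — each image row is
  convolved with a normalized squared half-sine window (100 samples);
  subtracting the filtered image removes the smooth streamline
  background. After contrast enhancement, Gaussian smoothing and Otsu
  binarization, an ellipse is fitted to each object's contour by direct
  least squares; cells pass only if `L_X > L_Y`,
  `L_X − L_Y ≥ 0.2·L_X`, and both diameters fall in configured size
  windows (4–9 and 2.5–7 units).
* **DoG pipeline** (`rbcdeform.dog`) — a difference-of-Gaussians
  band-pass (σ₁ = 0.7, σ₂ = 16 px) plus a 45-px horizontal white top-hat
  suppress streaks; the image is binarized at 1.06 × the Otsu threshold,
  border-touching components are dropped, components of 50–130 px are
  kept, and each cell is measured by its farthest pixel pair (`L_X`)
  and the perpendicular projection extent (`L_Y`); cells with
  DI > 0.35 are rejected as artifacts.
* **statistics** (`rbcdeform.stats`) — Shapiro–Wilk, Mann–Whitney U,
  Pearson, Bland–Altman agreement (bias and 95% limits of agreement),
  and a donor-random-intercept linear mixed model with Type III F tests,
  Satterthwaite denominator degrees of freedom and partial eta squared
  η²p = F·df1/(F·df1 + df2).
* **synthetic data** (`rbcdeform.synthgen`) — ground-truthed streamline
  images with elliptical cells of known axes, and two-group donor
  cohorts drawn from a saturating shear response
  DI(τ) = DI_max·τ/(τ_half + τ); no external image data is needed to
  exercise the whole system.

## Worked example

```python
import rbcdeform as r

config = r.PipelineConfig(criteria_units="micrometers")
image, truth = r.generate_image(r.BackgroundSpec(noise_sd=2.0), n_cells=20, seed=42)
cells, summary = r.run_sinewin(image, config)
print(summary.n_cells, round(summary.DI_Mean, 4))
```

Running `python examples/analyze_synthetic_image.py` prints

```
ground truth: 20 cells, mean DI = 0.1816
sine-window  accepted 20 cells, DI_Total = 3.397, DI_Mean = 0.1699
DoG          accepted 20 cells, DI_Total = 2.897, DI_Mean = 0.1448
```

Both pipelines find all 20 rendered cells; their mean DI sits close to
the generating truth, with the sine-window value above the DoG value —
the same ordering seen when the two methods are applied to real images,
because they localize cell boundaries differently.
`python examples/cohort_statistics.py` fits the mixed model to a
simulated healthy-vs-CLL cohort:

```
group        F(1, 20.0) =   50.20   p = 7.21e-07   eta2p = 0.72
shear        F(6, 120.0) =  176.35   p = 4.65e-57   eta2p = 0.90
group:shear  F(6, 120.0) =    0.92   p = 4.83e-01   eta2p = 0.04
```

The large group effect says the patient group deforms less across the
shear sweep. See `examples/donor_profile.py` (per-donor shear profile)
and `examples/pipeline_agreement.py` (Pearson + Bland–Altman between
pipelines).

A thin CLI wraps the same functionality:

```
rbcdeform simulate image --out data --seed 3
rbcdeform analyze --pipeline dog --out results data/synthetic_3.tif
rbcdeform simulate cohort --out cohort.csv --seed 5
rbcdeform stats mixed --cohort cohort.csv --out mixed.json
rbcdeform compare --a a.csv --b b.csv --out agreement.json
```

## Layout

```
src/rbcdeform/
  core.py           image container, preprocessing, I/O, configuration
  sinewin.py        sine-window convolution pipeline
  dog.py            difference-of-Gaussians pipeline
  deformability.py  DI metric, aggregation, shear conversion
  stats.py          mixed model, agreement and group tests
  synthgen.py       synthetic images and cohorts
  analyze.py, cli.py  batch orchestration and command line
docs/methods.md     model and design notes
examples/           one narrative script per capability
```
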