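# foveapit

Quantitative analysis of **foveal pit morphology** from macular OCT
scans: total retinal thickness (TRT) maps, foveal center location,
parametric pit models, geometric pit parameters, and the agreement
statistics used to compare methods between paired acquisitions.

The fovea is the retinal region of maximum visual acuity; its concave
depression (the foveal pit) is characterized in research and clinical
studies by parameters such as central foveal thickness (CFT), rim height,
rim radius, and maximum slope. Two methodological steps dominate the
reliability of those parameters and are the focus of this package:

1. **Where is the foveal center?** Imperfect fixation decenters the scan;
   the package implements four strategies — trust fixation (*none*), raw
   thickness minimum (*min*), minimum of a cubically resampled central
   window (*interp+min*), and minimum after circular-kernel smoothing
   (*smooth+min*) — and compares them by the alignment dissimilarity of
   paired raster/star acquisitions,

   D_align = (1/M) Σᵢⱼ |TRT_raster[i,j] − TRT_star[i,j]|,

   over the cells of a common 3 × 3 mm, 0.02 mm grid defined in both maps.
2. **Should the pit be modelled before measuring it?** Six parametric
   models from the literature (difference of two Gaussians; polynomial
   surface + Gaussian; center-anchored radial "second derivative of a
   Gaussian"; sloped piecemeal Gaussian; pinned cubic Bézier curves; sum
   of three Gaussians) plus LOESS and moving-average smoothing are fitted
   by nonlinear least squares to 24-direction radial profiles, and
   compared by fitting RMSE, by raster/star absolute agreement
   (ICC(2,1) = (MS_S − MS_E)/(MS_S + MS_E + 2(MS_M − MS_E)/n) with
   percentile-bootstrap CIs), and by the relative estimation bias
   100·(x_model − x_raw)/x_raw of each parameter.

Because clinical OCT volumes are rarely shareable, the package ships a
synthetic-data module that generates ground-truth pit surfaces and samples
them with the two Spectralis-style acquisition geometries (raster:
25 × 512 over 9.0 × 7.5 mm; star: 12 diameters × 768 over 4.5 mm),
including fixation decentration, correlated "wiggliness" noise, blip
outliers, and noisier star scans. See `docs/methods.md` for the models,
numerical choices, and what the generator does and does not emulate.

## Worked example

```python
import foveapit as fp

# ground-truth surface and one noisy, decentered star acquisition
truth = fp.make_surface({"cft_um": 220.0, "rim_height_um": 345.0,
                         "rim_radius_mm": 1.05}, seed=7)
cfg = fp.AcquisitionConfig(pattern="star", decenter_mm=(0.25, -0.1), seed=11)
scan = fp.sample_scan(truth, cfg)

cloud = fp.standardize_orientation(fp.compute_trt(scan), scan.meta.eye)
center = fp.locate_smooth_min(cloud)
radial = fp.resample_radial(cloud, center=center)
raw = fp.compute_parameters(radial)
fit = fp.fit_model(radial, "scheibe", seed=0)
smoothed = fp.parameters_from_fit(fit, radial)
```

This prints (via the obvious `print` statements):

```
located center: (0.20, -0.18) mm  [true decentration (0.25, -0.10)]
raw cft_um: 221.7
raw rim_height_um: 350.5
raw rim_radius_mm: 1.1
raw max_slope_um_per_mm: 586.0
scheibe fit: rmse 3.54 um, converged=True
fitted max slope: 192.1 um/mm (bias -67.2%)
```

Reading it: the smoothed-minimum search recovers the fixation error to
within a tenth of a millimetre; the thickness parameters (CFT 221.7 µm,
rim height 350.5 µm vs. true 220/345) are robust to noise; but the *raw*
maximum slope (586 µm/mm) is wildly inflated by the wiggliness of the
noisy star profile — the true value is 194 µm/mm, and the smooth radial
model fit recovers 192 µm/mm. The large negative "bias" of the model
relative to the raw estimate is exactly the bias-vs-agreement trade-off
the model-comparison workflow quantifies cohort-wide.

Cohort-level studies are one call each — `run_center_comparison` and
`run_model_comparison` — or one CLI verb:

```bash
foveapit simulate --n 20 --seed 7 --out cohort/
foveapit compare-centers --in cohort/ --seed 7 --out center_report/
foveapit compare-models  --in cohort/ --seed 7 --out model_report/
```

producing JSON reports plus TSV tables (models × RMSE/ICC and models ×
bias, with dash cells where a model pins a parameter to its raw value).

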