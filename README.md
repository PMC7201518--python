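# octaperf

Quantification of macular perfusion from OCTA en-face angiograms, built
for longitudinal (pre/post treatment) studies of retinal capillary
dropout — e.g. tracking perfusion change across a course of intravitreal
anti-VEGF injections for diabetic macular edema.

Optical coherence tomography angiography (OCTA) renders retinal blood
flow as square grayscale *en-face* projections per capillary slab (full
thickness, superficial and deep plexus) on a 6×6 mm or 3×3 mm macular
field. From each image pair the package computes the four standard
perfusion metrics and the statistics that compare them across visits:

- **Vascular density (VD)** — percent of the analysis region occupied by
  binarized vessel signal.
- **Skeleton VD** — the same ratio on the 1-px-thinned centerline map;
  proportional to vessel *length* density and the most sensitive marker
  of capillary loss.
- **Fractal dimension (FD)** — box-counting dimension of the skeleton,
  `FD = −d log N(ε) / d log ε`, summarizing branching complexity.
- **FAZ area** — mean shoelace area (mm²) of replicate manual traces of
  the foveal avascular zone.

The processing chain mirrors the established clinical workflow:
scan-quality gating (signal-strength index < 5 rejected), rigid
registration of the follow-up image to baseline with a common-area mask
so both visits are measured over identical retina, and a **3-way
binarization** — a global noise threshold derived from intensity
statistics sampled inside the FAZ, top-hat background flattening, then
Hessian vesselness AND adaptive-median thresholding (a pixel counts as
vessel only if both branches detect it) — followed by topology-
preserving skeletonization. Paired statistics select the paired *t*-test
or Wilcoxon signed-rank by Shapiro–Wilk normality of the differences,
with Spearman/Pearson correlations and OLS regression of metric change
on baseline covariates (the "floor effect" analysis).

Because no public OCTA cohort accompanies this type of study, the
package ships a first-class synthetic-data module: branching capillary
trees sparing a central avascular disk, rendered with background noise
and vessel speckle, degraded between visits by terminal-segment dropout
with a known length fraction, and displaced by a known rigid motion —
giving every pipeline stage a measurable ground truth.

## Worked example

```python
from octaperf import (SimulationConfig, generate_paired_cohort,
                      analyze_cohort, build_report)
from octaperf.stats import format_report

cfg = SimulationConfig()                       # 6x6 mm, 304 px protocol
cohort = generate_paired_cohort(10, cfg, effect=(0.10, 0.03), seed=5)
table = analyze_cohort(cohort, sim_config=cfg) # register + segment + measure
print(format_report(build_report(table, metrics=["vd_percent",
                                                 "skeleton_vd_percent", "fd"])))
```

prints (one row per metric; your exact numbers depend on the seed):

```
            vd_percent  pre  10.576 ±  1.188  post  10.039 ±  0.997  change  -0.537 ±  0.251  ( -5.1%)  paired t-test, p = 8.205e-05
   skeleton_vd_percent  pre   6.790 ±  0.784  post   6.319 ±  0.681  change  -0.472 ±  0.147  ( -6.9%)  paired t-test, p = 3.218e-06
                    fd  pre   1.522 ±  0.026  post   1.503 ±  0.023  change  -0.019 ±  0.008  ( -1.3%)  paired t-test, p = 3.555e-05
```

Ten simulated eyes with ~10% capillary dropout between visits show a
significant decrease in vessel density, a proportionally larger decrease
in skeleton density (length is lost faster than area when thin terminals
drop out), and a small decrease in fractal dimension — the qualitative
signature reported for anti-VEGF-treated eyes.

A thin CLI wraps the same functions: `octaperf segment` (binarize one
image), `octaperf report` (paired summary from metric/clinical CSVs),
`octaperf simulate` (write a synthetic cohort).

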