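# periocort

Radiomic texture analysis of **peri-implant bone corticalization** on
intraoral radiographs, and its longitudinal relation to **marginal bone
loss (MBL)**.

After a dental implant is functionally loaded, the trabecular (spongy)
bone around the implant neck often remodels into dense, cortical-like
bone. On a periapical radiograph this *corticalization* appears as a
brighter, more homogeneous texture with long runs of similar optical
density, whereas healthy cancellous bone shows a chaotic, high-entropy
trabecular pattern. `periocort` quantifies this transformation and
provides the statistical machinery to relate it to vertical bone loss in
long-term follow-up cohorts — for researchers in dental radiology and
implantology, and for anyone who needs a clean, tested reference
implementation of these classic texture statistics.

## The corticalization index

Each region of interest (ROI; the acquisition protocol uses 1500-pixel
patches at the implant neck and in distant reference bone) is
intensity-normalized to the window `μ ± 3σ` and quantized to
`N_g = 2^6 = 64` gray levels. Three features are computed on the prepared
ROI, with `p(i)` the normalized gray-level histogram:

- **Mean optical density** — first-order mean, `Σ_i i·p(i)`.
- **Difference entropy** (`DifEntr`) — the common-logarithm Shannon
  entropy of the co-occurrence difference histogram `p_{x−y}(k)` at a
  5-pixel spacing: `−Σ_k p_{x−y}(k) log₁₀ p_{x−y}(k)`. High in cancellous
  bone.
- **Long-run emphasis** (`LngREmph`) — from the gray-level run-length
  matrix `p(i,k)`: `Σ_{i,k} k² p(i,k) / Σ_{i,k} p(i,k)`. High for thick,
  uniformly dense, radio-opaque structures.

The second-order features are computed in the four lattice directions
(0°, 45°, 90°, 135°) and averaged arithmetically. The **corticalization
index** combines them as

```
CI = MeanOpticalDensity · LngREmph / DifEntr
```

so corticalized bone scores high and trabecular bone low. Because the
clinical radiographs behind the method are available on request only,
the package ships a synthetic-data module (`periocort.synthetic`) that
generates radiograph-like Gaussian-random-field textures, full 476 × 620
study frames at 70 μm/pixel with protocol-sized ROIs, and longitudinal
cohorts with zero-inflated MBL and a weak positive CI–MBL coupling.

## Worked example

```python
import numpy as np
from periocort import (TextureParams, generate_texture_patch, analyze_roi,
                       CohortSimConfig, generate_cohort, longitudinal_summary)

roi = np.column_stack([g.ravel() for g in np.mgrid[0:100, 0:100]])
for cls in ("cortical", "trabecular", "soft_tissue"):
    patch = generate_texture_patch(TextureParams(tissue_class=cls, seed=1))
    f = analyze_roi(patch, roi)
    print(f"{cls:>11}: mean_od={f.mean_od:5.2f}  DifEntr={f.difentr_avg:.3f}  "
          f"LngREmph={f.lngremph_avg:.3f}  CI={f.ci:6.2f}")
```

```
   cortical: mean_od=32.53  DifEntr=1.267  LngREmph=1.404  CI= 36.05
 trabecular: mean_od=32.50  DifEntr=1.481  LngREmph=1.281  CI= 28.11
soft_tissue: mean_od=32.58  DifEntr=1.381  LngREmph=1.294  CI= 30.53
```

The per-ROI normalization pins the mean optical density near
`(N_g + 1)/2 = 32.5`, so the discrimination is carried by the run-length
and entropy terms: the corticalized patch has longer uniform runs
(LngREmph 1.40 vs 1.28) and a less chaotic co-occurrence structure
(DifEntr 1.27 vs 1.48), hence the highest CI.

A simulated 2700-implant cohort, summarized longitudinally:

```python
records, truth = generate_cohort(CohortSimConfig(n_implants=2700, seed=1))
print(longitudinal_summary(records).table)
```

```
timepoint  n_ci  ci_mean   ci_sd  mbl_mean     cc  r_squared_pct  reg_p
  initial  2700  202.753 148.792     0.266 -0.030          0.087  0.125
       y5  2700  277.626 175.745     0.880  0.083          0.690  0.000
      y10  2700  261.285 168.151     1.523  0.128          1.631  0.000
```

CI rises steeply over the first five years of loading and stays high;
MBL progresses throughout; and from year five on the CI–MBL regression
is weakly positive and significant (coefficient of determination `R² =
100·CC²` of about one percent) — corticalization accompanies, rather
than protects against, marginal bone loss.

The same workflow is available from the shell:

```sh
periocort simulate --seed 1 --n-implants 100 --n-frames 4 --out sim/
periocort analyze  --images sim/frames --out features.csv
periocort stats    --cohort sim/cohort.csv --out reports/
```

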