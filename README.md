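# tmdkit — tumor-margin delineation from hyperspectral skin images

`tmdkit` is an open reimplementation of a region-based tumor-margin
delineation (TMD) pipeline for VIS–NIR hyperspectral images of
non-melanoma skin cancers (basal and squamous cell carcinoma).  Surgical
excision of these tumors depends on knowing where the tumor ends;
hyperspectral imaging captures a full reflectance spectrum per pixel, and
the spectra of carcinoma and normal skin differ enough (ΔR on the order
of 0.2–0.3 at 700 nm) that the margin can be mapped objectively.

The pipeline:

1. **Reflectance calibration.** Raw digital numbers are converted to
   reflectance with dark and white reference images,
   `R = ρ_w (I − D) / (W − D)`, where `W` is the in-scene PTFE tile
   (ρ_w ≈ 0.98) and `D` the dark-current frame.
2. **Region formation.** The mean-intensity image is over-segmented along
   intensity edges (Sobel gradient, percentile suppression at the *scale
   level*, watershed), then segments are merged by the **full
   lambda-schedule** algorithm: the adjacent pair (S_i, S_j) with minimal
   cost

   t_ij = [ |S_i||S_j| / (|S_i|+|S_j|) · ‖v_i − v_j‖² ] / l(∂(S_i, S_j))

   is merged repeatedly while t_ij < T, where v_i is the segment's mean
   spectrum, l the shared boundary length, and T derives from the *merge
   level* percentile.  Defaults: scale level 30, merge level 75.
3. **Classification.** Each segment's mean spectrum is compared to
   per-class reference spectra (area-weighted means over ~37% training
   segments) with the **Spectral Angle Mapper**,
   `α = arccos( t·r / (‖t‖‖r‖) )`; a segment is tumor or normal if its
   best angle is within 0.1 rad, otherwise unclassified.
4. **Evaluation.** Per-class ROC/AUC on held-out segments (scored by the
   SAM rule angle), the maximum horizontal distance D_max from the tumor
   center to the mapped margin, and Bland–Altman limits of agreement
   between two distance series.

Everything is exercisable without patient data through a synthetic
hyperspectral skin-phantom generator with ground truth.

## Worked example

```python
import numpy as np
from tmdkit import phantom, pipeline

spec = phantom.PhantomSpec(seed=3)          # 64x64x40, ΔR(700nm)=0.2
res = phantom.generate(spec)
out = pipeline.run_arrays(res.raw, res.refs, roi=res.roi,
                          truth=res.truth, seed=3)
print("segments:", out.initial_n_segments, "->", out.segments.n_segments)
print("fractions:", {k: round(v, 3) for k, v in out.fractions.items()})
print("AUC:", {k: round(v.auc, 3) for k, v in out.roc.items()})
```

prints

```
segments: 282 -> 16
fractions: {'tumor': 0.195, 'normal': 0.805, 'unclassified': 0.0}
AUC: {'tumor': 1.0, 'normal': 1.0}
```

i.e. the edge stage found 282 raw regions, lambda-schedule merging
reduced them to 16 spectrally homogeneous segments, SAM assigned 19.5%
of the pixel area to the tumor class (the generated disc covers 19.5%),
and held-out segments of both classes are ranked perfectly by their rule
angles.

The same run is available from the shell:

```sh
tmd phantom --out ph --seed 3
tmd run --raw ph/raw.hdr --dark ph/dark.hdr --white ph/white.hdr \
        --truth ph/truth.png --seed 3 --out run/
```

which writes the calibrated ENVI cube, segment map, merge schedule,
classification map (red tumor / green normal / black unclassified), rule
angles, ROC report and a replayable JSON manifest into `run/`.

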