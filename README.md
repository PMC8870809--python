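# tmtvnet

Automated **total metabolic tumor volume (TMTV)** computation for
FDG-avid lymphoma PET/CT.

TMTV — the summed volume (mL) of all tumor voxels on the baseline
¹⁸F-FDG PET — is a prognostic factor in Hodgkin lymphoma, DLBCL and
follicular lymphoma, but manual whole-body delineation is slow and the
field has not converged on a single thresholding rule.  `tmtvnet`
implements a methodology-agnostic automation pipeline for nuclear
medicine researchers:

1. **TMTVprob ground truth** — within each manual region of interest,
   four standard segmentation rules are applied (41% SUVmax,
   SUV > 2.5, SUV > 4.0, Otsu) and averaged voxel-wise into a
   probability map with values in {0, ¼, ½, ¾, 1} that encodes where
   the methodologies agree and disagree;
2. **3D V-NET** (4 levels, 8 base channels, residual stages, skip
   connections, sigmoid output) trained on 0–1-scaled CT+PET channels
   against TMTVprob with the soft dice loss
   `1 − (2Σpt + ε)/(Σp + Σt + ε)`, SGD (lr 0.001, momentum 0.9) and
   rigid+scale augmentation — implemented in pure NumPy with its own
   reverse-mode autograd, so it runs anywhere;
3. **Post-processing** that reproduces each clinical methodology from
   the binarized (> 0.5) prediction: global SUV cutoffs, or — for the
   per-lesion 41% rule — connected components, watershed splitting of
   coalescent masses over 30 mL along SUV topography, and thresholding
   each sub-component at 0.41 × its own SUVmax;
4. **Agreement statistics**: dice/Jaccard, voxel-level Se/Sp/PPV/NPV,
   distribution summaries, paired t-test, Spearman correlation and
   Bland–Altman limits of agreement, stratifiable by lymphoma subtype.

Because clinical lymphoma cohorts are restricted data, the package ships
a seeded synthetic phantom generator (whole-body PET/CT with hot
ellipsoidal lesions, coalescent double-peak masses, physiological
uptakes, an injection-site artifact and exact analytic lesion volumes)
that exercises every stage end-to-end.

## Worked example

```python
import numpy as np
import tmtvnet as tv

# one flat 10 mm sphere (analytic volume 4.19 mL) on a 2 mm grid
spec = tv.PhantomSpec(
    grid_shape=(40, 40, 40), voxel_spacing_mm=(2, 2, 2),
    lesions=[tv.LesionSpec(center_mm=(40, 40, 40), radii_mm=(10, 10, 10),
                           peak_suv=10.0)],
    background_suv=0.5, noise_sd=0.05, seed=1,
)
case = tv.generate_phantom(spec)
print("analytic lesion volume:", round(case.truth_volumes_ml[1], 2), "mL")

rois = tv.manual_roi_boxes(case.truth_masks, margin_mm=6, spacing_mm=(2, 2, 2))
prob = tv.ground_truth_for_case(case.pet, rois)
print("TMTVprob levels attained:", sorted(float(v) for v in np.unique(prob)))

raw = tv.binarize_prediction(prob)
for method in (tv.PERCENT41, tv.CUTOFF25, tv.CUTOFF40):
    res = tv.apply_methodology(raw, case.pet, method)
    print(f"{method.name:7s} TMTV = {res.tmtv_ml:.2f} mL, ROIs = {tv.count_rois(res)}")
```

prints

```
analytic lesion volume: 4.19 mL
TMTVprob levels attained: [0.0, 0.25, 1.0]
41pc    TMTV = 4.12 mL, ROIs = 1
suv2.5  TMTV = 4.12 mL, ROIs = 1
suv4    TMTV = 4.12 mL, ROIs = 1
```

The voxelized TMTV (4.12 mL) recovers the analytic sphere volume within
2% on a 2 mm grid; the lesion core is unanimous across methodologies
(probability 1.0) while its rim is not (0.25), and all three
post-processing methodologies agree here because the lesion is flat and
well above every threshold.

## Command line

A thin `tmtv` CLI wraps the library:
`tmtv phantom`, `tmtv preprocess`, `tmtv groundtruth`, `tmtv train`,
`tmtv predict`, `tmtv postprocess`, `tmtv evaluate` — see
`tmtv --help`.  Volumes are exchanged as NIfTI (`.nii`/`.nii.gz`); a
minimal DICOM PET reader with body-weight SUV conversion is included.

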