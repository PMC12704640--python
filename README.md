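# desimri

Automated computation of the **Disproportionately Elevated Sulcal Index
(DESI)** from T1-weighted brain MRI.

Idiopathic normal pressure hydrocephalus (iNPH) is a treatable dementia
whose hallmark on imaging is not just big ventricles but a *redistribution*
of cerebrospinal fluid: the Sylvian fissures balloon while the sulci at the
high convexity are squeezed shut (the DESH pattern). DESI turns that
pattern into a single dimensionless number,

```
DESI = V_sylvian / V_superior
```

the ratio of Sylvian-fissure CSF volume to the superior sulcal CSF volume
inside a dihedral wedge that opens upward from the AC-PC line with a 30°
aperture. High DESI means disproportion. Shipped decision thresholds
(score ≥ threshold ⇒ positive): **6.10** for DESH vs non-DESH
hydrocephalus, **4.83** for DESH vs other diagnostic groups, **1.92** for
hydrocephalus vs everyone else.

The pipeline: read NIfTI → reorient to RAS → N4 bias correction → rigid
AC-PC realignment from supplied landmark coordinates → per-slice 2D
multi-label segmentation of the coronal planes between AC and PC (left
Sylvian, right Sylvian, suprasylvian sulci) → 3D reconstruction and
small-component filtering → wedge-restricted volumetry on the native grid
→ DESI and threshold classification.

It is aimed at researchers working on quantitative CSF-space morphometry
who need a reproducible, fully automated DESH biomarker — and at anyone who
wants a completely self-validating testbed: the package ships a synthetic
phantom generator whose Sylvian and convexity-sulcal compartments have
closed-form volumes, so the entire geometry stack can be checked against
analytic ground truth (see `docs/methods.md`).

## Worked example

Generate a severe-DESH phantom, run the pipeline in oracle-mask mode
(ground-truth masks stand in for the segmenter, isolating the geometry),
and classify:

```python
from desimri import PhantomSpec, generate_phantom
from desimri.image_io import VolumeImage
from desimri.pipeline import PipelineConfig, run_pipeline

spec = PhantomSpec(desh_severity=0.8, seed=7)
vol, truth = generate_phantom(spec)
labels = VolumeImage(truth.label_mask.to_labels(), vol.affine)

cfg = PipelineConfig(bias_correction=False, threshold=4.83)
out = run_pipeline(cfg, volume=vol, landmarks=truth.landmarks,
                   oracle_labels=labels)
print(f"sylvian  {out['volumes']['sylvian_total_mm3']:.0f} mm^3")
print(f"superior {out['volumes']['superior_wedge_mm3']:.0f} mm^3")
print(f"DESI     {out['desi']['desi']:.3f}  -> {out['desi']['label']}")
print(f"analytic {truth.analytic_desi:.3f}")
```

prints

```
sylvian  25950 mm^3
superior 4300 mm^3
DESI     6.035  -> positive
analytic 6.000
```

The phantom's analytic DESI at severity 0.8 is 6.000; the voxelized
pipeline recovers 6.035 (0.6% discretization error at 1 mm spacing), above
the 4.83 threshold, so the case classifies DESH-positive.

The same flow is available from the shell:

```bash
desi generate-phantom --severity 0.8 --seed 7 --out ph/
desi run --volume ph/phantom_t1.nii.gz --landmarks ph/landmarks.json \
         --oracle-labels ph/phantom_labels.nii.gz --no-bias-correction \
         --threshold 4.83 --out result/
desi train --n-phantoms 100 --epochs 20 --out model/   # CPU-scale segmenter
desi evaluate --scores cohort.csv --threshold 4.83     # cohort ROC/metrics
```

To segment with a trained model instead of oracle masks, pass
`--model model/segmenter.npz` to `desi run`.

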