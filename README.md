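# cervimetry

Automated multi-layer analysis of the pregnant cervix on 3D T2-weighted
MRI-style volumes: parcellation conventions, landmark-based biometry,
volumetry, a trainable 3D UNet segmentation network, population-averaged
atlas construction and gestational-age normative charts — plus a parametric
cervix phantom with analytically known geometry so the whole pipeline is
testable without patient data.

## Who this is for

Clinical cervical-length measurement (the standard preterm-birth screening
metric) is done in 2D on transvaginal ultrasound and suffers from
substantial inter-observer variability. Motion-corrected 3D T2w MRI
resolves the internal cervical layers — endocervical canal, inner stroma
(subglandular zone), outer stroma, canal cysts — and makes fully 3D,
automated measurement possible. This package implements that measurement
pipeline for researchers working with multi-label cervix segmentations in
NIfTI format.

## The measurements

Given a label map (0 background, 1 canal, 2 inner stroma, 3 outer stroma,
4 cyst, 5 bladder) on a world-mm affine:

- **Landmarks** — the canal's two open ends (internal os = inlet, external
  os = outlet) are found as interfaces between the canal (including cysts)
  and background; their centre-points are the means of the interface
  voxels; the canal **midpoint** is the mean coordinate of the canal label.
- **Cervical length (CL)** — the clinical two-line measurement:
  `CL = |inlet − midpoint| + |midpoint − outlet|`.
- **Inlet/outlet diameters** — ray-cast at each end centre, in the
  landmark (mid-sagittal) plane perpendicular to the local canal axis,
  with the boundary defined by the inner stroma.
- **Volumetry** — per-label voxel-count volumes in mm³; the total canal
  volume includes cysts.
- **Agreement metrics** — Dice, absolute/relative volume difference, and
  ICC(2,1) for method comparison.

A digital cervix phantom (two-segment mitre-joined tube with concentric
stromal shells, cysts, optional bladder, plus a T2w-like intensity
renderer) provides exact ground truth — arc length, diameters and
closed-form volumes — for every operator, at any bend angle and
orientation.

## Worked example

```python
import numpy as np
from cervimetry import PhantomSpec, generate_phantom, run_biometry, compute_volumes

# a gently bent cervix: 30 mm two-line length, 3 mm canal radius
spec = PhantomSpec(
    inlet_point=(0, 4, 14), mid_point=(0, 0, 0), outlet_point=(0, 4, -14),
    canal_radius=3.0,
)
labels, truth = generate_phantom(spec)

result = run_biometry(labels)
vols = compute_volumes(labels)
print(f"length   {result.cervical_length_mm:5.2f} mm (truth {truth.length_mm:5.2f})")
print(f"inlet    {result.inlet_diameter_mm:5.2f} mm (truth {truth.inlet_diameter_mm:5.2f})")
print(f"outlet   {result.outlet_diameter_mm:5.2f} mm (truth {truth.outlet_diameter_mm:5.2f})")
print(f"canal    {vols.canal_total_mm3:6.1f} mm3 (truth {truth.canal_total_mm3:6.1f})")
```

prints

```
length   27.51 mm (truth 29.12)
inlet     5.76 mm (truth  6.00)
outlet    5.76 mm (truth  6.00)
canal     837.6 mm3 (truth  823.4)
```

The length sits ~1.6 mm short of truth: the measured midpoint is the canal
centroid, which is pulled slightly inside the bend, and each end
centre-point lies half a voxel inside the open cap — both properties of
the clinical measurement definition itself (see `docs/methods.md`).

## Command line

```sh
cervimetry phantom --out labels.nii.gz --truth truth.json --render t2w.nii.gz
cervimetry biometry labels.nii.gz --out biometry.json
cervimetry volumetry labels.nii.gz --out volumes.json
cervimetry evaluate --pred pred.nii.gz --ref ref.nii.gz --out report.json
cervimetry train --data pairs/ --out model.npz
cervimetry segment t2w.nii.gz --model model.npz --out pred.nii.gz
cervimetry atlas --inputs subjects/ --out atlas.nii.gz
cervimetry charts table.csv --out charts/
```

The charts command reads a CSV with columns `case_id, ga_weeks,
field_strength` plus any of `cervical_length_mm, inlet_diameter_mm,
outlet_diameter_mm, canal_volume_mm3, inner_volume_mm3, outer_volume_mm3`,
fits gestational-age trendlines with empirical 5th/50th/95th centile
bands, and writes one figure + centile CSV per measurement.

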