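# aortascreen

Automatic screening for abdominal aortic aneurysm (AAA) from 3D segmentation
masks. Given per-case label volumes of the aortic lumen and (optionally) the
intraluminal thrombus, the pipeline measures the maximum wall-to-wall diameter
of the abdominal aorta perpendicular to its centerline, the thrombus volume,
and classifies each case against the 30 mm screening threshold. Cohort-level
confusion-matrix metrics (accuracy, sensitivity, specificity) are produced
when reference diameters are available.

## The problem

An abdominal aortic aneurysm is a focal dilation of the abdominal aorta; a
maximum outer diameter above ~30 mm is the common screening criterion, and
rupture risk grows steeply with diameter. Manual measurement on CT is slow
and reader-dependent: the clinically meaningful quantity is the wall-to-wall
diameter measured in the plane *perpendicular to the vessel axis*, which
axial slices only approximate. This package automates the measurement chain
downstream of segmentation:

1. **Fusion + smoothing** — the lumen and thrombus masks are united into a
   whole-aorta model and regularised by morphological closing and opening
   with a 1.5 mm ball.
2. **Axial bounding** — per-slice connected-component counting locates the
   aortic arch (two limbs merging into one, scanning upward) and the iliac
   bifurcation (one component splitting into two, scanning downward); the
   volume is cropped between the two levels.
3. **Centerline** — the cropped lumen is thinned to a skeleton; skeleton
   endpoints seed a minimum-cost path on the interior voxel graph weighted
   by `1/(distance-to-wall)²`, which is then re-centered on
   perpendicular-section centroids, spline-smoothed and resampled at 2.5 mm.
4. **Abdominal isolation** — the centerline is decomposed into branches;
   bifurcation planes are derived at every divergence, the most inferior
   non-iliac plane marks the renal level, and the model is clipped between
   the renal and iliac planes.
5. **Measurement** — cross-sections perpendicular to the abdominal
   centerline are cut every 2.5 mm; each section's wall-to-wall diameter is
   its maximum Feret diameter, and the case measurement is the maximum over
   sections. Thrombus volume is the foreground volume of the thrombus mask
   in mL.
6. **Screening** — a case is classified AAA when the measured diameter
   strictly exceeds 30 mm (configurable); cohort metrics use AAA as the
   positive class.

A synthetic **phantom generator** (`aortascreen.phantoms`) builds
thoraco-abdominal geometries — arched trunk, fusiform bulge, renal and iliac
branches, thrombus annulus — with *analytic* ground truth for every
quantity the pipeline measures, so the whole chain is testable without
clinical data.

## Worked example

Generate a 35 mm aneurysmal phantom and measure it:

```bash
$ aortascreen phantom --diameter 35 --seed 7 --out-dir demo
wrote 1 case (max outer diameter 35.0 mm) to demo

$ aortascreen measure --lumen demo/case_lumen.nii.gz \
      --thrombus demo/case_thrombus.nii.gz --case-id demo --out-dir demo
demo: max diameter 35.4 mm, thrombus 7.9 mL -> AAA
```

This writes `demo/demo_report.json` (diameter, thrombus volume, detected
renal/iliac planes, predicted class) and `demo/demo_sections.csv` (the full
diameter profile along the abdominal centerline). A cohort is screened from
a manifest CSV (`case_id, lumen_path[, thrombus_path, manual_diameter_mm]`):

```bash
aortascreen screen --manifest cohort/manifest.csv --out-dir results
aortascreen metrics --cases results/cohort_cases.csv --threshold 30
```

The same functionality is available as a library:

```python
from aortascreen import measure_case, classify, read_label_volume, split_labels

lumen, thrombus = split_labels(read_label_volume("case.nii.gz"))
result = measure_case(lumen, thrombus)
print(result.max_diameter, result.thrombus_volume_ml, classify(result.max_diameter))
```

## Layout

- `src/aortascreen/volume_io.py` — NIfTI/MetaImage I/O, canonical
  orientation, label handling, isotropic resampling, cohort manifests
- `src/aortascreen/multiview.py` — multi-view probability fusion, Dice
- `src/aortascreen/surface.py` — mask fusion, morphological smoothing,
  antialiased marching-cubes surfaces, plane slicing with capping
- `src/aortascreen/centerline.py` — axial bounds, skeleton, seeds, refined
  centerline
- `src/aortascreen/abdominal.py` — branch splitting, bifurcation planes,
  renal/iliac levels, abdominal clipping
- `src/aortascreen/morphometry.py` — perpendicular sections, Feret
  diameters, thrombus volume, the per-case pipeline
- `src/aortascreen/screening.py` — threshold classification, cohort metrics
  and reports
- `src/aortascreen/phantoms.py` — synthetic phantoms with analytic truth
- `src/aortascreen/cli.py` — `aortascreen measure | screen | phantom | metrics`

See `docs/methods.md` for the measurement model, parameter reference, and
numerical design decisions.
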