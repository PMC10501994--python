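# Methods

This note documents the measurement model, every tunable parameter, the
numerical choices behind the implementation, and known limitations.

## Measurement model

The input is one or two 3D label volumes per case: the aortic lumen and,
when present, the intraluminal thrombus (labels 1 and 2 of a combined file,
or two binary files). All geometry is computed in physical millimetres with
`pos = origin + index * spacing`; files are reoriented on read so that the
third axis points superior.

### Whole-aorta model

The lumen and thrombus masks are fused by voxelwise union. The fused mask is
regularised by morphological **closing followed by opening** with a
Euclidean ball of radius 1.5 mm, implemented with distance transforms so
anisotropic spacing is handled exactly. Closing removes surface pits and
cracks between lumen and thrombus labels; opening removes spikes and
specks. Surfaces are triangulated by marching cubes at the 0.5 level.

Binary marching cubes has a resolution-independent staircase bias: the area
of a voxelized sphere is overestimated by ~8–9% at any spacing. The binary
field is therefore antialiased with a Gaussian of 0.8 voxels per axis
before contouring, which brings sphere area within 0.5% and removes most of
the positive diameter bias. The filter is expressed in voxels because it
corrects a sampling artifact; physical regularisation is the morphology
stage's job.

### Axial bounds (arch and iliac levels)

Scanning axial slices, the ascending and descending limbs of the arch
appear as two 8-connected in-plane components that merge into one at the
top of the bend; the iliac limbs symmetrically split below the bifurcation.
Components smaller than 4 voxels are ignored. The arch level is the most
superior 2-to-1 transition, the iliac level the most inferior one; without
two transitions the bounds degenerate to the full z extent. The volume is
cropped one slice *below* the detected arch merge so the two arch limbs are
actually disconnected (the first merged slice is a one-voxel bridge), and
the largest connected component is kept.

### Centerline

The **raw** cropped lumen (not the smoothed model) is resampled
isotropically and thinned to a voxel skeleton. Smoothing before thinning is
harmful: the closing/opening slightly erodes thin side branches (e.g. 3 mm
renal stubs) below the thickness the thinning algorithm preserves, which
silently deletes their endpoints. Terminal skeleton limbs shorter than 5 mm
are pruned (up to 3 passes); endpoints are skeleton voxels with fewer than
two foreground 26-neighbors. The **source seed** is the endpoint with the
highest z (descending side of the arch after the crop); all other endpoints
are targets.

For each target, the centerline is the minimum-cost path on the 26-connected
interior voxel graph of the *smoothed fused* model, with edge cost
`step_length * (w(u)+w(v))/2` where `w = 1/(DT + 0.01)²` and DT is the
Euclidean distance-to-wall in mm. This presses paths onto the medial axis.
Each path is then:

1. **re-centered**: every point is moved to the centroid of the in-plane
   connected lumen region of its perpendicular cross-section. A centroid
   shift larger than max(local inscribed radius, one voxel) is rejected as
   corrupted sampling (this happens when the plane grazes a clip boundary);
2. **spline-smoothed**: a cubic smoothing spline with penalty
   `s = n·(0.4·smooth_factor)²` and the two endpoints weighted 1000× (free
   ends of a smoothing spline can hook, corrupting terminal tangents);
3. **resampled** at equal arc-length steps of 2.5 mm.

The maximal inscribed radius at each point uses the 1-Lipschitz bound
`max_v [DT(v) − |p − v|]` over the 8 surrounding voxel centers minus half a
voxel (linear interpolation of DT underestimates on the medial ridge).

### Abdominal isolation

The multi-target paths share exact voxel prefixes; splitting at the
divergences yields a branch tree with junctions. For every divergence a
**bifurcation plane** is placed where the departing child leaves the parent
vessel (first child point farther from the trunk polyline than the local
trunk radius), with the trunk tangent as normal. Planes whose junction lies
within one local vessel radius of the centerline's inferior terminus belong
to the iliac split; the **renal plane** is the most inferior remaining
plane ("the last take-off above the iliacs"). When the iliac split does not
survive inside the crop, the iliac plane is anchored on the trunk at the
slice-detected iliac z, with the chord over the last two local radii as
normal (the end tangent itself curls inside the merged limb region). If no
renal candidate exists, a fallback plane 90 mm above the iliac plane is
used and flagged in the diagnostics.

The surface is clipped by the renal plane (normal facing inferior) and the
iliac plane (normal facing superior); cut rings are capped by centroid fans
(cross-sections are star-shaped, so the fan is valid). The abdominal
centerline is recomputed between the two plane origins on the clipped
interior mask.

### Sections and diameter

Cross-sections are cut perpendicular to the abdominal centerline every
2.5 mm (terminal stations are inset 0.5 mm so no cutting plane is coplanar
with a clip cap). Of each planar intersection only the loop containing the
centerline point is kept. Stations are skipped when their plane intersects
a detected **side-branch exclusion tube** (renal ostium remnants below the
renal plane would otherwise widen the contour) or falls within one median
vessel radius of the iliac end (the limb-split saddle is not a single-tube
cross-section). The **wall-to-wall diameter** of a section is its maximum
Feret diameter — the largest pairwise distance between contour points,
computed on the convex hull; the equivalent-circle diameter `2√(area/π)` is
reported alongside. The case measurement is the maximum over sections.
**Thrombus volume** is the foreground voxel count times the voxel volume,
in mL.

### Screening

A case is AAA iff its measured maximum diameter **strictly exceeds** the
threshold (default 30 mm); a measurement exactly at the threshold is a
control. AAA is the positive class. Reported percentages are rounded to
integers; rates with zero denominators are reported as missing, never as 0.
Summary statistics use the sample SD (n−1) and linear-interpolation
percentiles.

## Parameter reference

| Parameter | Default | Unit | Meaning |
|---|---|---|---|
| `smoothing_radius_mm` | 1.5 | mm | ball radius of closing+opening |
| `presmooth_sigma_vox` | 0.8 | voxels | marching-cubes antialiasing sigma |
| `resampling_step` | 2.5 | mm | centerline arc-length step |
| `smooth_factor` | 0.5 | – | spline smoothing in [0, 1] |
| `prune_mm` | 5.0 | mm | minimum skeleton limb length |
| `section_step_mm` | = resampling step | mm | spacing of perpendicular sections |
| `renal_fallback_offset_mm` | 90.0 | mm | renal plane height above iliac plane when no bifurcation is found |
| `threshold_mm` | 30.0 | mm | AAA decision threshold (strict >) |
| `min_component_voxels` | 4 | voxels | in-slice component size for axial bounds |

All of these are exposed through `PipelineConfig` / `CenterlineParams` /
`ScreeningConfig` and the CLI's YAML config + flags.

## Phantoms

Phantoms are generalized cylinders around a parametric trunk: straight,
arched "candy-cane" (ascending stub, semicircular bend of radius 25 mm
topping at z = 215 mm, descending trunk to the iliac apex at z = 25 mm), or
explicit control points. The lumen radius profile is a baseline plus an
optional Gaussian bulge; thrombus is the annulus between the lumen and an
outer Gaussian thickness profile. Side branches are straight tubes (renal
pair at z = 115 mm, nearly lateral; iliac pair at 50° from vertical). A
voxel is foreground iff its distance to the densely sampled curve is at
most the local radius. The trunk lumen is clipped flat at the iliac apex so
the limbs — not a rounded end-cap — fill the space below the bifurcation,
keeping the analytic limb-separation level valid.

The analytic truth record carries the exact maximum outer diameter and its
location, the thrombus volume as a trapezoid integral of the annulus area
at 0.01 mm arc step, the centerline polyline, and the branch/arch z levels,
including the *detectable* levels (slice-wise merge at `apex − r`,
limb separation at `apex − r_limb/lateral_rate`).

**Realism limits.** Phantoms have circular cross-sections, piecewise-smooth
geometry, binary masks without segmentation noise (optional radial jitter
exists but is off by default), no calcifications, no tortuosity beyond the
arch bend, and branch counts fixed by the spec. They validate geometry
recovery, not segmentation robustness.

## Verified accuracy (synthetic)

On the standard candy-cane phantom at 0.75 mm isotropic spacing: maximum
diameter errors +0.05…+0.57 mm over the 18–90 mm range; renal plane within
3.2 mm and iliac plane within 2.8 mm of the analytic branch levels; the
abdominal clip removes >99% of the surface area above the renal level;
measured thrombus volumes match the analytic annulus integral to <0.1%;
centerline deviation on a cylinder+quarter-torus ≤0.35 mm with arc length
within 0.04%.

## Known limitations

- **Distal aneurysms**: sections within one median vessel radius of the
  iliac end are excluded (limb-split saddle). An aneurysm whose maximum
  lies exactly at the aorto-iliac junction would be partially masked and
  could be under-measured.
- **Oblique acquisitions**: volumes with non-diagonal orientation matrices
  are rejected rather than resampled; reorient upstream.
- **Renal-level definition**: the renal plane is the most inferior non-iliac
  *detected* bifurcation; accessory renal arteries or segmentation stubs
  below the true renal level shift the plane caudally.
- **Single aorta assumption**: the pipeline keeps the largest connected
  component after cropping; disconnected segmentation fragments are
  silently dropped.
- **Fan capping** assumes cut rings are star-shaped about their centroid;
  true for vessel cross-sections, not for arbitrary geometry.
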