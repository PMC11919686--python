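# memcurve

Membrane-curvature morphometrics for cryo-electron tomography and
cryo-EM. The package quantifies how a membrane-remodeling protein coat
(an ESCRT-III-family assembly such as Vipp1) occupies membranes as a
function of membrane curvature, and provides the companion map analyses:
cyclic-symmetry determination of ring densities and radial/axial
profiling of membrane-containing tube reconstructions.

It is written for structural biologists who have segmented tomograms
(membrane/coat label volumes in MRC format) or density maps and want the
downstream quantitative analyses without a GUI pipeline:

* **Coat occupancy vs. curvedness** — clean the segmentation (drop
  islands of < 150 voxels), extract a membrane mid-surface, estimate
  principal curvatures per point by local quadric fitting, mark points
  within 50 Å of the coat class, bin them by curvedness
  C = √((k₁² + k₂²)/2) and fit a linear-ramp-plus-plateau saturation
  model O(C) = clamp(a + b·min(C, c*)).
* **Particle preparation** — seed subtomogram particles from the
  surface points: ≥ 15 Å interparticle spacing, ZYZ Euler priors from
  membrane normals, k-means clustering by curvedness, local
  orientation-consensus outlier rejection.
* **Cn symmetry search** — find the cyclic symmetry of a full ring or
  an off-axis patch by maximizing the Pearson correlation between a map
  and its Cₙ-averaged copies over the order n, the axis offset along x
  (1-Å steps) and the rotation register.
* **Tube profiles** — radial density profiles about the tube axis;
  bilayer leaflet radii at the two innermost density peaks and their
  peak-to-peak thickness; outer diameter at the outward half-maximum
  crossing; per-slice leaflet traces with constriction extrema and the
  kink angle between flank fits.

A synthetic-scene generator (`memcurve.synthetic_scenes`) produces
coated-vesicle label volumes, bilayer-tube and Cn-ring density maps with
exact ground truth, so the whole pipeline is testable without any
downloads.

## Worked example

Generate a field of 30 coated vesicles whose coat coverage follows a
curvature ramp (zero below 0.02 nm⁻¹, linear up to full coverage at
0.06 nm⁻¹) and run the occupancy workflow:

```python
import numpy as np
from memcurve import synthetic_scenes as syn
from memcurve.pipelines import run_occupancy
from memcurve.coat_occupancy import saturation_diameter_nm

curv = np.linspace(0.016, 0.088, 30)              # true curvedness, nm^-1
vol, truth = syn.make_vesicle_scene(10.0 / curv,  # radii in Angstroms
                                    c_lo=0.02, c_hi=0.06, seed=1)
profile, fit, particles = run_occupancy(vol)
print(f"fitted ramp slope      : {fit.slope:.1f} per nm^-1")
print(f"saturation breakpoint  : {fit.breakpoint:.3f} nm^-1")
print(f"plateau occupancy      : {fit.plateau:.3f}")
print(f"saturation diameter    : {saturation_diameter_nm(fit.breakpoint):.1f} nm")
print(f"particles prepared     : {len(particles)}")
```

prints

```
fitted ramp slope      : 21.8 per nm^-1
saturation breakpoint  : 0.064 nm^-1
plateau occupancy      : 0.988
saturation diameter    : 31.2 nm
particles prepared     : 19622
```

The fitted breakpoint lands within one bin width (0.004 nm⁻¹) of the
generator's ramp end at 0.06 nm⁻¹, and the plateau within ~1% of full
coverage. The saturation diameter is the vesicle diameter 2/C at the
breakpoint: occupancy stops growing for vesicles smaller than roughly
30 nm, which is the physically interesting readout — the coat prefers,
and saturates on, highly curved membranes.

The same stages are available from the shell:

```sh
memcurve simulate vesicles --out scene.mrc --seed 1
memcurve occupancy scene.mrc --out occupancy_out
memcurve simulate cnmap --out ring.mrc --n 20 --ring-radius 110 --wedge 150
memcurve symsearch ring.mrc --n 18:22 --offset 95:125:1 --out sym_out
memcurve tubeprof tube.mrc --trace --out prof_out
```

Every output directory receives the TSV tables plus a
`provenance.json` recording the full parameter set and input checksums.

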