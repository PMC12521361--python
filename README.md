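# tibmorph

Standardized analysis of trabecular bone compartments in micro-CT scans of
the mouse proximal tibia.

Preclinical bone studies (PTH dosing, mechanical loading, ageing) measure
trabecular morphometry — bone volume fraction BV/TV, trabecular thickness
Tb.Th, trabecular separation Tb.Sp — inside a volume of interest (VOI) of
the tibial metaphysis. The conventional way to place that VOI, a fixed
offset below the growth plate, silently mixes anatomically different
compartments when treatment shifts the compartment boundaries, and can turn
an anatomical shift into a spurious "treatment effect". `tibmorph`
implements an anatomy-anchored alternative: classify every transverse slice
into one of four compartments — epiphyseal bone (C=0), growth plate (C=1),
primary spongiosa (C=2), secondary spongiosa (C=3) — and place VOIs at the
transitional landmarks between them.

The core is the **regional probability distribution** method. A slice
classifier emits per-slice class probabilities P(z, C) (softmax over four
logits); after rolling-median smoothing (window 0.05 mm) the three
landmarks are the equality points of adjacent class probabilities along
the tibial axis (z = 0 proximal):

    Z_eg = min z  where  P(z, C=0) = P(z, C=1)   (scanned proximal→distal)
    Z_gp = min z  where  P(z, C=1) = P(z, C=2)   (within (Z_eg, Z_ps))
    Z_ps = min z  where  P(z, C=2) = P(z, C=3)   (scanned distal→proximal)

Standard VOIs hang off these landmarks: the secondary spongiosa from Z_ps
to 1 mm distally, the mixed primary–secondary spongiosa from Z_gp to 1 mm
distally, and the epiphyseal trabecular bone from Z_eg to 0.25 mm
proximally. Morphometry uses Hildebrand–Rüegsegger local thickness
(largest inscribed sphere, computed by a fast distance-ridge /
sphere-painting scheme) both in 3D and depth-resolved in 20 µm bins, with
one-way ANOVA + Tukey HSD (3D) and per-bin ANOVA + Games–Howell with a
four-color significance code (2D). Landmark agreement is judged by paired
TOST equivalence within ±0.05 mm and ICC(2,1).

Because real scan cohorts of this kind are not freely redistributable, the
package ships a synthetic tibia **phantom generator**: four compartments
inside an annular cortical shell, trabecular texture from thresholded
Gaussian random fields calibrated to target BV/TV and Tb.Th, undulating
growth-plate boundaries, noise, optional rigid misalignment — with
voxel-level ground-truth labels and landmark planes. Every stage of the
pipeline is tested end-to-end against this ground truth.

## Worked example

```python
from tibmorph import (prepare_slices, train_classifier,
                      predict_probabilities, smooth_profile,
                      detect_landmarks, VOISpec, extract_voi,
                      morphometry_3d, phantom_cohort)
from tibmorph.pipeline import slice_ground_truth

# train on a small cohort of 10 µm phantoms
X, y = [], []
for _, vol, truth in phantom_cohort(6, seed=1):
    X.extend(prepare_slices(vol))
    y.extend(slice_ground_truth(truth))
clf = train_classifier(X, y)

# detect landmarks on a held-out phantom
spec, vol, truth = phantom_cohort(1, seed=99)[0]
profile = predict_probabilities(clf, prepare_slices(vol), vol.voxel_size_mm)
lms = detect_landmarks(smooth_profile(profile))
print("detected:", {k: round(float(v), 3) for k, v in lms.to_dict().items()
                    if v is not None and not isinstance(v, list)})
print("truth:   ", {k: v for k, v in truth.true_landmarks.items()
                    if isinstance(v, float)})

# morphometry of a 0.5 mm Z_ps-anchored secondary-spongiosa VOI
# (0.5 mm because the coarse demo phantom is shorter than a real tibia;
# on 5 µm scans use VOISpec.preset("secondary") for the standard 1 mm)
sub, masks, _ = extract_voi(vol, lms, VOISpec("secondary", "Z_ps", 0.0, 0.5),
                            masks={"trab": truth.trabecular_mask,
                                   "med": truth.medullary_mask})
res = morphometry_3d(masks["trab"], masks["med"], vol.voxel_size_mm)
print(f"BV/TV {res.bvtv_pct:.1f}%  Tb.Th {res.tbth_um:.0f} µm  "
      f"Tb.Sp {res.tbsp_um:.0f} µm")
```

prints (exact values vary with the phantom seed):

```
detected: {'Z_eg': 0.394, 'Z_gp': 0.5, 'Z_ps': 0.805}
truth:    {'Z_eg': 0.4, 'Z_gp': 0.5, 'Z_ps': 0.8}
BV/TV 11.7%  Tb.Th 52 µm  Tb.Sp 167 µm
```

i.e. all three landmarks recovered within the ±0.05 mm equivalence bound
(worst error here 6 µm), and the secondary-spongiosa VOI reproduces the
phantom's target texture (BV/TV ≈ 12 %, Tb.Th ≈ 50 µm at 10 µm voxels).

A command-line interface mirrors the library
(`tibmorph phantom | prep | train | predict | landmarks | voi | morph |
stats | run`); `tibmorph run --out-dir out --seed 1` executes the whole
phantom demo pipeline and writes landmarks JSON, morphometry CSVs, TOST
results and a manifest.

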