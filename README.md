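# polseg — polarimetric segmentation of radiofrequency-ablation lesions

Radiofrequency ablation (RFA) of arrhythmogenic myocardium leaves a lesion
with three clinically distinct zones: a necrotic **core**, a surrounding
**rim** of intermixed viable and non-viable cardiomyocytes (the zone that
decides whether the arrhythmia recurs), and **healthy** tissue.  Mueller-matrix
polarimetry can see this structure: thermal coagulation homogenizes the
tissue's anisotropic micro-domains, so ablated tissue depolarizes light
*less* than healthy myocardium, with intermediate values in the rim.

`polseg` implements the full analysis from raw polarization-resolved
intensities to validated zone maps, for researchers working with tissue
polarimetry or evaluating multi-region segmentation of parametric images:

1. **Polarimetry** — a polarization-state generator cycles 4 input states
   (H, V, +45°, right-circular) and an analyzer projects onto 6 output
   states, giving 24 intensity images `I(g, a) = ½(S₀ + S·a)` with
   `S = M s(g)`.  The per-pixel Mueller matrix **M** is recovered from
   Stokes differences of these intensities, and the Lu–Chipman polar
   decomposition `M = M_Δ M_R M_D` yields the total depolarization
   `Δ_T = 1 − |tr m_Δ|/3 ∈ [0, 1]` (plus retardance and diattenuation).
2. **Segmentation** — *local fuzzy thresholding*: the tissue histogram is
   modelled as an L-component Gaussian mixture `h(I) ≈ Σ_l w_l p_l(x; θ_l)`
   fitted by EM (L = 3); each pixel gets a fuzzy membership vector (the
   posterior responsibility), memberships are averaged over each pixel's
   spatial neighborhood, and the argmax labels the pixel.  A *global rigid
   thresholding* baseline classifies by fixed cut-offs derived from 50×50
   per-zone ROI means.
3. **Evaluation** — per-class Dice similarity `DSC = 2|GT∩A|/(|GT|+|A|)`,
   sensitivity, specificity and accuracy (one-vs-rest over tissue pixels),
   normalized zone areas, through-origin regression slopes and Bland–Altman
   limits of agreement.
4. **Synthetic phantoms** — labeled three-zone lesions whose per-zone
   depolarization statistics default to 83.3 ± 3.5 % (core), 87.7 ± 1.4 %
   (rim) and 91.5 ± 1.3 % (healthy), with gradual inter-zone transitions
   and a dark background, so the whole pipeline is testable without any
   measured data.

## Worked example

```python
import polseg as ps

# a labeled synthetic lesion with the default zone statistics
phantom = ps.generate(ps.PhantomSpec(), seed=42, with_images=True)

# measurement chain: 24 intensities -> Mueller -> polar decomposition
rec = ps.reconstruct_mueller(phantom.images)
dec = ps.polar_decompose(rec, mask=phantom.delta.mask)
dmap = ps.depolarization_map(dec, phantom.delta.mask)

# local fuzzy thresholding and validation against ground truth
labels = ps.segment_local_fuzzy(dmap)
for cls, name in ((ps.LABEL_CORE, "core"), (ps.LABEL_RIM, "rim")):
    cm = ps.confusion(phantom.gt, labels, cls)
    print(f"{name}: DSC={cm.dsc:.3f}  Sn={cm.sensitivity:.3f}")
```

prints

```
core: DSC=0.984  Sn=0.970
rim: DSC=0.913  Sn=0.999
```

i.e. the fuzzy segmentation recovers the necrotic core and the thin rim
annulus almost perfectly on the default phantom; both numbers comfortably
exceed the agreement levels reported for expert histopathology ground truth
on real ablated myocardium, as they should on a phantom that matches the
model's assumptions exactly.

The same workflow is scriptable from the shell:

```bash
polseg simulate --seed 42 --with-images --outdir phantom/
polseg decompose --indir phantom/images --out phantom/delta_measured.tif
polseg segment --input phantom/delta_measured.tif --method fuzzy --out labels.tif
polseg evaluate --gt phantom/gt_labels.tif --pred labels.tif --out metrics.csv
polseg run --delta phantom/delta.tif --gt phantom/gt_labels.tif --outdir report/
```

## Analysis scripts

The `analysis/` drivers reproduce the study narrative end to end on a
five-phantom cohort and write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_phantoms.py` | generates the cohort; verifies interior zone means/SDs |
| `02_polarimetry_roundtrip.py` | measurement-chain accuracy vs intensity noise |
| `03_segment_cohort.py` | fuzzy vs global metrics tables; isolated-pixel counts |
| `04_area_agreement.py` | normalized areas, regression slopes, Bland–Altman |

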