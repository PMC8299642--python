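# tuberphen

Non-invasive phenotyping of potato (*Solanum tuberosum*) under water
deficit, for plant physiologists and phenotyping-platform engineers who
need the computational side of a pot-trial workflow: shoot morphology from
RGB cameras, leaf tissue water status from bench-top NMR relaxometry, and
underground tuber growth from 3-D MRI — each testable end-to-end against
seeded synthetic fixtures with known ground truth.

## What it computes

**Shoot traits (`tuberphen.rgb_traits`).** Plant foreground is segmented by
the Excess Green index,

    ExG = (2G − (R + B)) / (R + G + B),

(Otsu threshold, morphological cleaning, minimum component size), then the
standard architecture traits are extracted per image and assembled into
series over days after shoot emergence (DASE): projected area, convex hull
area (hull over unit pixel squares, so hull ≥ projected always), side-view
height/width, and mean ExG over the mask.

**T2 relaxometry (`tuberphen.relaxometry`).** A CPMG echo train
S(t_k) = Σⱼ fⱼ exp(−t_k/T2ⱼ) + c + ε, t_k = 2kτ (τ = 0.2 ms), is inverted
into a nonnegative T2 spectrum f on a log grid by maximum-entropy
regularisation — maximise −Σ fⱼ ln(fⱼ/mⱼ) subject to χ² ≈ K — with an
independent Tikhonov-NNLS solver as cross-check. Spectral peaks are water
pools in distinct cell compartments; the longest-T2, highest-intensity
peak(s) are vacuolar. A single vacuolar peak (vt) in young leaves splits
into spongy (vs) and palisade (vl) components as the mesophyll
differentiates; `detect_split_merge` locates these transitions along leaf
development, and replicates are averaged only within groups having the same
component count.

**MRI tuber volumetry (`tuberphen.mri_volumetry`).** Manually seeded tubers
in (Z, Y, X) MR volumes (voxel 1.1 × 1.0 × 1.0 mm) are grown to all
connected voxels within μ_seed ± 2.5 σ_seed, counted (26-connectivity),
measured (volume in cm³, equivalent-sphere diameter (6V/π)^(1/3), centroid),
tracked across imaging sessions by nearest-centroid matching, filtered by
the diameter rules (3 mm detectability; tubers under 15 mm at the final
session carry no yield and are dropped from all sessions), and summarised
per condition with ANOVA + Tukey HSD letters.

**Physiology (`tuberphen.physiology`).** RWC = (fresh−dry)/(turgid−dry),
LWD = 1 − RWC; gravimetric watering to a target fraction of field capacity
(70 / 40 / 20 % for Control / mild / severe deficit); the Tukey
compact-letter display used throughout.

**Fixtures (`tuberphen.synthetic_fixtures`).** Seeded generators for all
three modalities (procedural plants on logistic growth curves, leaf T2
component schedules with developmental splits, multi-session MRI scenes
with a depleting mother tuber), each returning ground truth — no external
data needed anywhere in the test suite.

## Worked example

Invert a simulated leaf decay (short-T2 cytoplasm/wall pool plus split
vacuolar components, SNR 10³) and label the vacuolar peaks:

```python
from tuberphen.relaxometry import (simulate_cpmg, invert_mem,
                                   find_peaks, assign_vacuolar)

decay = simulate_cpmg([(130, 0.35), (600, 0.45), (5, 0.2)],
                      tau=0.2, n_echoes=4000, noise_sigma=1e-3, seed=7)
dist = invert_mem(decay)
peaks = find_peaks(dist)
print(f"chi2/K = {dist.chi2_per_echo:.3f}")
for p in peaks:
    print(f"peak at T2 = {p.t2_mode:6.1f} ms, area fraction = {p.area_fraction:.3f}")
for name, p in sorted(assign_vacuolar(peaks).labels.items()):
    print(f"{name}: {p.t2_mode:.1f} ms")
```

prints

```
chi2/K = 0.985
peak at T2 =    4.9 ms, area fraction = 0.200
peak at T2 =  130.0 ms, area fraction = 0.346
peak at T2 =  597.2 ms, area fraction = 0.454
vl: 597.2 ms
vs: 130.0 ms
```

All three generating components are recovered (modes within one grid step,
area fractions within 0.01 of truth), the fit sits at the discrepancy
target (χ²/K ≈ 1), and the two long-T2 peaks are labelled spongy (vs) /
palisade (vl) vacuolar water.

The same pipelines are scriptable from the shell, e.g.

```sh
tuberphen simulate mri --seed 1 --out scene/
tuberphen mri-segment --volume scene/vol_d073.nii --seeds scene/seeds_d073.nii --out seg73/
tuberphen t2sim --components "40:0.4,400:0.6" --tau 0.2 --echoes 2000 --sigma 1e-3 --seed 7 --out decay.csv
tuberphen water --pots pots.csv --regime MWD
```

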