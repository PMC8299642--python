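# Methods

`tuberphen` implements the computational core of a non-invasive,
multi-modal phenotyping workflow for potted potato plants under water
deficit: RGB shoot-trait extraction, inverse-Laplace analysis of CPMG
transverse-relaxation decays in leaves, and 3-D MRI tuber volumetry with
longitudinal tracking, plus the small physiological utilities (leaf water
status, gravimetric watering, Tukey letter displays) the workflow leans on.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic fixtures do and do not emulate.

## Shoot traits from RGB images (`rgb_traits`)

**Model.** Foreground is defined by the Excess Green index,
ExG = (2G − R − B)/(R + G + B), which is ~0 for achromatic soil/background
and large for chlorophyll-rich pixels (bounds: −1 for pure red/blue, +2 for
pure green). Black pixels (R+G+B = 0) are assigned ExG = 0 by convention
(configurable in principle: they are background in this imaging geometry).

**Reference segmenter.** The imaging platforms this emulates use learned
segmentation models that are not published; the reference implementation is
deliberately simple and fully documented: per-pixel ExG → Otsu threshold
(fixed threshold 0.10 when the ExG map is flat or Otsu is disabled; the
Otsu value can be floored by `min_threshold`) → 3×3 morphological opening
then closing → retain connected components covering ≥ 0.5 % of the frame.
`build_trait_series` accepts any callable `RgbImage -> PlantMask`, so a
learned segmenter can be dropped in without touching the trait code.

**Trait conventions.** Pixels are unit squares; the convex hull is taken
over the four corners of every foreground pixel, so a single pixel has hull
area 1 and projected area never exceeds hull area. Height/width are
bounding-box extents (side view). Mean ExG is averaged over the plant mask
by default (whole-frame mode by flag): the alternative conventions differ
only by the background's near-zero contribution, but the masked mean is the
one that tracks leaf colour rather than plant size. Without a camera
calibration all outputs are px/px²; a mm-per-pixel scale converts them.

## CPMG inversion (`relaxometry`)

**Model.** A CPMG train samples S(t_k) at t_k = 2kτ (default τ = 0.2 ms).
In vacuolated tissue the decay is multi-exponential,
S(t) = Σ_j f_j exp(−t/T2_j) + c + ε, and the inverse problem is to recover
the nonnegative spectrum f on a log grid. Two independent solvers are
provided; their agreement on peak count is a standing cross-check.

* **Maximum entropy (`invert_mem`).** Maximise the Shannon–Jaynes entropy
  −Σ f_j ln(f_j/m_j) subject to the χ² discrepancy χ² ≈ K, via a Lagrange
  multiplier α found by log-space bisection (inner problems solved by
  L-BFGS-B with analytic gradients, warm-started along the α path). The
  prior is flat at m_j = 0.01·S0/n: with the conventional m_j = S0/n,
  bins the data cannot constrain (very short T2) drift toward the prior
  level and masquerade as peaks; at 0.01·S0/n unconstrained bins rest near
  zero while the entropy still provides smoothing. An unpenalised constant
  baseline c (instrument offset) is fitted by default.
* **Tikhonov NNLS (`invert_nnls_tikhonov`).** min_{f≥0} ‖(Kf − y)/σ‖² +
  λ‖f‖², with λ chosen by the discrepancy principle when not supplied.
  The L2 penalty spreads mass across the near-collinear kernel columns,
  giving smooth lobes comparable to the MEM output.

**Echo compression.** Both solvers first average the echoes into 150
log-spaced windows, averaging the kernel rows identically (exact for the
multi-exponential model) and propagating the noise as σ/√n_window. This is
standard practice for inverse-Laplace fitting of long echo trains: the tail
windows gain precision, the solver has ~150 well-conditioned points instead
of thousands of noisy ones to chase, and runtime drops accordingly.
`n_windows=None` disables compression.

**Goodness of fit.** The discrepancy search targets χ² = K on the
compressed design, but the reported `chi2_per_echo` is evaluated on the
full uncompressed train, where χ²/K concentrates tightly (sd ≈ √(2/K));
accepted fits must land in [0.8, 1.2]. For effectively noiseless input the
working σ is floored at 1e-4·S0 — the scale of the error made representing
an off-grid exponential on a 200-point log grid — and the acceptance band
becomes one-sided (a fit *better* than the target is fine).

**Grid.** `T2Grid.log_spaced()` spans [0.1, 3000] ms with 200 points
(≈ 5 % per step), covering bound water through late-senescence vacuoles.
The inverters default to a grid starting at the *first echo time* instead:
relaxation faster than the first recorded point is unobservable, and bins
below it only absorb first-echo noise.

**Noise.** σ is taken from the decay metadata when present, otherwise
estimated as the sd of the last 5 % of echoes about their mean (valid when
the signal has decayed there; an error is raised for short trains).

**Peaks.** Local maxima with topographic prominence ≥ 5 % of the spectrum
maximum; support bounded by the inter-peak minima (valley bins assigned to
the right-hand peak, so peak areas partition the total); adjacent maxima
whose modes are within a factor 1.5 in T2 are merged — exponentials closer
than ~1.5× are below the physical resolution of inverse-Laplace inversion,
so separate reporting would be spurious structure. Peaks below 1 % of the
total area are dropped. Peak areas are sums of the discrete bin amplitudes,
so the total area plus offset extrapolates S(0).

**Vacuolar assignment.** Candidate vacuolar peaks have mode > 30 ms and
area fraction ≥ 0.15 (the vacuole is the dominant, longest-T2 pool). Two or
more candidates → the two longest are spongy (vs) / palisade (vl); exactly
one → undifferentiated (vt); none → the longest peak as vt (dehydrated
tissue fallback). The 30 ms floor and 0.15 dominance threshold
operationalise "longest T2, highest intensity", which has no published
quantitative form. Split/merge events are component-count transitions
(1→2 split, 2→1 merge) along a DASE-ordered trajectory; replicate averaging
is done only within groups with the same component count, since averaging a
one-peak with a two-peak spectrum is meaningless.

## MRI tuber volumetry (`mri_volumetry`)

**Conventions.** Volumes are (Z, Y, X) with voxel size (1.1, 1.0, 1.0) mm
by default; physical coordinates are voxel index × voxel size at voxel
centres; connectivity defaults to 26 (the 3-D object-counter convention),
6 by flag.

**Seeded growing.** Each seed's voxels define μ ± k·σ (k = 2.5 default);
the grown region is the in-band voxel set connected to the seed, plus a
binary-closing smoothing pass. A voxel claimed by two fronts goes to the
label with the smaller seed z-score, ties to the lower label. A seed that
grows nowhere (e.g. placed on background, or a single-voxel seed whose σ is
degenerate) returns itself with a warning. Manual corrections are applied
deterministically from add/remove voxel lists after growing.

**Measures.** Volume = voxel count × voxel volume; "diameter" is the
equivalent-sphere diameter (6V/π)^(1/3). Objects under 3 mm diameter are
flagged sub-detectable; tubers strictly under 15 mm at the final session are
excluded from every session (they contribute no yield). Both cut-offs are
strict, so exactly 15.0 mm is retained. A track with no final-session record
is an error by default; `allow_missing_final` excludes it instead, the
right treatment for the mother tuber, which is depleted before the last
session.

**Tracking.** Pots are repositioned identically between sessions, so tubers
barely move; identities are linked by greedy nearest-centroid matching
within 15 mm, ties resolved by distance, unmatched objects starting new
tracks. Tracks are ranked Tuber-01.. by final-session volume descending.
Condition summaries (mean ± se of count and total volume per DASE) carry
Tukey letters via `physiology.anova_tukey_letters`; letters are suppressed
when any condition has fewer than two plants.

## Physiology utilities (`physiology`)

RWC = (fresh − dry)/(turgid − dry), LWD = 1 − RWC (their sum is exactly 1);
invalid weight orderings are rejected. Watering: target mass = tare + dry
soil + fraction × field-capacity water; the amount to add is clamped at
zero (water is never removed). Standard regimes: 70 % (Control), 40 %
(MWD), 20 % (SWD) of field capacity. Osmotic potential at full turgor uses
the Van't Hoff dilution correction ψπ(full turgor) = ψπ(RWC) × RWC — an
assumption (ideal osmotic behaviour, no solute exchange), not a measured
relation. The ANOVA + Tukey HSD letter display delegates the pairwise tests
to statsmodels and builds compact letters by insert-and-absorb; the
degenerate zero-variance case is handled explicitly (identical constant
groups are "not different", distinct constant groups are).

## Synthetic fixtures (`synthetic_fixtures`)

Every generator is a pure function of its scenario (seed included):
regeneration is bit-identical, and ground truth is returned with the data.

* **Plant images.** Random-walk stems plus elliptical leaflets in green hues
  (G ≈ 150–220) over a grey-brown textured background (≈ (120, 100, 80),
  ExG ≈ 0), silhouette area following a logistic curve (default max
  8000 px ≈ 12 % of a 256² frame, rate 0.18/day, midpoint 30 DASE). The
  drawing loop adds leaflets until the target area is met, so mask areas
  track the curve within ~10 %. Not emulated: leaf occlusion by pots/stakes,
  specular highlights, shadows, soil-colour drift — real-image segmentation
  is harder than these fixtures.
* **Leaf T2 series.** Per-DASE component lists: a short-T2 pool (5 ms,
  fraction 0.25) plus one vacuolar component before the split (T2 rising
  180→280 ms) and two after (vs stable at 130 ms, fraction 0.30; vl rising
  550→700 ms), at SNR 10³ relative to S(0). The vl/vs ratio > 4 puts the
  scenario in the well-separated regime; an explicit per-DASE count schedule
  enables merge/split/merge sequences. No printed T2 values exist for this
  system, so these encode the qualitative pattern only. Not emulated:
  diffusion exchange between compartments, T2 shortening by dehydration
  within a session, hardware drift.
* **MRI scenes.** Voxelised ellipsoids (volume-preserving ±10 % random
  anisotropy) at fixed centres, logistic volume growth, a central mother
  tuber shrinking linearly to zero at the final session, object intensity
  200 vs background 50 with Gaussian noise sd 15 (contrast-to-noise 10).
  Seeds are eroded object cores on the one or two central slices. The
  default scene is scaled down from the real acquisition (48×96×96 voxels
  vs 192×256×256; final volumes 0.4–8 cm³) so Monte-Carlo batteries run in
  minutes; the geometry deliberately straddles the 15 mm yield cut-off.
  Not emulated: partial-volume effects, bias fields, soil-moisture contrast
  changes between sessions, roots/stolons touching tubers — so passing Dice
  here bounds the method's behaviour on clean contrast, not on hard real
  volumes.

## Known limitations

* The ExG/Otsu reference segmenter assumes green-on-neutral scenes; it is a
  stand-in interface for learned segmenters, not a competitor.
* Inverse-Laplace inversion cannot resolve T2 ratios ≲ 1.5 at realistic
  SNR; `find_peaks` enforces this honestly rather than reporting spurious
  splittings, which also means a genuine ratio-1.4 doublet would be
  reported as one peak.
* The MEM variant here (flat low prior, discrepancy bisection, offset term,
  echo compression) is a defensible modern formulation, not a
  reconstruction of any particular historical implementation.
* Region growing assumes near-uniform object intensity; strong bias fields
  would require pre-correction (out of scope).
* Tracking assumes displacements below the matching radius; repotting or
  large soil settling would break identity.
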