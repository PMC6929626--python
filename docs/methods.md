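# Methods

This note records the models implemented in `betaquant`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
phantom does and does not establish about real data.

## MR quantification

**Signal model.** Spoiled gradient-echo steady state with ideal spoiling:
S = M0 sin α (1−E1)/(1−E1 cos α), E1 = exp(−TR/T1), at TR = 10 ms,
TE = 1.9 ms. TE decay is folded into M0 (TE is short against tissue T2*),
so M0 is an *apparent* equilibrium signal; no B1 correction is applied —
flip angles are taken as nominal.

**T1 fitting (`fit_t1_vfa`).** The model is linearized as
S/sin α = E1 · S/tan α + M0(1−E1). With two angles (4°, 22°) this line is
exactly determined and the solution is closed-form. With three angles
(4°, 14°, 27°) the linearized least-squares estimate seeds a nonlinear
polish: M0 is profiled out analytically and the residual sum of squares is
minimized over T1 by golden-section search, vectorized over all voxels,
bracketed at [T1ₗᵢₙ/3, 3·T1ₗᵢₙ] (full window [0.01, 10] s when the seed is
unusable) and iterated to an absolute bracket width of 1 ns. Voxels with
non-physical E1 (≤0 or ≥1), all-zero signal, or a polish that terminates at
the window edge are flagged invalid; no silent defaults are substituted.
Noise-free inversion is exact to ≈1e-11 relative over T1 ∈ [0.1, 3] s, and
under 1% signal noise the fit lands within one 1-ms step of an exhaustive
grid search (the acceptance checks measure both).

**R1 filter.** R1 = 1/T1 on valid voxels; voxels outside 0.4–10 s⁻¹ are
invalidated and counted. The interval is treated as **closed** — "between
0.4 and 10" is read inclusively, so a voxel at exactly 10 s⁻¹ survives.

**Relaxivity.** Ordinary least squares of R1 on [Mn] for a phantom dilution
series (≥3 distinct concentrations): slope r1 (s⁻¹·mM⁻¹), intercept
(diluent R1, *fitted*, not forced), R². The pipeline treats r1 as a
required calibration input; the synthetic generator uses 6.5 s⁻¹·mM⁻¹, a
realistic value for a small Mn chelate/salt at high field.

**[Mn] estimation.** Voxel-wise: [Mn] = (R1post − R1pre)/r1 on jointly
valid voxels. Negative values are preserved and counted, never clipped —
they diagnose co-registration and noise problems (clipping would bias
region means). 24-h sessions image the animal in an independent position,
so a voxel-wise difference is not meaningful there; the 24-h index is the
difference of VOI-mean R1 values (pre and post VOIs drawn independently)
divided by r1.

## PET quantification

%ID/mL = 100 · A · 2^(t/12.7 h) / dose, referencing the static frame back
to injection time (t½ of ⁶⁴Cu). The frame is abstracted to a single
mid-time `frame_time_h`; decay correction can be disabled by flag since
conventions differ between sites. No SUV or %ID/g variants are computed.

## Multimodal analysis

Registration is out of scope: rigid/affine 4×4 world-coordinate transforms
are inputs (identity for phantom data), applied by trilinear resampling
with out-of-source voxels invalidated.

Voxel-wise PET–MR comparison first block-averages the VOI with integer
factors 2–8 per axis (factor 1 = pass-through) to blunt residual
co-registration mismatch. Blocks anchor at the VOI bounding-box corner
(reproducible regardless of grid phase); a block contributes the mean of
its in-mask voxels and is dropped when its in-mask fraction is below 0.5
(configurable). Correlation is Pearson on log10-transformed pairs; pairs
with a non-positive member are excluded pairwise and the exclusion count is
reported. Region-level analysis correlates per-region summaries — the
**median** by default (the choice is recorded in output metadata; means are
available) — across animals/replicates.

Group comparisons: Welch's t (unequal variances, Satterthwaite df; scipy's
implementation behind the package surface, verified against the closed form
in tests) and the Wilcoxon rank-sum test. The rank-sum statistic uses
midranks for ties; for combined n ≤ 10 the two-sided p is exact by
enumerating all group assignments of the observed midranks, otherwise a
normal approximation with tie correction and a 0.5 continuity correction is
used — written in-package because scipy's exact path refuses ties and its
large-sample path omits the continuity correction.

## Ex vivo chain

Autoradiography (50 µm pixels): background is the image median (exocrine
tissue dominates a pancreas section), spots are 8-connected components
above `threshold_k` × background (default 2.0 — the procedure in the
original workflow was manual, so the factor and minimum size are exposed),
islet size is the equivalent-circle diameter 2√(area/π)·pixel size, and
each spot is summarized as mean signal and islet-to-exocrine ratio.
The supplementary-style regression of signal on diameter is OLS; because
"uptake predicts diameter" can be read in either orientation, the response
variable (ratio or raw mean) is configurable and both orientations can be
reported.

Elemental maps (60 µm pixels): per-channel min–max normalization to 0–255
with floor rounding (a constant map normalizes to all zeros so blank
control channels merge cleanly; the exact maximum is pinned to 255 against
float round-down), then additive RGB merge Ca→R, Zn→G, Mn→B. Endocrine
enrichment is mean(islet)/mean(exocrine) per channel.

## Secretion assay

Enhancement index = mean of the three replicate contents at 15 mM divided
by the mean at 3 mM (the stimulating and basal conditions); other
concentrations in the 3–30 mM series are carried for dose-response
description only. Replicates aggregate by arithmetic mean (median by flag);
the ratio-of-means rather than mean-of-ratios form was chosen as the
conventional reading. Groups are summarized as mean/SD/n and compared by
Welch's t; a single-mouse group skips the test with a logged notice.

## The phantom: what it emulates, and what it does not

Compartments: background (0), exocrine pancreas (1), islets (2), optional
insulinoma (3). The exocrine organ is an ellipsoid (semi-axes
3.5/2.8/2.2 mm) on a 64³ grid of 0.15 mm voxels; islets are
rejection-sampled non-overlapping spheres fully inside the exocrine mask
with ≥1 voxel clearance (so component count equals islet count); diameters
are Normal(400, 120) µm truncated at one voxel. 400 µm sits at the large
end of the murine islet range; it was chosen so islets span ≥2 voxels at
this grid and remain resolvable compartments — smaller, partial-volume
islets are exactly what the block-averaged voxel-wise analysis tolerates in
real data but are not separately modeled here. The insulinoma variant adds
a 2 mm sphere, matching late-stage RIP1-Tag2 tumors.

Default contrast tables (per compartment; chosen once as field-realistic):

* T1 (pre-contrast, s): background 1.9, exocrine 1.0, islet 1.05,
  insulinoma 1.4.
* [Mn] (mM): zero pre-contrast; at 1 h exocrine 0.20 > islet 0.10 >
  insulinoma 0.05 (perfusion-dominated); at 24 h islet 0.12 and insulinoma
  0.10 > exocrine 0.04 (endocrine retention). The spec validates this
  ordering — it *is* the studied pattern, including the glucose-stimulated
  uptake, which is folded into the per-time-point table rather than
  modeled kinetically (time points are discrete labels pre/1 h/24 h).
* Tracer uptake (%ID/mL): islet 3.0 and insulinoma 5.0 ≫ exocrine 0.5,
  GLP-1R-specific and stable between frames.
* Elemental abundances: Ca and Zn endocrine-enriched, ¹³C uniform
  (tissue control), ⁵⁵Mn = small endogenous baseline + 50 counts/mM of
  exogenous Mn.

Noise is additive Gaussian after forward modeling (σ_MR = 0.002 on the
M0 = 1 signal scale ≈ 1% of the peak SPGR signal; σ_PET = 5 kBq/mL ≈ 2% of
pancreas activity), seeded per modality/time point/angle so all generators
are bit-reproducible. A Rician option exists for magnitude-noise realism
studies; at this SNR the Gaussian approximation is adequate for testing.
Sections are rendered by nearest-neighbour resampling of the label slice to
50 µm (autoradiography) and 60 µm (MSI) pixels. The secretion generator
produces triplicates of five-islet batches whose mean content rises
linearly from the basal level at 3 mM to basal × index at 15 mM with a mild
plateau decline at 30 mM; true indices default to 15 (control) and 12
(transgenic), inside the physiological 10–20× range.

**Limits of inference.** Passing tests show the *estimators* are correct
and that the pipeline recovers the built-in contrast pattern; they do not
validate the biology. The phantom has no between-animal variation (so
region-level correlations across replicates are dominated by noise and are
expectedly weak — the voxel-wise analysis carries the signature), no
respiratory motion, no registration error (identity transforms), no B1
inhomogeneity, no partial-volume islets below one voxel, no k-space or
sinogram physics, and no kinetic washout between the three discrete time
points.

## Problem sizes and determinism

Default analyses run on 64³ grids; the sign-inversion study uses 50
replicates with the two-angle protocol (closed-form fit) and completes in
well under a minute, and the acceptance script regenerates every quantity
in about 10 s on one CPU. All randomness flows from explicit integer seeds
through `numpy.random.default_rng` seed sequences; reruns of any generator
or of deterministic pipeline stages are bit-identical.
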