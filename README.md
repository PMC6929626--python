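# betaquant

Quantification pipeline for simultaneous PET / manganese-enhanced MRI
(ME-MRI) of the pancreatic beta cell, with the matching ex vivo validation
chain and a digital mouse-pancreas phantom.

## The problem

Two quantities describe the endocrine pancreas in diabetes research and they
must be measured together:

* **Beta-cell mass** — imaged by PET with a GLP-1R-targeted exendin-4
  tracer (e.g. [⁶⁴Cu]Ex4). The readout is the decay-corrected percent
  injected dose per millilitre,
  `%ID/mL = 100 · A(kBq/mL) · 2^(t/t_half) / dose`, with t½(⁶⁴Cu) = 12.7 h.
* **Beta-cell function** — imaged by ME-MRI: Mn²⁺ enters beta cells through
  voltage-dependent calcium channels coupled to glucose-stimulated insulin
  secretion. Mn shortens T1, so the longitudinal relaxation rate R1 = 1/T1
  tracks local Mn. T1 is mapped with the variable-flip-angle (VFA) spoiled
  gradient-echo method, `S = M0 sin α (1−E1)/(1−E1 cos α)`, `E1 = e^(−TR/T1)`
  (TR/TE = 10/1.9 ms; flip sets 4°/22° or 4°/14°/27°), R1 maps are filtered
  to the physiological window 0.4–10 s⁻¹, and concentration follows from
  the relaxivity calibration `[Mn] = (R1post − R1pre)/r1`.

The informative signature is the *correlation* of the two inside a pancreas
VOI: shortly after injection (1 h) Mn is perfusion-dominated and highest in
exocrine tissue, so log10(%ID/mL) vs log10(R1) correlates **negatively**;
by 24 h Mn is retained by islets and insulinomas — where the tracer also
binds — and the correlation turns **positive**. The package reproduces this
inversion end-to-end on synthetic ground truth, plus the ex vivo chain that
validates it: autoradiography islet-spot quantification (islet-to-exocrine
ratios, signal-vs-diameter regression) and LA-ICP-MS elemental maps merged
as 8-bit RGB (⁴⁴Ca red, ⁶⁴Zn green, ⁵⁵Mn blue), and the glucose-stimulated
insulin-secretion enhancement index (15 mM vs 3 mM) as the physiological
control.

No animal data ship with the package: the `phantom` module generates seeded
synthetic datasets (label maps, VFA stacks, PET volumes, 2D sections,
secretion tables) with the reported compartmental contrast, so every stage
is testable and every number below is recomputable.

## Worked example

```bash
betaquant run-all --out-dir results/demo --seed 11
```

prints

```
voxel-wise log10 correlation: r(1h)=-0.804, r(24h)=+0.560 (pattern matches: True)
report written to results/demo/report.json
```

i.e. on a default 64³ phantom (0.15 mm voxels, 40 islets) the voxel-wise
log10(%ID/mL)–log10(R1) Pearson correlation inside the pancreas VOI is
negative at 1 h and positive at 24 h — the Mn-retention signature. The run
directory holds the T1/R1/[Mn]/%ID/mL NIfTI volumes, autoradiography and
RGB-merge TIFFs, and CSV tables (correlations, enrichment scores, islet
records, secretion summary), each stamped with the seed and config hash.

The same steps are available as a library:

```python
from betaquant import phantom, mr_quant, pet_quant, multimodal
from betaquant.mr_quant import AcquisitionParams

spec = phantom.PhantomSpec(rng_seed=11)
labels = phantom.build_label_map(spec)
acq = AcquisitionParams(flip_deg=(4, 22))            # TR/TE = 10/1.9 ms
stacks = phantom.simulate_vfa_stacks(labels, spec, "1h", acq)
r1 = mr_quant.t1_to_r1(mr_quant.fit_t1_vfa(stacks, acq))   # 0.4-10 1/s filter
```

The numbered scripts under `analysis/` run the full study narrative:
`01_simulate_phantom.py` (datasets), `02_quantify_t1_mn.py` ([Mn] recovery),
`03_quantify_pet.py` (%ID/mL group tables), `04_correlate_multimodal.py`
(sign inversion), `05_exvivo_sections.py` (spots, regression, RGB merges),
`06_secretion_assay.py` (enhancement indices). Each accepts `--seed` and
writes its tables under `results/analysis/`.

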