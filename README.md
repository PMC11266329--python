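# petmrac

Desk-scale evaluation of **PET-MR attenuation correction** in the pelvis.

PET reconstruction must correct for photon attenuation using a 511 keV
linear-attenuation-coefficient (μ) map of the patient. On a PET-MR scanner
no CT is available: the standard Dixon-based four-class map (**MRAC**)
contains no bone and is known to underestimate SUV, while synthetic CT
(**sCT**) maps predicted from MR promise near-CT accuracy. `petmrac`
rebuilds this evaluation end to end on synthetic pelvic phantoms, for
medical-physics researchers who want a transparent, fully seeded testbed
for how μ-map errors propagate into SUV quantification, tumour delineation
and a formal equivalence verdict:

1. **Phantom cohort** — seeded digital patients (HU volume, tissue labels,
   SUV activity truth with primary/nodal hot lesions, manual tumour
   volumes), plus controlled degradations: an MRAC-style class map (bone →
   soft tissue) and an sCT-style HU volume (bone HU bias / boundary shift).
2. **Attenuation maps** — bilinear HU → μ(511 keV) conversion, four-class
   bulk LAC assignment, and common-support preparation (crop to the
   external contour, missing tissue and internal air → water).
3. **PET simulation** — one attenuated parallel-beam acquisition per
   patient (Poisson counts, CTAC as physical truth) reconstructed once per
   candidate map with matched-projector OSEM (4 iterations × 16 subsets,
   5 mm Gaussian post-filter): identical data, different correction.
4. **Metrics** — per-voxel percentage SUV differences inside the external
   contour (cohort histogram: 400 bins over ±100 %), bone-region analysis,
   40 %-of-SUVmax GTV delineation, Dice similarity coefficient (DSC) and
   mean/max distance to agreement (DTA), per-lesion SUVmax/SUVmean.
5. **Equivalence statistics** — margin from the quadrature uncertainty
   budget Δ_total = √(Δ_PETCT² + Δ_AC²) (12 % baseline + 0.5 % allowed
   growth ⇒ ±3.5 %), two one-sided paired *t* tests (TOST, reported
   p = max of the two one-sided p-values) at α = 0.05/(8 − 1) ≈ 0.007
   across 8 comparisons.

See `docs/methods.md` for the model, assumptions and limitations.

## Worked example

The statistics layer alone, from summary statistics (mean % ± SE, n):

```python
>>> from petmrac import derive_margin, corrected_alpha, tost_from_summary
>>> margin = derive_margin(12.0, 0.5)   # quadrature budget
>>> round(margin, 1)
3.5
>>> corrected_alpha(8, 0.05)[0]         # 0.05 / (8 - 1), reported
0.007
>>> round(tost_from_summary(1.0, 0.8, 9, margin), 3)   # equivalent
0.007
>>> round(tost_from_summary(-4.3, 0.8, 9, margin), 2)  # not equivalent
0.83
```

The full pipeline, here on a reduced 3-patient cohort (64² grid):

```bash
petmrac init-config cfg.yaml   # edit cohort/acquisition blocks as needed
petmrac run-all --config cfg.yaml --seed 11 --outdir out
```

prints (actual output):

```
Whole-image / bone-region mean SUV differences to CTAC (%):
  bone  MRAC   -26.01%
  bone  sCTAC  -1.16%
  whole MRAC   -3.51%
  whole sCTAC  -0.09%

Equivalence (TOST, margin 3.5%, alpha 0.0071):
  sCTAC/primary/suv_max    n= 3 mean= -0.07% se= 0.01% p=0.0000 -> equivalent
  ...
  MRAC/primary/suv_max     n= 3 mean= -3.34% se= 0.13% p=0.1741 -> NOT equivalent
```

Reading this: removing bone from the correction map (MRAC) depresses
reconstructed SUV everywhere (−3.5 % whole-image) and far more inside bone
(−26 %), while a near-exact synthetic CT stays within a fraction of a
percent; the TOST verdicts then formalise which candidate map is clinically
interchangeable with the CT gold standard within the ±3.5 % margin.
`out/` also receives per-lesion CSVs (`gtv_metrics.csv`), the delineation
summary, histogram CSVs and a JSON report. The staged subcommands
`generate`, `simulate`, `reconstruct`, `evaluate`, `report` run the same
pipeline through NIfTI/CSV intermediates on disk.

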