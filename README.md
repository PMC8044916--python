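# deltarad

Longitudinal DCE-MRI delta-radiomics for early prediction of breast-tumor
response to neoadjuvant chemotherapy (NACT).

## The problem

A subset of breast-cancer patients gains little from NACT while bearing its
toxicity, so an early, non-invasive readout of eventual response is
valuable. After the first treatment cycles, responding tumors shrink
non-uniformly and lose internal heterogeneity. `deltarad` quantifies both
effects from a pair of dynamic contrast-enhanced MRI scans (baseline and
early follow-up) and turns them into a held-out-validated classifier of
pathological response (Miller-Payne grade 4–5 = responder).

Two complementary change measures are computed for every patient:

- **Voxel level.** The follow-up scan is aligned to the baseline scan with
  multi-resolution Gaussian-regularized demons registration. The Jacobian
  determinant map of the recovered transformation,
  `J(x) = det(I + du/dx)`, gives the local volume ratio
  v_followup / v_baseline at every voxel: J < 1 marks shrinkage, J = 1
  preservation, J > 1 expansion.
- **Feature level (deltaRAD).** 102 radiomic features (shape,
  first-order, GLCM, GLRLM, GLSZM, GLDM) are extracted from the tumor ROI
  on each scan and summarized as the relative net change
  `fΔⁱ = (fⁱ_baseline − fⁱ_followup) / fⁱ_baseline`.

Features from the baseline image, follow-up image, Jacobian map and
deltaRAD — separately, fused, and fused with molecular subtype — feed a
Gaussian-kernel SVM with SVM-RFE feature ranking, tuned by 10-fold
cross-validated grid search on a development arm and evaluated once on a
testing arm (AUC ± SE and Youden-point sensitivity/specificity/PPV/NPV,
with DeLong paired model comparisons).

Because clinical images cannot be redistributed, the package ships a
synthetic-cohort generator that plants the effects of interest with known
ground truth: responders contract more strongly (per-axis scale 0.75 vs
0.95) and lose more intratumoral heterogeneity (variance shrinkage 0.40 vs
0.10) than nonresponders. Every stage is validated against analytic or
brute-force oracles; see `docs/methods.md`.

## Worked example

```python
import deltarad as dr

# one synthetic patient: baseline + follow-up DCE series with ground truth
cfg = dr.SimulationConfig()
baseline, followup, mask, true_field, meta = dr.generate_tumor_pair(cfg, is_responder=True, seed=3)
print(meta["contraction"])            # (0.649, 0.738, 0.707)  per-axis truth
print(meta["true_volume_ratio"])      # 0.339

# peak-enhancement subtraction images (frame index is computed, not assumed)
idx, sub_b = dr.select_enhancement_frame(baseline)   # idx == 3
_,   sub_f = dr.select_enhancement_frame(followup)

# registration and the Jacobian map
field, warped, report = dr.register_deformable(sub_b, sub_f)
jmap = dr.compute_jacobian_map(field)
print(dr.summarize_jacobian(jmap, mask)["mean"])     # 0.447  (true ratio 0.339)

# radiomics and deltaRAD
f_b = dr.extract_all(sub_b, mask)                    # 102 named features
f_f = dr.extract_all(sub_f, mask)
delta, flagged = dr.delta_rad(f_b, f_f)
print(delta["firstorder_Energy"])                    # 0.627: energy fell under treatment
```

The mean Jacobian 0.447 < 1 says the tumor lost volume voxel-by-voxel;
demons regularization under-recovers this very strong contraction (truth
0.339), which compresses—but does not reorder—the group separation. A
positive deltaRAD energy says total enhancement dropped after treatment,
the direction expected for a responder.

A full cohort analysis is one call (or `deltarad run-all --seed 0 --n 114
--out results/`):

```python
result = dr.run_pipeline(dr.PipelineConfig(seed=0))
print(result.results_table)   # 6 rows: baseline, followup, delta, jacobian,
                              # fusion, fusion+subtype with AUC/SE/sens/spec/PPV/NPV
```

On the default synthetic cohort the responders' mean Jacobian sits far
below the nonresponders' (≈ 0.48 vs ≈ 0.90 at the planted contractions)
and fused-feature models dominate baseline-only models in held-out AUC.

## Command-line interface

`deltarad` exposes subcommands `simulate`, `preprocess`, `register`,
`features`, `delta`, `cohort-stats`, and `run-all`; volumes, masks and
displacement fields travel as NIfTI, cohorts and feature tables as CSV,
reports as JSON. `deltarad <cmd> --help` shows the options.

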