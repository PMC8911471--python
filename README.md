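# adaptqa

Plan-quality auditing for **physician-free adapt-to-shape (ATS) workflows
on MR-LINACs**, exercised end to end on a synthetic pelvic phantom so no
patient data is needed.

In daily adaptive MR-guided radiotherapy, organ-at-risk contours are edited
on the table before each fraction is replanned. If radiation therapists
perform that editing without a physician present, two questions decide
whether the workflow is safe:

1. **How close are non-physician contours to the specialist's?** Measured
   with the Dice similarity index on binary structure masks,
   `DSI = 2|V_ref ∩ V_test| / (|V_ref| + |V_test|)`.
2. **Does the adapted dose still meet the organ constraints when scored on
   the specialist's ("gold standard") structures, even when it meets them
   on the adapter's own structures?** A plan that passes its clinical
   evaluation but fails on the gold structures is a *silent failure* — it
   would be treated and caught only at offline review.

`adaptqa` implements the full evaluation chain:

* voxel-grid structure masks, polygon rasterization, anisotropic Euclidean
  expansion, depth-limited trimming and plane cropping;
* the Boolean planning rules `CTV → CTVplan → PTV` (trim the CTV to extend
  ≤ 3 mm into the bladder, subtract the bowel, expand by 3 mm), plus the
  bowel evaluation limit 1.5 cm cranial to the CTV;
* a DVH engine with Dmean, Dmax, Dx%, D(v cc) and the RTOG conformity
  index `CI = V_95% / V_PTV`;
* tiered constraint classification (ideal / acceptable-variation / fail)
  for conventional (1.8–2 Gy/fx) and short-course (5 Gy/fx) prescriptions:
  bladder Dmean ≤ 40 (44) Gy and bowel D(0.03 cc) ≤ 50 (55) Gy, scaled to
  22 (24) and 27.5 (30) Gy for short courses;
* gold-standard overlay re-evaluation and workflow aggregation: clinical
  pass rate, gold pass rate, safety rate (delivered-acceptably **or**
  halted for on-table review), and the per-fraction outcome heat map;
* a synthetic pelvic phantom (bladder, bowel loops, CTV penetrating 1 cm
  into the bladder) with per-fraction organ deformation, per-observer
  contour noise with calibratable expected Dice, and a conformal dose
  surrogate with controllable conformity and OAR sparing;
* DICOM RT Structure Set / RT Dose adapters and a portable fraction-bundle
  archive, so real exports can replace phantom data without code change.

## Worked example

Simulate a study-shaped cohort (10 patients × 2 fractions × 6 observers —
two physicians, three therapists, one student with increasing contour
noise) and evaluate it:

```bash
adaptqa simulate --out cohort/ --seed 1
adaptqa evaluate --in cohort/ --report report/
```

The evaluate step prints, for this seed:

```
clinical pass 120/120 (100.0%), gold pass 112/120 (93.3%), safety 112/120 (93.3%)
```

meaning every adapted plan met the constraints on the adapter's own
structures, but 8 of 120 fractions were silent failures on the gold
(truth) structures — all in the two highest-prescription patients, and
almost all from the noisier observers. `report/` contains the pairwise
DSI table (physician pair ≈ 0.98 bladder / 0.98 bowel, student pair
lower), the per-observer conformity indices (means ≈ 1.1–1.2), the
per-constraint dose values, the JSON workflow summary and the
green/yellow/red outcome heat map.

The same machinery is importable as a library:

```python
from adaptqa import (AnatomyParams, default_grid, generate_planning_case,
                     make_ctvplan, make_ptv, dice)

bundle = generate_planning_case(AnatomyParams(), default_grid())
ctvplan = make_ctvplan(bundle["ctv"], bundle["bladder"], bundle["bowel"])
ptv = make_ptv(ctvplan)
print(round(ptv.volume_cc, 1))          # 105.9 cc on the default phantom
```

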