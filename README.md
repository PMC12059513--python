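# dlvhkit

Outcome analysis for pencil-beam-scanning (PBS) proton therapy based on the
**dose–LET volume histogram (DLVH)**.

In PBS fields the dose-averaged linear energy transfer (LETd) peaks at the
distal falloff of the beam, so normal tissues just beyond the target — for
post-mastectomy chest-wall treatments, the ribs and intercostal muscles —
can receive a moderate dose together with high LETd. `dlvhkit` implements
the statistical pipeline used to ask whether such dose/LETd patterns are
associated with a clinical endpoint (e.g. rib fracture) in a matched
case-control cohort:

1. **DLVH surface.** For each patient, the joint cumulative histogram

   V(d, l) = volume of the structure with dose ≥ d Gy[RBE] **and**
   LETd ≥ l keV/µm,

   tabulated on a (dose, LETd) grid (default 2 Gy[RBE] × 0.2 keV/µm
   steps), normalized so V(0, 0) = 100%. Iso-volume lines DLv% project
   the surface into the dose–LETd plane.
2. **Conditional logistic regression (CLR).** With one case and m matched
   controls per set, the outcome model is

   logit P(event) = α_i + β · V(d, l),

   and conditioning on one case per set eliminates the per-set intercept
   α_i. A separate CLR model is fitted at every grid node, giving a
   2-D **p-value map** for β over the dose–LETd plane.
3. **Feature extraction.** Sub-threshold, 4-connected regions of the
   p-value map (split by the sign of β) are the candidate dose/LETd
   features associated with the outcome.

Supporting pieces: LETd spectral averaging (SP²-weighted over SP-weighted
mean of the proton stopping-power spectrum), EQD2 conversion of
hypofractionated plans (α/β = 3 Gy default), derivation of the
risk-associated structure from the 50% prescription isodose, NRRD /
MetaImage / CSV-voxel-table I/O, and a synthetic PBS cohort generator so
the entire pipeline is testable without patient data.

## Worked example

```python
import numpy as np
from dlvhkit import (CohortSpec, simulate_cohort, compute_dlvh,
                     scan_pvalue_map, extract_feature_regions)

spec = CohortSpec(seed=7, n_sets=30, beta_true=0.5,
                  generating_index=(30.0, 4.0))
patients, cohort = simulate_cohort(spec)
surfaces = {p.patient_id: compute_dlvh(p.dose, p.letd, p.mask)
            for p in patients}
pmap = scan_pvalue_map(surfaces, cohort)

a = np.searchsorted(pmap.dose_grid, 30.0)
b = np.searchsorted(pmap.let_grid, 4.0)
print(f"p at V(30 Gy[RBE], 4 keV/um): {pmap.p[a, b]:.2e}")
region = extract_feature_regions(pmap, p_threshold=0.1)[0]
print(f"top region: {region.direction}, min p = {region.min_p:.2e}, "
      f"bounding box = {region.bounding_box}")
```

prints

```
p at V(30 Gy[RBE], 4 keV/um): 3.90e-04
top region: risk_increasing, min p = 9.88e-05, bounding box = (12.0, 14.0, 0.0, 7.0)
```

The cohort was generated with a positive effect (β = 0.5 per % volume) of
V(30 Gy[RBE], 4.0 keV/µm) on the outcome; the scan recovers a small
p-value at that index. Because nearby DLVH indices are strongly
interdependent, many nodes co-vary with the generating index: the
lowest-p region here sits at lower dose (its V values are near-perfectly
correlated with V(30, 4) in this beam model), and a separate
risk-increasing region contains the generating index itself — larger
volumes of moderate dose with high LETd in the cases.

The same pipeline is available as a CLI for on-disk volumes:

```bash
dlvhkit simulate --outdir run --seed 7
dlvhkit dlvh     --outdir run      # per-patient DLVH CSVs (EQD2-converted dose)
dlvhkit scan     --outdir run      # p-value map CSV
dlvhkit features --outdir run      # regions.json + report.md
dlvhkit summarize --outdir run --n-screened 216
```

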