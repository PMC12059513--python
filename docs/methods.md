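# Methods

## The DLVH surface

For a structure with voxels v (voxel volume w, in cc), paired fields
dose(v) in Gy[RBE] and LETd(v) in keV/µm, the DLVH index is

    V(d, l) = w · #{ v : dose(v) ≥ d  and  LETd(v) ≥ l }

reported as a percentage of the structure volume (normalized, the
default) or in cc. Both thresholds are **closed** (≥): this makes the
single-voxel case well defined (a voxel at exactly (d, l) contributes)
and keeps grid-node values exact counts. V is non-increasing along both
axes, V(d, 0) is the ordinary cumulative DVH, V(0, l) the LETd-volume
histogram, and V(d, l) ≤ min(V(d, 0), V(0, l)).

The implementation bins each masked voxel once against the grids and
tail-sums the 2-D histogram, which is exactly equivalent to per-node
enumeration (the tests assert bitwise equality against a brute-force
oracle). `query_index` always recounts voxels at the requested (d, l)
rather than interpolating the tabulated surface — the grid is a
scan/visualisation artifact, not the definition.

Default grids are 0–70 Gy[RBE] in steps of 2 and 0–8 keV/µm in steps of
0.2. The steps are the scan increments of the analysis; the upper bounds
are configurable and simply need to cover the prescription (plus boost)
and the distal-edge LETd range.

Iso-volume lines DLv% and iso-p lines are marching-squares level sets
(scikit-image `find_contours`) with linear interpolation between nodes;
for the p-value map, masked nodes are excluded from interpolation so
contours never cross into uninformative bins. Level sets are degenerate
exactly at plateau values of a stepped surface (a consequence of
marching squares, not of the data); querying a level strictly between
plateaus avoids this.

## Physics helpers

* **LETd spectral average.** For a binned proton fluence spectrum φ_j
  with unrestricted stopping powers SP_j (keV/µm, to medium) and bin
  widths ΔE_j,

      LETd = Σ φ_j SP_j² ΔE_j / Σ φ_j SP_j ΔE_j .

  It is invariant to rescaling φ, bounded by [min SP, max SP] over bins
  with φ > 0, and ≥ the fluence-weighted mean SP (Cauchy–Schwarz).
* **EQD2.** A scheme of total dose D in n fractions converts to
  D · (D/n + α/β) / (2 + α/β), the equi-effective dose at 2 Gy/fraction
  under the linear-quadratic model. Default α/β = 3 Gy (late
  bone/soft-tissue effects). `eqd2_field` converts voxel-wise using each
  voxel's own dose per fraction (voxel dose / n); in a uniform region
  this reduces to the plan-level conversion, and in non-uniform regions
  it is the standard voxel-wise interpretation.
* **Risk structure.** The analysed structure is the anatomical mask
  restricted to the region at or above a fraction (default 50%) of the
  prescription dose — a closed threshold, since "enclosed by the isodose
  line" is boundary-ambiguous. An empty result flags a warning instead
  of raising, so batch pipelines can proceed and report.

## Conditional logistic regression

Matched sets contain one case and m ≥ 1 controls sharing the matching
covariates; the outcome model logit P(event) = α_i + β V(d, l) has a
per-set intercept α_i. Conditioning on one case per set gives the
conditional log-likelihood

    ℓ(β) = Σ_i [ β x_case,i − log Σ_{j∈set i} exp(β x_j) ] ,

concave in β, invariant to per-set location shifts, and free of α_i.

Numerical choices:

* Covariates are divided by their pooled standard deviation across
  informative sets before optimisation (percent volumes reach 100 while
  β is small; standardising keeps Newton steps O(1)); β̂ and its standard
  error are transformed back, so the user-facing scale is per % volume.
* Newton–Raphson from β = 0; convergence at |score| < 1e-8 or 50
  iterations; steps clipped to ±5 on the standardized scale.
* Sets whose members share one value are dropped as non-informative
  (their conditional probability is constant in β); if none remain the
  fit's status is `non_informative`.
* The MLE diverges iff the case value is ≥ every control (or ≤ every
  control) in **each** informative set — the score then keeps one sign
  for every finite β. This condition (including ties at the extremum,
  where Newton would otherwise stall on a likelihood plateau) is checked
  up front and again if |β| exceeds 15 on the standardized scale; such
  fits carry status `monotone_likelihood` and no numbers.
* p-values: two-sided Wald (default, matching the conventional clogit
  summary) with se from the inverse observed information, or the
  likelihood-ratio test (`p_method="lr"`).

**Small-sample behaviour.** At very small numbers of sets the Wald test
is conservative: the observed information shrinks as |β̂| grows, so |z| =
|β̂|/se is bounded (the Hauck–Donner effect) — with 7 informative 1:2
sets the null rejection rate at 0.05 is well below 0.05. The LR test is
close to nominal at the same size, which is why the calibration checks
in the test-suite assert the binomial band on the LR p-value and
one-sided conservatism for the Wald p-value. This is worth knowing when
reading p-value maps from small cohorts: Wald maps understate
significance rather than inventing it.

The scan fits one CLR per grid node and stores p, sign(β̂) and the
status; nodes with non-ok status are **masked, not imputed** — assigning
p = 1 would fabricate spatial structure in the map. An optional
Benjamini-Hochberg or Benjamini-Yekutieli adjustment over the ok nodes is
available but off by default: the raw map is the primary, transparent
output, and neighbouring DLVH indices are strongly dependent.

## Feature regions

Regions are 4-connected components of {ok nodes : p < threshold}, split
by the sign of β̂ (risk-increasing vs risk-decreasing), sorted by minimal
p with deterministic tie-breaks, each reporting its bounding box in
(dose, LETd) units and its minimum-p representative index. 4-connectivity
(no diagonal bridges) is the conservative choice. Default reporting
thresholds are 0.1 and 0.2, with 0.05 as the formal significance line;
rectangular feature descriptions are bounding boxes of components, not
the extraction primitive.

## Synthetic cohorts

The generator exists so every stage can be exercised end-to-end without
patient data. It emulates the one feature of PBS chest-wall fields the
analysis depends on — the anti-correlated dose/LETd depth structure —
and nothing else.

Depth profiles along the beam axis z (mm):

    dose(z) = plateau · σ((R − z)/σ_D)
    letd(z) = L0 + (Lmax − L0) · σ((z − R + δ)/σ_L)

with σ the logistic function, extruded over the transverse axes. Default
parameters: prescription/plateau 50 Gy[RBE] in 25 fractions, range
R = 40 mm, falloff width σ_D = 3 mm, LETd plateau L0 = 2 keV/µm rising
to Lmax = 8 keV/µm over σ_L = 4 mm, offset δ = 3 mm placing the LETd
rise at the falloff; grid 8×8×30 voxels at (4, 4, 2) mm. With these
values voxels at LETd ≥ 4 keV/µm sit below the prescription dose, and
dose and LETd are negatively correlated over the chest-wall slab (a
fixed 24 mm slab about R, so masks align across patients). Per-patient
variation: the range R is jittered (sd 2 mm), the plateau by 2%
relative, plus bounded ±3% multiplicative voxel noise — this drives the
between-patient spread in V(d, l) (sd ≈ 2.7% at V(30, 4)) that the
regression sees. These values were chosen once to reproduce the
qualitative DLVH shapes of distal-edge fields; they are synthetic, not
fitted to measurements, and carry no anatomical realism, setup/range
uncertainty, or respiratory motion. Passing tests therefore demonstrate
the statistical machinery, not dosimetric accuracy on real fields.

Outcomes follow the generating model P(case) = expit(α_i + β_true ·
V(d*, l*)) with default generating index (d*, l*) = (30 Gy[RBE],
4 keV/µm). Candidate sets are redrawn until exactly one member is a case
(cap 10,000 attempts), mirroring matched case-control ascertainment.
Conditional on acceptance, P(member j is the case) =
exp(β x_j)/Σ_k exp(β x_k) exactly — so fitting CLR at (d*, l*) is
consistent for β_true, and the set intercept may be chosen freely; it is
set to α0 − β_true · mean(V_set) (α0 = −0.7) purely to keep rejection
sampling efficient. Matching covariates are drawn per set (identical
within a set) and are not used by the statistics — conditioning absorbs
them — but keep the cohort-table schema realistic; grade and
time-to-event columns are sampled for cases only to exercise the
summary. The 7-case design with control counts (4, 1, 1, 2, 2, 2, 2)
reproduces the reference 7-case/14-control shape.

## Reproducibility and problem sizes

Everything derives from a single integer seed (`numpy.random.default_rng`);
the same spec and seed give identical p-value maps, and `generate_cohort`
writes a manifest with per-file SHA-256 digests that is byte-identical
across runs. The simulation studies use: 500 replicates of 7 sets (1:2)
for null calibration; 200 replicates of 40 sets (1:2) at β_true = 0.2
for Wald CI coverage (40 sets is comfortably inside the Wald asymptotic
regime); and one 30-set cohort at β_true = 0.5 for end-to-end feature
recovery. On one CPU the full test-suite runs in well under two minutes
and the acceptance script in about one.

## Known limitations

* No DICOM RT-DOSE/RT-STRUCT input and no resampling: misaligned volumes
  are rejected, because voxel-level dose/LETd pairing is the quantity of
  interest and interpolation would silently alter the joint histogram.
* Univariable CLR only (one DLVH index at a time); no multivariable
  adjustment for additional clinical covariates beyond the matching.
* The map's p-values at extreme (d, l) rest on few voxels and few
  informative sets; statuses make this visible but cannot repair it.
* The beam model is 1-D-extruded; it cannot represent multi-field
  geometries, heterogeneities, or motion.
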