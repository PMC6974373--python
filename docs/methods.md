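# Methods

This note documents the models, numerical conventions and design choices
behind planbio, and what the synthetic-data tests do and do not demonstrate.

## Dose grids and DVHs

Dose is stored on a regular voxel lattice (default 0.5 × 0.5 × 0.5 cm³, the
grid resolution typical of clinical dose calculation; a 2 mm option exists
for oracle tests). Structures are binary masks with full-voxel inclusion —
no partial-volume weighting — so the voxel-sort oracle used in tests is
exact and mask volumes are integer multiples of the voxel volume. Rectum and
bladder are contoured as walls (tube and shell), not solid organs; no
solid-to-wall conversion exists.

Differential DVHs are histograms with half-open bins [e, e + w), constant
width w = 0.05 Gy by default, on a contiguous grid starting at 0 Gy. The
curve object itself accepts arbitrary strictly-ascending bin edges, because
the per-bin EQD2 map is nonlinear and transforms a uniform grid into a
non-uniform one; representing that exactly was preferred over re-binning
noise. Bin contents are treated as point masses at the left edge:

* V(D) counts bins with edge ≥ D, so it brackets the true voxel count
  between thresholds D and D + w;
* D(v) (`dose_at_hot_volume`) returns the highest bin edge with at least v
  cm³ at or above it. Sub-bin linear interpolation was deliberately not
  used: doses are already quantised to the bin grid, so interpolation adds
  no information, and on sparse user-supplied curves it would smear volume
  between distant doses and corrupt the rank-matched plan sum. The step rule
  is exact for uniform doses and within one bin width of a voxel-level sort
  otherwise, which is the accuracy contract the tests enforce.

## LQ isoeffect machinery

* Fractionated/HDR: BED = D(1 + d/(α/β)), assuming complete repair between
  fractions. EQD2 = BED/1.2 for α/β = 10 Gy (tumour) or BED/(5/3) for
  α/β = 3 Gy (late normal tissue). Repair half-times: 1 h tumour, 3 h
  normal tissue; the repair rate is always derived as μ = ln2/T½.
* Continuous irradiation uses the constant-dose-rate protraction factor
  g(μT) = (2/μT)[1 − (1 − e^(−μT))/μT]; a series expansion below μT = 1e−4
  avoids cancellation, and the acute (T→0) and full-repair (T→∞) limits are
  verified to 0.1%. The implementation is cross-checked in tests against a
  numeric Lea–Catcheside double integral over the dose-rate history.
* Pulsed dose rate treats 0.5 Gy pulses as instantaneous (pulse duration is
  a few minutes against repair half-times of hours) with the standard
  inter-pulse incomplete-repair factor h_n(φ). The closed form is verified
  against the O(n²) pairwise-repair sum to 1e−9 relative for up to 200
  pulses. Intra-pulse protraction is not modelled.
* For DVH-level radiobiology of PDR deliveries the pipeline uses the
  clinically stated HDR equivalents (PDR 15 Gy ↔ HDR 4 Gy × 3; PDR 30 Gy ↔
  HDR 4 Gy × 6): boost DVH doses are scaled by the equivalent-to-physical
  total-dose ratio and converted per bin with the equivalent fraction count.
  This is the route the printed BED values of such regimens follow; the
  pulse-train model itself remains available (and gives 17.2 Gy rather than
  16.8 Gy BED for the hourly 30 × 0.5 Gy train — the regimen report prints
  both). One printed-value conflict is handled explicitly: a 12 Gy in 4 Gy
  fractions regimen has BED 16.8 Gy and therefore EQD2 14.0 Gy; quoted
  values of 14.2 Gy for it are inconsistent with the BED and the report
  flags rather than reproduces them.
* `isoeffective_fractions` returns the smallest integer fraction count whose
  BED reaches the target, plus the achieved BED (which may overshoot);
  rounding of reported table values is half-up at one decimal, applied only
  at print time.

## Conformity

Equation-level ambiguity exists in the literature between CI = V_RI/TV
(RTOG) and CI = TV_RI/TV (coverage). Both are exposed —
`conformity_index` implements the RTOG reading, consistent with the
interpretation that CI > 1 means healthy tissue is irradiated;
`coverage_fraction` gives the other. CN = coverage × selectivity is
unambiguous and is the primary comparison quantity. Reports show all three.

## Outcome models

* TCP: Poisson model on the differential DVH; the printed exponent of the
  survival term is implemented as (α + β·dᵢ)·Dᵢ, the dimensionally
  consistent LQ exponent. α is not a study-stated value: the default is
  0.3 Gy⁻¹ (configurable), with β = α/(α/β); TCP magnitudes therefore carry
  this assumption and only orderings are meaningful. Clonogen densities:
  10⁵ cm⁻³ post-operative, 10⁷ cm⁻³ radical. TCP is evaluated on
  EQD2-domain DVHs at 2 Gy per fraction, consistent with the EQD2-space plan
  summation that precedes it.
* NTCP: Kutcher–Burman reduction D_eff = (Σ vᵢDᵢ^(1/n))^n (the hottest dose
  is factored out for numerical headroom at small n; n = 0 returns D_max
  with a warning, its analytic limit), then the Lyman probit evaluated with
  erfc rather than quadrature. Rectal parameters (n = 0.13, m = 0.14,
  TD50 = 81 Gy) are study-stated; bladder (0.5, 0.11, 80 Gy) and bowel
  (0.15, 0.16, 55 Gy) triples are package defaults from the classical Lyman
  parameter fits and every report flags them as such in its provenance
  footer.
* `fit_lkb` refits (m, TD50) by Bernoulli maximum likelihood at fixed n
  (Nelder–Mead on the negative log-likelihood, probabilities clipped at
  1e−12). At 500 simulated organs the sampling standard error of m is about
  6–8% (an information bound of the probit design, not an implementation
  limit), so the 10%-recovery check holds at the packaged fixed seed and for
  most replicates, while TD50 recovers to ~1–3%.

## Plan summation

Rank-matched addition: both EQD2 cumulative curves are sampled at 1000 equal
volume-fraction midpoints and added at equal cumulative-volume rank — the
worst case of spatially coincident hot regions, appropriate when the two
plans cannot be deformably registered. An alternative "uniform-background"
mode adds the second plan's mean dose uniformly; both modes are labelled in
output. Total volume is conserved exactly; structure volumes must agree
within 1%. Resampling accuracy is tested against a 10⁴-point dense oracle.

## Synthetic cohort

The generator replaces unpublished patient plans and defines the study
conditions; its defaults are not tuned per experiment.

* Geometry (ellipsoids, tubes, shells on a 48³ × 5 mm grid): boost CTV at
  the origin with jittered radii so the intracavitary boost volume
  (CTV + 5 mm) lands in the emulated cohort range (~12–88 cm³, mean
  ≈ 37 cm³); the external-beam boost target adds a 7–10 mm setup margin and
  strictly contains it. The pelvic PTV (~1.2–1.3 litres) sits anteriorly
  with its posterior border at the anterior rectal wall. Rectum (tube) and
  bladder (shell) abut the boost margin with 1–6 mm jittered gaps; bowel
  loops sit superiorly, clear of the tandem tip; femoral heads and spinal
  cord complete the set.
* During the intracavitary session, vaginal packing and the Foley balloon
  displace rectum and bladder 5–10 mm away from the sources; the phantom
  therefore carries a second OAR configuration (`brachy_masks`) used for the
  brachytherapy dose only. Displacements are snapped to whole voxels so the
  displaced structures keep exactly their natural volumes, which keeps the
  DVH-level plan sum well-defined. This mirrors the clinical situation in
  which intracavitary hot spots are low while an external-beam boost with a
  setup margin sits against the undisplaced organ.
* Four-field box: flat dose inside the field intersection with an erf
  penumbra (σ = 6 mm), ±2.5% ripple, and bony-landmark field borders
  (larger posterior margin) that cover the whole rectum, as a box technique
  does.
* Brachytherapy: inverse-square point-kernel superposition over a tandem of
  13 dwell positions (5 mm steps, 60 mm) plus two ovoid sources at triple
  dwell weight, normalised at a point-A-like prescription point 20 mm
  lateral at 20 mm above the vault. This loading reproduces the classical
  lateral gradient of roughly 200% → 100% between 10 and 20 mm from the
  tandem. Voxels at the sources are capped at 1000% of prescription — DVH
  metrics used downstream are insensitive to the cap. Linear attenuation is
  available but off by default; full TG-43 dosimetry is out of scope.
* Conformal boost: prescription ±3% inside the target, exponential falloff
  (8 mm constant) outside, with the prescription isodose carried ~2.5 mm
  outside the target as optimisers produce. The voxel-centre distance
  transform is corrected by half a voxel so the falloff is grid-independent.
* Cohort: groups I (post-operative, HDR 5 Gy × 3), II (post-operative,
  PDR 15 Gy in hourly 0.5 Gy pulses) and III (radical, PDR 15 or 30 Gy
  alternating), assigned in equal thirds; the external-beam boost
  prescription per patient is the isoeffective 1.8 Gy/fraction schedule.
  Pelvic course default 45 Gy / 25 fx (50.4 Gy / 28 fx configurable). All
  sampling derives from a single seed; identical seeds give byte-identical
  DVH CSV output.

### What the synthetic tests show — and what they do not

The phantom is idealised: no real anatomy, no optimiser, no inter-fraction
motion, and OAR-to-source distances that are conservative (no patient has an
applicator nearly touching the rectal wall, as occurs clinically). Cohort
*orderings* are therefore the meaningful reproduced claims — conformal
boosts conform better (CN), intracavitary boosts keep OAR hot spots lower
(rectum and bladder D_2cm³ as % of prescription), and the summed
conventional-plus-intracavitary treatment predicts higher rectal NTCP than
the all-conformal treatment — while absolute cohort means (TCP/NTCP
percentages in particular) are compressed relative to what heterogeneous
clinical cohorts show and should not be read as clinical estimates. The
bowel hot-spot ordering depends entirely on how close sigmoid loops come to
the tandem tip, which the phantom places conservatively far; it is reported
but not treated as a stable property. Problem sizes used throughout
(15-patient cohorts on 48³ grids, 500-organ refits) were chosen as the
smallest that leave the tested orderings and recovery margins stable.

## Degenerate inputs and tie-breaks

Empty masks, mismatched lattices, inconsistent regimen totals (beyond 1e−9),
non-positive α/β or T½, cumulative-on-cumulative transforms, hot volumes
exceeding the structure, and >1% structure-volume mismatches in plan
addition all raise typed errors. Zero-volume prescription isodoses return
CN = 0 with a warning. The HDR-equivalent solver is closed-form (quadratic)
and verifies its own round trip to 0.01 Gy.
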