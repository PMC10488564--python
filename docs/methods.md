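# Methods

## Scope

`iodect` implements the quantitative analysis pipeline used to differentiate
thymic epithelial tumors on dual-energy CT (DECT) iodine-density maps:
per-case feature extraction from paired unenhanced / 180 s equilibrium-phase
volumes, a seeded synthetic phantom cohort that emulates the published class
structure, and the downstream diagnostic statistics (Youden cutoffs, 2×2
Wald odds ratios, stepwise logistic selection, operating-point performance).
DICOM ingestion, spectral material decomposition, segmentation and
inter-phase registration are out of scope: volumes arrive as NIfTI iodine
maps with voxel-aligned masks.

## Feature definitions

Let `x_i` be the enhanced-phase iodine density (mg/cc) of the `i`-th voxel
inside the whole-tumor VOI, `n` the VOI voxel count, and `m_k` the k-th
central *population* moment of `{x_i}`.

* **maximum, minimum, median, average** — order statistics and mean of the
  raw voxel values.  No histogram binning is applied: the "histogram" is
  the per-voxel value distribution itself, so results do not depend on an
  arbitrary bin width.  The median of an even `n` is the midpoint of the
  two central order statistics.
* **SD** — sample standard deviation with the `n − 1` denominator.
* **skewness** = `m3 / m2^(3/2)`; **kurtosis** = `m4 / m2²` (non-excess: a
  normal distribution has kurtosis 3).  The non-excess convention is the
  one consistent with the per-case values the source workstation reports
  (per-case kurtosis ≈ 2.5–6.4 on roughly bell-shaped iodine histograms).
  With zero variance the shape moments are undefined; the result carries a
  `degenerate` flag and NaNs rather than a silent value.
* **iodine effect** (mg/cc) — VOI-average enhanced iodine minus VOI-average
  unenhanced iodine.  Under a fixed mask this equals the VOI average of the
  voxelwise phase difference.  Subtracting the unenhanced phase removes the
  decomposition's background/noise bias (true unenhanced iodine is zero;
  the map shows noise around a floor near −2.9 mg/cc).
* **ECV** (%) — `100 × (1 − hematocrit) × (Δtumor / Δaorta)`, with
  `Δ` the VOI-averaged enhanced-minus-unenhanced iodine density of the
  tumor and of aortic blood.  The assumption is contrast equilibrium at
  180 s: contrast distributes evenly through extracellular fluid, so the
  tumor-to-blood iodine ratio, corrected for the cellular fraction of
  blood, proxies the extracellular extravascular space, which tracks
  fibrosis.  `Δaorta ≤ 0` (no blood-pool enhancement) makes ECV undefined
  and raises an error rather than returning a sign-flipped number; in the
  batch pipeline such cases are routed to an exclusions file.

Texture statistics are computed on the *enhanced* volume: the published
cutoffs refer to contrast CT, and the equilibrium phase is where the tumor
signal lives.  Whether the source workstation used the enhanced or the
subtracted volume is not documented; this choice is ours and is stated, not
asserted as the original one.

ECV uses whole-VOI averages of the phase difference for both structures
(one ECV per case).  Per-voxel ECV maps are out of scope.

## Phantom cohort generator

The generator's purpose is to produce cohorts whose *feature distributions*
match the published per-class summary statistics, so every downstream stage
is testable without patient data.  It is a distributional phantom, not an
anatomical one.

Geometry: tumors are random ellipsoids (per-axis radii uniform in
8–14 mm) on a 56×56×36 grid at 1.0×1.0×1.25 mm spacing — VOIs of roughly
2–10×10³ voxels, matching mediastinal nodule scale; the aorta is a
cylinder of radius 8 mm, disjoint from the tumor.

Intensity model, per case with class parameters
(`mean_enhanced_iodine μ, sd_inter, sd_intra, necrosis range, ECV mean/sd`):

1. hematocrit ~ truncated Normal(0.42, 0.05) on [0.25, 0.55] — the adult
   reference range;
2. case mean `μ_case` ~ Normal(μ, sd_inter), truncated below at
   0.2 mg/cc (a tumor that does not enhance at all would leave ECV
   uncalibratable);
3. enhanced tumor voxels ~ Normal(μ_case, sd_intra); a contiguous
   ellipsoidal necrotic blob occupying a fraction `f` ~ Uniform(class
   range) of the VOI enhances like water, Normal(0, sd_intra);
4. unenhanced voxels are pure decomposition noise, Normal(0, 0.5 mg/cc),
   zero-mean by design;
5. both phases are clamped at the decomposition floor, −2.9 mg/cc.  With
   realistic voxel spread the VOI minimum censors onto the floor, which is
   why per-class minima pile up at −2.87…−2.9;
6. aortic enhancement is set per case so the expected ECV equals a
   per-case target drawn from the class ECV distribution (truncated below
   at 5%), given the drawn hematocrit and the realized tumor Δ.  ECV
   calibration is therefore decoupled from tumor uptake;
7. fibrosis grade ~ class-conditional categorical on {1, 2, 3}.

Default class calibration:

| class | iodine-effect target (mg/cc) | sd_inter | sd_intra | necrosis `f` | ECV target (%) | fibrosis P(1,2,3) |
|---|---|---|---|---|---|---|
| low-risk thymoma | 1.31 | 0.51 | 0.80 | 0–0.05 | 20.49 ± 7.22 | .60/.35/.05 |
| high-risk thymoma | 1.20 | 0.36 | 0.86 | 0.05–0.25 | 18.65 ± 5.97 | .50/.44/.06 |
| thymic carcinoma | 1.61 | 0.26 | 0.97 | 0.02–0.15 | 25.58 ± 4.67 | .00/.75/.25 |

`mean_enhanced_iodine` is the iodine-effect target divided by
`(1 − E[f])`: necrosis is *not* compensated per case, so more necrosis
lowers the cohort mean iodine effect — the mechanism by which high-risk
tumors, though biologically similar in viable-tissue uptake, show the
lowest uptake class-wide.  The between-case spread (`sd_inter`) and the
within-VOI voxel spread (`sd_intra`) are calibrated separately because the
published per-class summaries report both: the ± on the per-case means is
between-case spread, while the per-class mean of the per-case "SD" feature
is the voxel-level spread.  Fibrosis probabilities reproduce per-class
pathological score means of ≈1.45/1.56/2.25 with carcinoma confined to
grades {2, 3}.

Reproducibility: one cohort seed is expanded via `SeedSequence.spawn` into
a substream per case, so a case's draws do not depend on cohort ordering.

What the phantom does **not** emulate: CT texture (no partial-volume
effects, beam hardening or spatially correlated noise — voxels are i.i.d.
within compartments), morphology of invasion or lymphadenopathy, any
coupling between fibrosis grade and image content, and any voxel-level
distributional claim about the original patients (the study published only
summary statistics).  Consequently, passing calibration tests shows the
*pipeline* recovers the distributions it was pointed at — not that the
phantom is a substitute for external validation on real cohorts.

## Diagnostic statistics

* **Youden cutoff** — exhaustive search of `value > c` and `value ≤ c`
  over observed unique values, maximizing `J = sens + spec − 1`.  Ties
  break toward higher specificity, then smaller `|c|`, then the `>`
  direction, making the search deterministic and oracle-testable.  The
  source tool's exact grid is unknown; this rule is ours.
* **Odds ratios** — cross-product `ad/bc` with asymptotic Wald inference:
  `SE = sqrt(1/a + 1/b + 1/c + 1/d)`, CI `exp(ln OR ± z₀.₉₇₅·SE)`, two-
  sided normal p.  Recomputing the published counts with exactly this
  method lands on the printed CIs and p-values at printed precision, which
  identifies it as the method behind those tables.  No continuity
  correction by default; a zero cell yields a flagged non-estimable result
  (the divergent ~10⁸ "odds ratios" sometimes printed in such rows are the
  MLE separation artifact this flag replaces).  Haldane–Anscombe +0.5 is
  available behind an explicit flag.
* **Logistic models** — maximum likelihood via statsmodels.  On a
  saturated 2×2 the MLE OR equals the cross-product OR, which is property-
  tested.  Stepwise selection is forward-with-pruning: Rao score-test
  entry at p ≤ 0.05, Wald removal at p > 0.1, candidates pre-screened by
  univariate significance, lexicographic tie-breaks, every step logged.
  The published thresholds name no algorithm; this is the standard
  interpretation.  A candidate whose joint fit diverges (quasi-separation
  in the multivariable model: singular Hessian, non-finite SEs, or
  |coef| > 50) is rolled back and blocked from re-entry, with the event
  recorded in the trace.
* **Performance** — sensitivity `a/(a+c)`, specificity `d/(b+d)`; the AUC
  of a binarized predictor is the two-point trapezoidal ROC area
  `(sens + spec)/2`, which is exactly how the published AUCs (0.76, 0.69)
  relate to their printed operating points.  A rank-based AUC (ties ½) is
  provided for continuous scores.
* **Rank tests** — the three-group omnibus comparison is Kruskal–Wallis
  with tie correction.  (The source text names Friedman's test, which
  requires repeated measures; for three independent groups Kruskal–Wallis
  is the applicable omnibus test, and we implement that.)  Mann–Whitney U
  uses an exhaustive, tie-safe permutation enumeration when the combined
  sample is ≤ 20 (so identical groups give p = 1 exactly) and the tie-
  corrected normal approximation otherwise.
* **Multiplicity** — no correction is applied, matching the original
  analysis; reports echo the 9-feature family size so readers can judge.

## Embedded published rows

All eighteen binarized 2×2 rows (nine features × two contrasts) are
embedded with their printed OR/CI/p and, for the two headline predictors,
sensitivity/specificity/AUC.  `reproduce_printed_analysis()` recomputes
each estimable row and compares at printed precision (one unit in the last
printed digit).  Three rows are flagged rather than compared: the two
zero-cell rows, and the high-risk kurtosis row whose printed score labels
contradict its own counts.  Two further printed quirks are handled
explicitly: the high-risk "average" OR appears as 10.7 in the running text
but 10 in the table (10 is the cross-product of the table's counts and is
the value compared), and the SD-row p-value computes to 0.0455, half a
unit in the last digit from the printed 0.046.

## Problem sizes and numerical choices

Calibration checks run at 200 cases/class (sampling SE of the class ECV
mean ≈ 0.4 points against a ±1.5-point tolerance); stepwise causal-vs-noise
recovery uses 100 replicates of n = 200 with a true OR of 8; parameter
recovery on image cohorts uses 10 replicates at 200 cases/class.  Oracle
property suites use 200 random instances (Youden), all-pairs counting at
1e−12 (AUC), and 1e−6 relative agreement (logistic vs cross-product OR).
Floating-point volume I/O is float64 end to end; voxel spacing is carried
at full precision in the JSON sidecar because NIfTI header zooms are
float32.

## Known limitations

* The stepwise procedure and the Youden grid are reconstructions of
  under-specified published methods; both are deterministic and documented
  but may differ from the original vendor tools in tie cases.
* Cutoffs are chosen and evaluated on the same cohort (as in the original
  analysis); reported performance is therefore optimistic — no
  cross-validation is attempted.
* The phantom's voxel-level texture is a convention, so texture-sensitive
  features (skewness, kurtosis, maximum) should not be compared numerically
  against published per-class values; only the calibrated quantities
  (iodine effect, ECV, SD regime, fibrosis grades) are.
* Exact (conditional) OR inference is intentionally absent: the goal is the
  method the published tables actually used, and small-sample exactness
  would change the reproduced values.
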