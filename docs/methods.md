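# Methods

This note documents the computational conventions of the package: the
derivation formulas and their edge cases, the rule semantics, the
synthetic-data model, and the places where the design was genuinely open
and a choice had to be made.

## Unit conventions and input model

Inputs follow the clinical worksheet: lengths in cm except TAPSE and IVC
diameters (mm); velocities in cm/s except the regurgitant jets TR/MR
(m/s); volumes in mL; minute distance in cm/min. No unit inference or
conversion happens at input — a CSV dialect may *declare* units, and a
declaration that contradicts the canonical unit is a hard error.

Every measurement field is optional. Validation is finding-based: range
limits (wide physiologic bounds, e.g. VTI 5–60 cm, E 20–250 cm/s, e′ 1–30
cm/s, TAPSE 5–40 mm, HR 30–220 bpm, LVOT 1.5–3.0 cm) and logical
consistency (LVIDs < LVIDd, LVESV < LVEDV, IVCmin ≤ IVCmax, stage labels,
age within the 18–120 adult range) produce findings with severity; only
error-severity findings block the pipeline. Missing optional inputs
degrade gracefully: dependent indices stay absent and dependent rules
evaluate *indeterminate*, never silently normal.

Manual-entry overrides: a measurement set may carry worksheet values for
derived indices (e.g. an LV mass read from a different method, or an SVR
computed from pressures not otherwise recorded). Overrides replace the
computed value, are flagged `[manual]` in reports, and keep their indexed
companions consistent.

## Derivation conventions

- **BSA** is Du Bois, `0.007184·W^0.425·H^0.725`. This choice is
  load-bearing: for a 60 kg/160 cm patient Du Bois gives 1.62 m² where
  Mosteller gives 1.63, and downstream indexed values are sensitive to it.
- **Indexed quantities divide by BSA rounded to 2 decimals** — the number
  printed on the worksheet header — not the raw BSA. This is observable:
  105 mL / 1.90 = 55.3 mL/m², while 105 / 1.9031 would print 55.2.
- **Stroke volume uses the unrounded LVOT area** (π(d/2)²·VTI); the
  displayed CSA row is rounded for presentation only.
- **Heart rate** is taken as entered, else recovered as MD/VTI (the two
  are related by MD = VTI·HR); CO = SV·HR/1000 L/min, CI = CO/BSA₂dp.
- **PCWP** uses the linear E/e′ estimator `1.24·(E/e′) + 1.9` (Nagueh).
  The wedge-to-flow ratio `(E/e′)/SV` — a distinct quantity sometimes
  called PCWR — is computed alongside under its own name and is never
  substituted for the pressure estimate; all pressure-threshold rules
  bind the PCWP estimate.
- **RAP** follows the ASE inferior-vena-cava rule: 3 mmHg when IVCmax ≤ 21
  mm with collapsibility > 50 %, 15 mmHg when IVCmax > 21 mm with
  collapsibility strictly < 50 %, 8 mmHg otherwise (a collapsibility of
  exactly 50 % is the intermediate pattern).
- **LV mass** uses the ASE-corrected cube formula
  `0.8·1.04·[(IVS+LVIDd+PW)³ − LVIDd³] + 0.6` (dimensions in cm, grams).
- **Diastolic reserve index (DRi)** is a configurable plug-in slot on
  `compute_pair_indices` and is absent by default; no published closed
  form reproduces the worksheet values consistently, and no rule depends
  on it.
- **Stiffness index (LVSI)** is `(E/e′)/LVEDV`. The formula is recorded
  as provisional: it reproduces the HFpEF reference worksheet (0.21/0.22)
  but not the normal one, whose printed LVSI appears to come from a
  different definition. The stiffness rule (LVSI > 0.15 with E/e′ > 15)
  is a documented package convention, exposed in `ThresholdConfig`.

Degenerate inputs raise a `DomainError` carrying the offending field
(zero e′ or A-wave denominators, LVEDV ≤ LVESV, zero IVC or CO). All
computation is deterministic and pure; recomputation is bit-identical.

### Presentation rounding

Internal values keep full precision. The presentation layer rounds
half-away-from-zero to fixed per-parameter decimals, and the **dynamics
column is chained from the rounded stage values** ((peak − rest)/rest,
1 dp): a printed table is thereby self-consistent with its own cells,
which is how clinical worksheets behave. Pair-level dynamics used by the
rule engine remain full precision.

## Rule semantics

A rule is a conjunction of atoms *(parameter, comparator, named
threshold, stage binding)* with a scope (`rest`, `peak`, `either_stage`,
`pair`). Comparators are exactly as written — strict thresholds do not
fire on equality (E/e′ = 15.0 fails `> 15`). Evaluation is Kleene
three-valued: any false atom → *not fired* (even if another atom's value
is missing); otherwise any missing value → *indeterminate*; otherwise
*fired*. `either_stage` rules are evaluated per stage; `pair` rules once,
with stage-dependent parameters read at peak (the loaded state is the
diagnostic one). The Δe′ criterion written "Δe′ = 0" is implemented as
Δe′ ≤ 0: exact equality would be measure-zero on continuous data.

Two criteria deserve comment:

- **Borderline VTI (`VTI < 22 cm`)** binds the *peak* VTI at both grid
  columns. The 18–22 cm band is read as a flow-reserve question — does
  per-beat outflow distance reach the normal range under load? — rather
  than a resting screen; a resting VTI of 21 cm with brisk augmentation
  to 26 cm is not flagged.
- **"Elevated filling pressure despite preserved CO and EF"** is
  implemented as PCWP > 12 mmHg ∧ EF ≥ 50 % ∧ CO ≥ 4.0 L/min, and its
  resting-SVR sibling as SVR(rest) > 1,200 dyn·s·cm⁻⁵ with the same
  CO/EF qualifiers; the preserved-EF bound matches the population the
  tool is intended for.

All thresholds live in `ThresholdConfig` and can be overridden from a
YAML file; the merged configuration is echoed into every report for
audit. The rulebase itself serializes to YAML so the logic can be
reviewed and edited without code changes.

**Clustering.** Fired rules map to ordered diagnostic statements through
an explicit table (`DEFAULT_CLUSTERS`): filling-pressure, reserve,
stiffness, HFpEF-combination and vascular clusters each contribute one
label and one narrative line; the right-ventricular cluster contributes a
label only (it qualifies, but does not headline, a report). The
normal-pattern rule alone produces the four-line normal narrative; if it
fires alongside a pathological cluster the normal statement is suppressed
and the conflict is logged in the report. Every statement is supported by
at least one fired rule present in the trace, and every abnormal flag
comes from a satisfied atom of a fired rule.

## Synthetic cohorts

The generator emulates *measurement-level* variability around the two
built-in reference profiles (normal adaptation; HFpEF with impaired
reserve). Defaults: truncated-Gaussian draws per parameter with SD equal
to 7 % of the centroid magnitude, truncated to the plausibility ranges;
demographics from the intended source population (age 61.3 ± 8.7 years
truncated to 42–77, 58.2 % female). Only hard constraints are enforced on
top of independence: chamber ordering, MD = VTI·HR consistency, and the
phenotype-defining e′ response (Δe′ clamped ≤ 0 for HFpEF, ≥ 2 cm/s for
normal adaptation). With all SDs zero a draw equals its centroid exactly.

What this does *not* model — and therefore what passing tests do and do
not show: there is no inter-parameter covariance beyond the hard
constraints, no exercise-protocol physiology over time, no vendor or
reader effects, and no borderline phenotypes between the two centroids.
A perfect concordance on the noiseless synthetic cohort demonstrates that
the rule engine recovers the generating phenotype, not that the system
would reach any particular agreement on real patients. The observer
perturbation (`perturb_observer`) adds independent truncated-Gaussian
re-measurement noise per parameter and exists to exercise the agreement
statistics (ICC, κ), not to model real inter-reader behaviour.

## Agreement statistics

Implemented from first principles: 2×2 confusion metrics (undefined
proportions reported as NaN with a warning, never 0); Cohen's κ with
marginal-product expected agreement; ICC(2,1) — two-way random effects,
absolute agreement, single measure — from the two-way ANOVA mean squares
(the standard form for method-vs-expert continuous agreement; the form
choice is a documented convention); ROC AUC via the Mann–Whitney U
identity with midrank ties, CI by the Hanley–McNeil normal
approximation; and a simple primary-statement concordance rate. Library
implementations (scikit-learn, pingouin) are used in the test suite as
independent cross-checks only.

## Problem sizes and numerical choices

The package's own regression net runs at worksheet scale: two reference
studies row-by-row at printed precision (tolerance one unit in the last
printed digit, which also absorbs the worksheets' own chained rounding),
1,000 randomized straight-line oracle comparisons at ≤ 1e−9 relative
error, and statistical property checks at n = 200–10,000 (κ independence
|κ| < 0.05 at n = 10,000; AUC 0.5 ± 0.02 at n = 5,000; ICC
variance-component recovery ± 0.03 at n = 500; 200-study noiseless cohort
at 100 % concordance). Ties in rounding are broken half-away-from-zero
throughout.

## Known limitations

- Image-derived measurement extraction, DICOM handling and hardware
  integration are out of scope; inputs are structured numbers.
- A handful of worksheet rows in the reference material are internally
  inconsistent (one case's LV mass, MRPG and stiffness rows, one IVC
  collapsibility cell); these are carried as manual overrides or excluded
  from regression, as noted in the fixture module.
- The stiffness criterion and the DRi slot are explicit conventions, not
  guideline quantities.
- Cohort-level diagnostic performance (κ, ICC, AUC against expert
  readers) cannot be established from this package alone; the shipped
  statistics are the machinery for such a validation, exercised here only
  on synthetic data.
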