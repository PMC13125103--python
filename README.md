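# diastolic-cdss

Rule-based clinical decision support for assessing **left-ventricular
diastolic function during semi-supine bicycle stress echocardiography**,
aimed at functional-diagnostics laboratories working up exertional dyspnea
with preserved ejection fraction (suspected HFpEF).

Diastolic stress testing unmasks load-dependent filling abnormalities that
are invisible at rest, but interpreting it means juggling many
interdependent indices (E/e′, Δe′, TAPSE, VTI, TR velocity, estimated
PCWP, SVR, …) under time pressure — a recipe for inter-observer
variability. This package automates that interpretation with a fully
*explainable* pipeline: every conclusion is traceable to explicit
guideline-derived IF–THEN rules over deterministically computed indices.

## What it computes

From paired rest/peak measurement sets and demographics, the calculation
engine derives (full internal precision, presentation rounding separate):

- BSA (Du Bois, `0.007184·W^0.425·H^0.725`) and BMI; all indexed values
  divide by BSA rounded to 2 decimals, as on clinical worksheets
- LV geometry: EF, SF, RWT = 2·PW/LVIDd, LV mass by the ASE-corrected
  cube formula `0.8·1.04·[(IVS+LVIDd+PW)³ − LVIDd³] + 0.6`
- Flow: CSA_LVOT = π(d/2)², SV = CSA·VTI, HR (entered or MD/VTI),
  MD = VTI·HR, CO = SV·HR/1000, CI = CO/BSA
- Diastology: E/A, E/e′, PCWP ≈ 1.24·(E/e′) + 1.9, the wedge-to-flow
  ratio (E/e′)/SV under its own name, stiffness index (E/e′)/LVEDV
- Right heart: TRPG/MRPG = 4v², IVC collapsibility, RAP by the ASE
  3/8/15 mmHg rule
- Vascular: MAP = DBP + PP/3, SVR = (MAP − RAP)/CO·80
- Pair level: Δe′ = e′(peak) − e′(rest) and percent dynamics per parameter

The inference engine then evaluates a declarative rulebase (three-valued:
fired / not fired / indeterminate when inputs are missing) — e.g.
`Δe′ ≤ 0 AND E/e′ > 15 → "Impaired diastolic reserve"` — clusters fired
rules into ordered diagnostic statements, and renders a structured report
(text/markdown/JSON) with value table, criteria grid, conclusions and a
complete rule trace.

## Worked example

```bash
cdss fixtures --out fixtures/          # writes the two built-in reference cases
cdss run fixtures/case_b.json          # HFpEF with impaired reserve
```

For the HFpEF reference case (E/e′ 15.3→20.2, Δe′ = 0, TR 3.1→3.5 m/s,
TAPSE 16/15 mm) the report prints, among others:

```
Criteria grid
-------------
Criterion                                              Rest  Peak
-----------------------------------------------------  ----  ----
E/e' > 15                                              Yes   Yes
TAPSE < 17 mm                                          Yes   Yes
VTI < 18 cm                                            No    No
VTI < 22 cm                                            Yes   Yes
PCWP > 12 mmHg                                         Yes   Yes
E/e' > 15 + Δe' = 0 + TR > 3 m/s                       Yes   Yes
LAVi > 34 mL/m²                                        No    No
SVR > 1,200 + E/e' > 15                                Yes   No

Conclusions
-----------
Hemodynamic profile is consistent with HFpEF criteria.
Stress-induced elevation of left ventricular filling pressure.
Diastolic reserve, including indexed reserve, is impaired.
Impaired left ventricular filling due to increased myocardial stiffness.
```

Reading the grid: the resting E/e′ of 15.3 already exceeds the
filling-pressure threshold and maps to an estimated PCWP of
1.24·15.33 + 1.9 = **20.9 mmHg**; the absent e′ augmentation (Δe′ = 0)
together with TR > 3 m/s completes the HFpEF criteria combination at both
stages, while SVR (manually entered 1,228 → 755 dyn·s·cm⁻⁵) is elevated
only at rest. The normal-adaptation case (`case_a.json`) activates no
criterion and produces the four-line normal report instead.

Python API:

```python
from diastolic_cdss import case_b, derive_all
rest, peak, pair = derive_all(case_b())
print(rest.pcwp)          # 20.913...
print(pair.delta_e_prime) # 0.0
```

Other entry points: `cdss validate` (finding-based input checks),
`cdss simulate` (synthetic two-phenotype cohorts with truth labels),
`cdss evaluate` (sensitivity/specificity/PPV/NPV, Cohen's κ, concordance,
ROC AUC with Hanley–McNeil CI), and threshold/rulebase overrides via
`--config` / `--rulebase` YAML files.

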