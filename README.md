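# vttrial

Analysis machinery for a single-arm Phase II study of pre-surgical
(neoadjuvant) therapy aimed at shrinking venous tumour thrombus (VTT) —
tumour growing inside the renal vein (RV) and/or inferior vena cava (IVC)
in clear cell renal cell carcinoma.  The package is written for trial
statisticians and methodologists who need the full computational chain:
the two-stage design, exact inference that respects the interim stopping
rule, the bespoke anatomical endpoint rules, and a synthetic-cohort
generator so every stage is testable without patient-level data (which
are not publicly deposited).

## What it computes

**Simon two-stage design.** A design `(r1, n1, r, n)` enrols `n1`
patients, stops for futility if at most `r1` respond, otherwise enrols
`n − n1` more and declares success when total responses exceed `r`.
`vttrial.design.search_designs` enumerates all designs up to a ceiling
and returns the **minimax** design (smallest `n`) and the **optimal**
design (smallest expected sample size under the null), using exact
binomial sums throughout.  For the study's specification — unacceptable
response rate p₀ = 0.05 vs target p₁ = 0.25 at one-sided α = 0.10 and
power 0.90 — the minimax design is `(r1=0, n1=13, r=2, n=20)`.

**Design-adjusted inference.** After an adaptive two-stage rule, naive
x/n estimates and Clopper–Pearson intervals are biased.  The package
builds everything on the stage-wise tail probability

    Q(p) = P(reach stage 2 and X₁ + X₂ ≥ x | p),   X₁ ~ Bin(n₁, p), X₂ ~ Bin(n₂, p)

which is strictly increasing in p.  The design-adjusted p-value is
Q(p₀); the point estimate is the **median-unbiased** root of Q(p) = ½;
the two-sided confidence interval inverts Q at γ and 1 − γ with
γ = (1 − conf)/2; and the **UMVUE** is the ratio of truncated binomial
coefficient sums over stage-1 counts compatible with continuation.

**Endpoint rules.** Mayo level 0–4 of thrombus extent from the tip
landmark (level 1/2 boundary at 2 cm above the RV ostium), the per-patient
improvement call including the left-sided gonadal-vein sub-level rule,
percent change in summed thrombus length `100 × (1 − Sum_T / Sum_0)`,
the >30% thrombus partial-response call, RECIST v1.1 target-lesion
categories, planned-vs-performed surgical extent comparison, and
eligibility screens (Cockcroft–Gault clearance, ECOG, proteinuria,
MSKCC risk).

**Cohorts and pipeline.** `vttrial.cohort.generate_cohort` draws seeded
synthetic cohorts with the study's assumed structure;
`vttrial.cohort.reference_cohort` is a deterministic, hand-constructed
20-patient cohort (entirely synthetic) that reproduces the study's
published aggregates through the real classifier code.
`vttrial.pipeline.run_trial_analysis` derives every endpoint, applies
the decision rule and inference, and emits a JSON trial report.

## Worked example

```python
from vttrial import DesignSpec, TrialOutcome, infer, search_designs

design, props = search_designs(DesignSpec(p0=0.05, p1=0.25, alpha=0.10, beta=0.10))["minimax"]
print(design)                      # TwoStageDesign(r1=0, n1=13, r=2, n=20)
print(round(props.attained_alpha, 4), round(props.attained_power, 4))
# 0.0736 0.903

result = infer(TrialOutcome(total_responses=7), design, p0=0.05, conf_level=0.80)
print(f"{100 * result.estimate:.1f}% [{100 * result.ci_lower:.1f}%, "
      f"{100 * result.ci_upper:.1f}%], p = {result.p_value:.4g}")
# 32.8% [20.7%, 46.7%], p = 3.395e-05
```

Seven responders of twenty is an observed rate of 35%, but the
design-adjusted estimate is 32.8% because outcomes reaching stage 2 are a
selected subset; the 80% interval excludes the 5% null hypothesis by a
wide margin (p ≈ 3.4 × 10⁻⁵), so the trial's success criterion (≥ 3
improvements) is met with room to spare.

The numbered drivers under `analysis/` run the same computations as
scripts: `01_design_search.py`, `02_design_inference.py`,
`03_simulate_cohort.py`, `04_trial_report.py` (full report on the
packaged reference cohort) and `05_operating_characteristics.py`
(Monte-Carlo validation and an exact coverage audit of the confidence
interval).  Each writes its tables under `results/`.

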