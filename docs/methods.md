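# Methods

## Two-stage design model

The trial model is a single-arm binomial experiment with one interim
futility look.  Stage 1 enrols `n1` patients; if at most `r1` respond,
accrual stops and the null (response probability ≤ p₀) is retained.
Otherwise `n2 = n − n1` more patients are enrolled and the null is
rejected when total responses exceed `r`.  Rejection is *strict*
(`x > r`), so a published success rule of "at least three responses" maps
to `r = 2`.

All operating characteristics are exact binomial sums via scipy's stable
cumulative routines; no normal approximation is used anywhere.  The
rejection probability is

    P(reject | p) = Σ_{x1 = r1+1}^{n1}  Bin(x1; n1, p) · P(X2 > r − x1; n2, p)

and the expected sample size is `n1 + (1 − PET(p)) · n2` with
`PET(p) = P(X1 ≤ r1)`.

The search enumerates `n` from 2 to `n_max` (default 150; the shipped
analyses use 60, which is ample for the error rates considered), `n1`
from 1 to `n − 1` and `r1` from 0 to `n1`.  For fixed `(n, n1, r1)` the
type-I error is non-increasing in `r`, so the smallest `r` meeting the α
bound is located by bisection; only that `r` can also maximise power, so
larger `r` are pruned.  Minimax selects the feasible design with the
smallest `n`, ties broken by expected sample size at p₀ and then by
`n1`; optimal minimises expected sample size at p₀ outright.  For
p₀ = 0.05, p₁ = 0.25, α = 0.10, β = 0.10 the minimax design is
`(0, 13, 2, 20)` (attained α = 7.36%, power = 90.30%) and the optimal is
`(0, 9, 2, 24)` (EN(p₀) = 14.55 vs 16.41).

## Design-adjusted inference

Inference conditions on the sampling rule through the stage-wise tail

    Q(p) = Σ_{j = r1+1}^{n1} Bin(j; n1, p) · P(X2 ≥ x − j; n2, p),

with `P(X2 ≥ k) = 1` for `k ≤ 0`; for a stage-1 stop the tail is
`P(X1 ≥ x1)`.  The observed outcome is always included in the tail.
`Q` is continuous and strictly increasing in p for `x ≥ 1`, with
`Q(0) = 0` and `Q(1) = 1`, so every root below is found by bisection on
[0, 1] to absolute tolerance 1e-8 (200-iteration cap).

* **p-value:** `Q(p₀)`.
* **Point estimate:** the median-unbiased value solving `Q(p) = ½`
  (0 by convention when no responses occur).  For 7/20 responders under
  the `(0, 13, 2, 20)` design this is 0.32795 — reported as 32.8%,
  deliberately below the naive 7/20 = 35% because outcomes that reach
  stage 2 are a selected subset.
* **Confidence interval:** with γ = (1 − conf)/2, the lower bound solves
  `Q(p) = γ` and the upper bound `Q(p) = 1 − γ`.  Both bounds use the
  observed-inclusive tail; this is the convention under which the
  interval for 7/20 at 80% is (20.7%, 46.7%).
* **UMVUE:** after stage 2,
  `Σ_j C(n1−1, j−1) C(n2, x−j) / Σ_j C(n1, j) C(n2, x−j)` over
  `j` from `max(r1+1, x−n2)` to `min(n1, x)`; after a stage-1 stop the
  stage-1 MLE `x1/n1` is already unbiased.  Exact unbiasedness is
  verified by summation over the complete outcome space (tolerance
  1e-10), not by simulation.

**Degenerate outcome.** With zero responses `Q ≡ 1` and the upper bound
cannot be obtained by inverting `Q`; the package returns the exact
Clopper–Pearson upper bound for 0 successes in `n1` trials,
`1 − γ^(1/n1)`.

**Known limitation — interval coverage.** The observed-inclusive upper
bound is anti-conservative for small response counts.  Exact coverage of
the 80% interval under the `(0, 13, 2, 20)` design (computed by
`analysis/05_operating_characteristics.py` over the full outcome space)
is 0.926 at p = 0.05 and 0.933 at p = 0.15 but 0.699–0.732 around
p = 0.20–0.25.  The dual convention (`Q` at `x + 1` for the upper bound)
restores conservative coverage but yields a different interval
(upper bound 51.8% instead of 46.7% for 7/20); this package implements
the inclusive convention because it is the one the trial's published
interval uses.  The p-value itself is exactly super-uniform under the
null (verified over the outcome space), so test validity is unaffected.

**Attained vs planned sample size.** If the analysed cohort's evaluable
count differs from the planned `n`, inference keeps the planned
`(r1, n1, r)` with the attained stage-2 size and logs a
protocol-deviation warning; if the evaluable count does not exceed `n1`
the two-stage likelihood is undefined and the pipeline raises.

## Endpoint rules

* **Mayo level:** 0 = thrombus confined to the renal vein; 1 = IVC tip
  < 2 cm (20 mm) above the RV ostium; 2 = ≥ 2 cm but below the hepatic
  veins; 3 = at/above the hepatic veins, below the diaphragm; 4 = above
  the diaphragm.  A tip at exactly 2.0 cm is level 2: level 1 is defined
  strictly as "< 2 cm", and that strict reading wins over the ambiguous
  "> 2 cm" in the level-2 wording.  All lengths are stored in mm.
* **Improvement call:** for baseline level ≥ 1, any drop in level.  For
  level-0 disease, improvement is a caudad sub-level move that enables
  minimally invasive surgery: main RV → RV branches (right side), or
  main RV → lateral-to-gonadal / lateral-to-gonadal → branches (left
  side; the right gonadal vein drains directly to the IVC, so no
  right-sided gonadal sub-level exists).  Worsening at level 0 is
  extension into the IVC only; a craniad move *within* the renal vein is
  recorded as stable.  Consequently the call is antisymmetric under
  swapping baseline and follow-up for IVC-level disease but intentionally
  not for level-0 sub-level moves, and the property tests are scoped
  accordingly.
* **Length change:** `100 × (1 − Sum_T / Sum_0)` over the sum of RV,
  IVC-above-ostium and IVC-below-ostium components (positive =
  shrinkage); undefined and raised for a zero baseline sum.  A thrombus
  can lengthen without crossing a Mayo boundary; the pipeline reports
  level calls and length changes as separate outputs and does not
  reconcile them.
* **Missing week-9 scan:** both the Mayo and the length endpoint fall
  back to the week-3 scan when week 9 is absent; with neither, the
  patient is non-evaluable and reported as missing, never imputed.
* **RECIST v1.1:** target-lesion-sum arithmetic plus a new-lesion flag
  (CR = disappearance, PR = ≥ 30% decrease from baseline, PD = new
  lesion or ≥ 20% and ≥ 5 mm increase from nadir, else SD).  Non-target
  qualitative progression is out of scope.
* **Surgical change:** less extensive if any of (a) open → minimally
  invasive, (b) lower level of venous control (six-step ordinal from
  "thrombus milked into RV, side clamp" to "suprahepatic,
  supradiaphragmatic clamp"), (c) smaller incision extent rank.
* **Reporting precision:** percentages are rounded half-up to 1 dp for
  display; all internal values stay unrounded.

## Synthetic cohorts

The generator emulates the study conditions, with all defaults fixed
from the published marginal summaries: 20 patients; baseline Mayo levels
drawn 4/3/9/2/2 (in 20ths); improvement probability 0.25 for level 0 and
0.375 for levels 1–4; week-9 percent length change Gaussian with mean
27.2 and SD 18 (SD chosen so the central 95% range brackets the reported
−20% to 51% spread); week-3 change = 0.5 × week-9 change plus noise
(week-3 vs week-9 medians were roughly 15% vs 27%), with direction
concordance enforced with probability 1 by default; 15% missing week-9
scans; 19% surgical dropout.  Mayo response is drawn first and length
change conditionally (responders always shrink); the joint distribution
of level response and length change is unreported beyond marginals, so
this coupling is one defensible choice among several.  Tip positions and
component lengths are kept mutually consistent (the IVC-above component
equals the tip distance), and stable patients' tips stay within their
level band so a drawn non-responder never drifts across a boundary.
When the week-9 scan is missing, the week-3 scan carries the patient's
response (early change was reported to be predictive of the week-9
result), so derived improvement frequencies match the configured
probabilities under the fallback rule.

The generator does **not** model dosing trajectories, adverse-event
biology beyond fixed per-term frequencies, imaging error, survival, or
correlation between response and surgical dropout beyond a simple
downstaging bonus for responders.  Passing tests on generated cohorts
therefore demonstrate correctness of the derivation and inference code
under the assumed structure, not fidelity of that structure to real
patients.

`reference_cohort()` is a separate, fully deterministic 20-patient
construction (no RNG) that reproduces the published aggregate results —
7/20 improved (six IVC, one left-sided gonadal-rule responder), none
worsened, 15/20 with any length reduction, 7/17 operated patients with
less extensive surgery — while exercising every documented classifier
path, including the week-3 fallback.  Its CSVs are committed under
`src/vttrial/data/` and byte-stability is asserted in tests.  It is a
synthetic reconstruction consistent with printed totals; no per-patient
row corresponds to a real participant.

## Problem sizes used in shipped analyses

Design searches run to `n_max = 60`; Monte-Carlo validation of the
rejection probabilities uses 200,000 replicated trials; coverage audits
use exact outcome enumeration (and 10,000 simulated trials per response
rate in the test suite); law-of-large-numbers checks of the generator
use 20,000 patients.
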