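# Methods

This note records the model, the synthetic data-generating process, the
numerical choices and the limitations of `htndtr`, at the level of
detail a user needs to judge what passing tests do and do not show.

## Decision process

**State space.** Patient state at a visit is the 5-tuple
(complications, age flag, diabetes-duration level, BP level, BMI level)
with 2·2·3·3·3 = 108 states, encoded mixed-radix
(index = 54·comp + 27·age + 9·period + 3·bp + bmi).  Conventions worth
noting:

* the age component is a *flag for being younger than 55* (value 1 =
  younger), so the lower-risk group carries the higher code;
* BP staging takes the worse of the systolic (<140 / 140–159 / ≥160
  mmHg) and diastolic (<90 / 90–99 / ≥100 mmHg) categories — the
  standard clinical convention when the two disagree; readings below
  120/80 fall into the lowest (prehypertensive) level, since the model
  has no separate normotensive level;
* interval boundaries are half-open with the boundary in the upper bin
  for BMI (18.5, 25) and BP (160, 100), and in the lower bin for
  diabetes duration (a duration of exactly 4 years is level 0, 8 years
  is level 1), following the stated component definitions;
* complication status is a prefix scan: one I11/I12/I13 claim turns the
  flag on for every later visit.

**Action space.** The 14 regimens over {D, ACEi, ARB, CCB}: four
monotherapies, all six pairs, all four triples, in a fixed id order
(1–4 mono, 5–10 dual, 11–14 triple).  The *tier* of an action is its
class count.

**Reward.** R(a, s′) = R_WTP · U(s′) − C_MED(a), where U is one QALY
degraded by five multiplicative utility decrements looked up per
component level of the *resulting* state (complications 0.010/0.248;
age 0.08 below 55, 0.129 at or above; duration 0.078/0.085/0.112;
BP 0.034/0.125/0.278; BMI 0.028/0.07/0.172).  The age and duration
decrements are attached exactly as the formula writes them even though
treatment cannot influence those components.  R_WTP has no canonical
numeric value in this setting; the package defaults to R_WTP = 1 so
rewards live on the QALY scale, and medication costs default to a
0 / 0.01 / 0.02 ladder per tier — a mild parsimony pressure that breaks
value ties toward fewer drugs.  Only the ratio cost/R_WTP matters:
scaling R_WTP and all costs by c > 0 scales every reward by c and leaves
the greedy policy unchanged (asserted by test).

## Offline learning

Transitions (s, a, r, s′) are extracted from consecutive visit pairs;
the earlier visit must carry a prescription, and the reward is computed
from the resulting state.  The fit sweeps the sample set in a seeded
shuffled order applying the α-weighted backup.  Numerical choices:

* **Step size.** Default α = N(s,a)^−0.6 (per-pair polynomial decay);
  a constant α (including α = 1, the plain overwrite rule) is available.
  A constant step size leaves an O(α) oscillation floor on a fixed
  offline dataset, which both prevents a convergence tolerance from
  being met and lets near-tied argmaxes flip.
* **Polyak tail averaging.** With `polyak_tail = t` the returned table
  is the average of the raw iterates over the last fraction t of sweeps
  (default one half).  On a fixed sample set this drives the iterate to
  the empirical Bellman fixed point: the oracle tests reach
  max |Q − Q*| ≈ 1e−4 against exact value iteration, and the greedy
  policies coincide on batches of random MDPs.
* **Q initialisation** is zero — pessimistic relative to the ≈ 0.3–0.95
  per-step rewards, so actions never observed in a state cannot win the
  argmax.
* **Tie-breaking** is toward the lowest action id everywhere (Q-table
  argmax, doctors' modal prescription).  Since ids order mono < dual <
  triple, ties resolve toward fewer drugs.
* **Support restriction.** Recommendations are restricted to actions
  observed in the state; by default an action additionally needs
  ≥ 5 recorded visits (`min_support`, capped at the state's
  best-supported count so a state whose only observed action is rare
  still gets a recommendation).  A Q estimate backed by one or two
  transitions is a single noisy draw, and without the threshold such
  flukes win the argmax in a visible fraction of rarely-visited states.
* **Convergence** is declared when the largest absolute change over a
  full sweep (of the averaged iterate, when averaging) falls below
  `tolerance` (default 1e−4), else after `max_sweeps`.

The baseline estimates a maximum-likelihood transition tensor with
add-k smoothing over next states (default k = 0.5, i.e. 54 pseudo-counts
per row against the 108-state space) and a mean-reward table, then
solves them by value iteration (Bellman-optimality backups to a 1e−9
sup-norm residual; the residual sequence contracts at factor γ and is
exposed for inspection).  With k = 0.5 the baseline is heavily shrunk
toward uniform transitions wherever data are thin, which is why it
trails the sweep-based learner at realistic sample sizes; value
iteration on the *unsmoothed* empirical model is the exact oracle used
in tests.  γ defaults to 0.9; ε-greedy selection (ε default 0.1) exists
for interactive use and plays no role in the offline fit.

## Synthetic cohort: what it emulates

The generator stands in for a national claims extract (check-ups,
diagnosis claims, prescriptions) whose real counterpart is not
redistributable.  Its planted structure:

* **Severity and appropriate tier.**  severity = 3·complications +
  bp_level + 1{bmi_level = 2}, mapped to mono (≤1), dual (2–3), triple
  (≥4).  The canonical regimen of a tier is its lowest action id
  (ARB; ARB+CCB; ARB+CCB+D).
* **Action quality** q(s,a): 1.0 for the canonical regimen, 0.35 for
  other regimens of the right tier, 0.2 one tier off, 0 two tiers off.
  The within-tier gap encodes that specific class combinations matter,
  not just the drug count.
* **Dynamics.**  BP and BMI follow birth–death steps whose improvement
  probability rises with q and worsening probability falls with q;
  complication onset hazard is (0.005 + 0.075·strength·(1−q)) ·
  (1 + bp_level) and the complication state is absorbing.  Age flag and
  duration level are static within a follow-up window.  All action
  dependence is proportional to `appropriateness_strength`
  (default 0.8); at 0 the action has no effect on transitions.  Under
  the default reward, the canonical regimen of the appropriate tier is
  the exact optimum of the ground-truth MDP (value iteration recovers
  the planted policy in all 108 states, with a minimum action gap of
  ≈ 0.02 and median ≈ 0.09 on the Q scale).
* **Prescribing behaviour.**  Doctors prescribe the canonical regimen
  and deviate uniformly over all 14 regimens with probability
  `doctor_noise` scaled by the patient's diabetes-duration level
  (0.5× / 1.0× / 2.5×) — variability is higher for long-standing,
  complex histories.  Duration is static and has no effect on the
  response dynamics, so deviation is exogenous to the health
  trajectory: the relation between a patient's model-concordance and
  their outcomes is a planted causal dose-response, not a confound, and
  the duration gradient spreads per-patient concordance across the full
  bucket range.
* **Visit schedule.**  Visits are every 120 days (default), horizon 8
  (10 in the full-scale checks), entry dates uniform over 2003–2008.
  The window length is validated against 3.6 years so that a patient's
  diabetes-duration band cannot cross a 4-year boundary mid-window —
  the condition under which re-discretization of the emitted records
  reproduces every planted state index exactly (the round-trip
  invariant the tests assert on all visits).
* **Emission.**  Continuous measurements are drawn inside the numeric
  band of each visit's discretized component (with margins so rounding
  cannot cross a boundary); every patient gets an I10 claim at entry
  and a diabetes claim at the planted onset date before entry;
  complication states emit one I11/I12/I13 claim at onset; each visit
  carries a prescription with days_supply = interval × adherence, the
  patient's adherence drawn once from U[0.25, 0.9].

What it does **not** emulate: irregular visit timing, dropout and
mortality, measurement error that crosses category boundaries, dose
(as opposed to class) decisions, medication side effects, secular
trends, and any demographic realism (no sex stratification; age and
duration are category-consistent rather than distribution-matched).
Passing tests therefore demonstrate that the pipeline recovers a
planted signal from correctly formatted records at realistic sample
sizes — not that the learned policies are clinically valid.

## Evaluation conventions

* **Concordance rate**: states where the model's recommendation equals
  the doctors' modal prescription, divided by the full 108-state space
  ("paper" mode; states undefined on either side count as unmatched) or
  by the states where both are defined ("supported" mode).  Percentages
  are reported to two decimals by truncation (92/108 → 85.18).
* **MPR** is capped at 100%.  The MPR "of the model's recommendations"
  is computed over prescription episodes whose drug-class set equals
  the recommendation for the visit's state, with the covered period
  taken as one inter-visit interval per concordant episode (inferred
  from the patient's median visit gap when not supplied).
* **Per-patient concordance** is visit-weighted over visits that have
  both a prescription and a recommendation; patients with no eligible
  visit are excluded.  Bucket curves use the five bins [0,20) … [80,100]
  and report empty bins as absent rather than zero.
* **Complication occurrence** counts claims strictly after the first
  visit (incident events), and the occurrence curve is computed over
  patients complication-free at baseline — the at-risk population; a
  patient already carrying the complication cannot have an incident
  event.
* **BP-level outcome** is the discretized level at the final visit
  (configurable to the mean over visits).

## Problem sizes used by the checks

The full-scale checks simulate 50,000 patients × 10 visits
(≈ 450,000 transitions), where the learned policy recovers the planted
regimen in ≥ 90% of states with ≥ 30 visits (100% of states when
prescribing is noise-free and recommendations are support-restricted);
the oracle-equivalence benchmark uses 20 random MDPs of up to 12 states
and 4 actions with exhaustively replicated samples; unit tests run on a
2,000-patient cohort (12,000 visits).  The acceptance script repeats the
full-scale run end to end.

## Known limitations

* The learner is purely tabular; states observed rarely get guarded,
  not generalised, recommendations (no function approximation by
  design).
* The MDP baseline's construction (smoothing level, tie handling) is a
  reasonable convention, not a calibrated reproduction of any specific
  prior system.
* Concordance against the doctors' *modal* action discards within-state
  prescribing heterogeneity.
* No off-policy evaluation estimators (importance sampling, doubly
  robust) and no causal adjustment are provided; on real observational
  data the concordance-outcome curves would be confounded by severity,
  and the package's causal reading holds only under the synthetic
  generator's exogeneity construction.
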