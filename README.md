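# htndtr

Offline tabular Q-learning for antihypertensive treatment recommendation
in patients with hypertension and type 2 diabetes.

## The problem

Hypertension in type-2 diabetics is managed by choosing among four
antihypertensive drug classes — diuretics (D), ACE inhibitors (ACEi),
angiotensin-II receptor blockers (ARB) and calcium-channel blockers
(CCB) — singly or in combination, escalating from monotherapy to dual
and triple therapy as the patient's condition worsens.  Claims and
check-up records from national health databases contain millions of
(state, prescription, outcome) episodes from which a sequential decision
rule — a dynamic treatment regime — can be learned without any model of
human physiology.  This package implements that pipeline end to end for
users who work with flat claims-style record tables: epidemiologists and
biostatisticians prototyping reinforcement-learning treatment policies,
and methodologists who need a fully testable stand-in for restricted
registry data.

## The model

Each visit is discretized into a five-component state

S<sub>t</sub> = (S<sub>COMPLICATIONS</sub>, S<sub>AGE</sub>, S<sub>PERIOD</sub>, S<sub>BP</sub>, S<sub>BMI</sub>)

with 2 x 2 x 3 x 3 x 3 = 108 states: hypertensive heart/kidney
complications (ICD-10 I11/I12/I13, 0/1), age (&lt;55 flag), years since
diabetes onset (&le;4 / 4–8 / &gt;8), blood-pressure stage
(prehypertension / stage 1 / stage 2) and BMI category (under / normal /
overweight).  Actions are the 14 regimens over the four drug classes
(4 mono + 6 dual + 4 triple).  The reward of action *a* landing in state
*s'* is a quality-adjusted life-year (QALY) utility degraded by five
multiplicative decrements, minus medication cost:

R(a, s') = R<sub>WTP</sub> · (1−d<sub>COMP</sub>)(1−d<sub>AGE</sub>)(1−d<sub>PERIOD</sub>)(1−d<sub>BP</sub>)(1−d<sub>BMI</sub>) − C<sub>MED</sub>(a)

The action-value table is fitted offline from recorded transitions by
sweeping the Q-learning backup

Q(s<sub>t</sub>, a<sub>t</sub>) ← (1−α) Q(s<sub>t</sub>, a<sub>t</sub>) + α [ r<sub>t</sub> + γ max<sub>a</sub> Q(s<sub>t+1</sub>, a) ]

(α = 1 gives the plain overwrite backup); the greedy policy of the
converged table is the recommendation.  An empirical-MDP baseline
(maximum-likelihood transition model + value iteration) is fitted from
the same samples for comparison, and value iteration doubles as the
exact oracle in the test suite.  Validation statistics mirror clinical
practice: the state-wise concordance rate against the doctors' modal
prescriptions, the medication possession ratio
(MPR = 100 · days supplied / days in period) of model-concordant
prescriptions, and outcome curves across 20%-wide buckets of per-patient
concordance.

Because the registry data behind such studies cannot be redistributed,
the package ships a synthetic cohort generator with a *planted* ground
truth: a treatment-response MDP in which the severity-appropriate
therapy tier maximises the probability of improvement.  Every stage of
the pipeline is therefore testable against a known optimum (see
`docs/methods.md`).

## Worked example

`examples/03_evaluate_against_doctors.py` simulates 20,000 patients with
8 visits each, fits the recommender, and evaluates it:

```text
concordance (percent of the 108 states where the policies agree):
       model       reference  matched_states  concordance_rate
  q_learning          doctor              92             85.18
  q_learning planted_optimal              92             85.18
mdp_baseline          doctor              49             45.37
mdp_baseline planted_optimal              49             45.37

MPR of model-concordant prescriptions, by therapy tier:
  tier  min  max  mean
  mono 25.0 90.0 57.52
  dual 25.0 90.0 57.37
triple 25.0 90.0 56.87

complication occurrence by patient-concordance bucket:
  bucket  mean_outcome  n_patients
  [0,20)      0.780876         251
 [20,40)      0.509686        1497
 [40,60)      0.327165        1513
 [60,80)      0.166171        5043
[80,100]      0.034424        8744
```

Reading the numbers: the fitted Q-table reproduces the doctors' modal
prescription (and the planted optimal regimen) in 92 of 108 states, a
concordance rate of 85.18%; the smoothed empirical-MDP baseline recovers
far fewer states at this sample size.  Mean adherence of
model-concordant prescriptions sits inside the simulated 25–90% range,
and patients whose prescriptions agree with the model more often have
strictly fewer incident complications — the planted dose-response
recovered from raw record tables.  The other example scripts cover
simulation (`01`), policy fitting and state-level recommendations
(`02`), and the value-iteration oracle/baseline (`04`).

A thin CLI wraps the same stages:

```bash
htndtr simulate --n-patients 2000 --horizon 8 --seed 7 --out raw/
htndtr build-cohort --in raw/ --out visits.csv
htndtr train --cohort visits.csv --out qtable.csv
htndtr evaluate --cohort visits.csv --policy policy.csv \
    --claims raw/claims.csv --out-dir report/
htndtr demo --n-patients 2000 --seed 7 --out-dir demo/
```

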