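# mcda4hta

Multi-criteria decision analysis (MCDA) for health technology assessment
(HTA): AHP group weighting over an HTA Core Model criteria hierarchy,
fuzzy encoding of mixed-type evidence, and three ranking engines — fuzzy
TOPSIS, fuzzy VIKOR and goal programming — that score technology
alternatives so that **lower values are better**.

It is aimed at HTA analysts and operations researchers who want a
transparent, reproducible alternative to deliberative-only appraisal:
the panel's value judgments enter only through the criterion weights,
while the scores come straight from the HTA report's evidence.

## The model

A goal sits on top of a criteria tree of up to four levels; the nine
first-level criteria are the HTA Core Model domains (health problem,
technical characteristics, safety, clinical effectiveness, costs and
economics, ethical, organizational, social, legal). Each parent node with
≥ 2 children yields one Saaty-scale pairwise comparison matrix per panel
respondent; the full packaged hierarchy requires 85 matrices delivered as
10 questionnaires (one for the main criteria, one per domain).

* **Weights.** Respondent matrices are pooled by element-wise geometric
  mean; local weights are the principal right eigenvector `w` of the
  pooled reciprocal matrix `A` (`Aw = λ_max w`), with consistency
  monitored by `CR = (λ_max − n)/((n − 1)·RI(n))` and `CR > 0.1` flagged.
  Global leaf weights are path products, summing to 1.
* **Scores.** Cells are numeric (`x → (x,x,x)`), yes/no (`1/0`), or one
  of 7 linguistic terms mapped to triangular fuzzy numbers `(l, m, u)`.
  Benefit columns are normalized by `u/c*`, cost columns by the
  reciprocal `a⁻/u` form, onto `[0, 1]` support.
* **Ranking.** Fuzzy TOPSIS reports the distance share to the ideal
  `d⁺/(d⁺ + d⁻)` under the vertex metric; fuzzy VIKOR reports
  `Q = v·(S − S*)/(S⁻ − S*) + (1 − v)·(R − R*)/(R⁻ − R*)` (v = 0.5);
  goal programming reports the weighted normalized absolute deviation
  from per-criterion goals. Rank 1 is the minimal index everywhere.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

The packaged dialysis-style fixture compares peritoneal dialysis (PD)
with hemodialysis (HD) over the full 282-criterion hierarchy with a
synthetic 12-respondent elicitation (see `docs/methods.md` for exactly
what is and is not synthetic about it):

```python
from mcda4hta import MCDADecisionModel, dialysis_fixture

hierarchy, weights, table = dialysis_fixture()
results = MCDADecisionModel(hierarchy, table, global_weights=weights).fit()
print(results.summary())
```

```
MCDA decision report (mcda4hta 0.1.0)
==============================================
goal: Select the best renal replacement modality
alternatives: PD, HD
criteria used: 198

configuration (all values explicit):
  methods = fuzzy_topsis,fuzzy_vikor,goal_programming
  vikor_v = 0.5
  defuzz = graded_mean
  scale = default7
  strict_cr = False
  aggregation = judgments
  eigen_method = eigenvector
  vikor_fuzzy_arithmetic = False

indices (lower = better):
    fuzzy_topsis  fuzzy_vikor  goal_programming
PD         0.137          0.0             0.199
HD         0.246          1.0             0.586

fuzzy_topsis: best = PD
fuzzy_vikor: best = PD
goal_programming: best = PD
```

All 198 scored leaf criteria enter the ranking; PD attains the lower
(better) index under every method. With only two alternatives VIKOR's Q
collapses to {0, 1} whenever the group-utility and max-regret orderings
agree. The TOPSIS value 0.137 says PD sits 13.7% of the way from the
fuzzy ideal toward the anti-ideal; the goal-programming value 0.199 is
PD's weighted average shortfall from the per-criterion goals.

The same pipeline runs from the shell on files:

```sh
mcda4hta synth --seed 3 --out study/          # synthetic hierarchy + responses + scores
mcda4hta plan --hierarchy study/hierarchy.json --out study/plan.csv
mcda4hta weights --hierarchy study/hierarchy.json --responses study/responses.csv \
                 --out study/weights.csv
mcda4hta rank --hierarchy study/hierarchy.json --table study/performance.csv \
              --weights study/weights.csv --method all --out study/report/
```

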