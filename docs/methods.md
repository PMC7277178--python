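# Methods

## The decision problem

`mcda4hta` implements an integrated multi-criteria decision analysis (MCDA)
workflow for health technology assessment (HTA). A technology choice (e.g.
between two renal replacement modalities) is structured as a goal over a
criteria hierarchy of up to four levels whose nine top-level criteria are
the domains of the HTA Core Model: health problem and current use,
technical characteristics, safety, clinical effectiveness, costs and
economic evaluation, ethical analysis, organizational aspects, social
aspects, and legal aspects. Two inputs drive the analysis:

* **weights** — the preferences of a multi-disciplinary decision panel,
  elicited as Saaty-scale pairwise comparisons (one reciprocal matrix per
  parent node with at least two children) and turned into global leaf
  weights by the Analytic Hierarchy Process (AHP);
* **scores** — evidence extracted from the HTA report, one row per
  technology alternative and one column per leaf criterion, as numeric
  values, yes/no judgments, or 7-level linguistic terms.

Scores are embedded into triangular fuzzy numbers (TFNs), normalized, and
ranked by three engines — fuzzy TOPSIS, fuzzy VIKOR, and goal
programming — all reported so that a **lower index means a better
alternative**, which lets the three columns of the result table be read
the same way.

## AHP weighting

Each pairwise matrix `A` is reciprocal (`a_ii = 1`, `a_ij a_ji = 1`) with
questionnaire entries on Saaty's {1..9} scale and reciprocals. Local
weights are the principal right eigenvector of `A`, computed by power
iteration (tolerance 1e-12 on the weight vector, cap 10,000 iterations);
the row geometric-mean approximation is available as
`eigen_method="geometric_mean"` and coincides with the eigenvector for
consistent matrices.

Panel aggregation defaults to aggregation of individual judgments:
element-wise geometric mean of the respondents' matrices before the
eigenvector is extracted. The geometric mean is the only pooling rule that
preserves reciprocity algebraically. Aggregation of individual priorities
(arithmetic mean of per-respondent eigenvectors) is available via
`aggregation="priorities"`; neither variant is canonical in group-AHP
practice, so both are exposed rather than hard-coded.

Coherence is tracked by Saaty's consistency ratio
`CR = (λ_max − n)/((n − 1)·RI(n))` with the standard random-index table for
orders up to 10 (orders 1–2 return 0 as they are consistent by
construction; larger orders are rejected — the packaged hierarchy never
exceeds order 9). `CR > 0.1` emits a warning and is recorded in the
report; it aborts only under `strict_cr=True`. Weight elicitation in the
emulated setting has no revision loop, so a hard failure would be wrong by
default.

Global leaf weights are products of local weights along the root-to-leaf
path; a parent with a single child contributes factor 1. Telescoping of
the per-sibling normalizations makes the global leaf weights sum to 1.

## Fuzzy encodings and normalization

* numeric `x` → degenerate TFN `(x, x, x)`;
* `yes`/`no` → `(1,1,1)` / `(0,0,0)`;
* a linguistic term → its entry in the active 7-term scale.

The shipped `default7` scale places term `k` (k = 1..7) at
`(max((k−2)/6, 0), (k−1)/6, min(k/6, 1))` on `[0, 1]`. The term-to-TFN anchors used in the original dialysis
application are not part of its openly available summary tables, so any
other scale must be supplied as a `term,l,m,u` CSV via `load_scale`.

Normalization is linear and direction-aware, per column `j`:

* benefit: divide every support point by `c*_j = max_i u_ij`;
* cost: with `a−_j = min_i l_ij`, map `(l, m, u) → (a−/u, a−/m, a−/l)`.

The reciprocal form for costs keeps the TFN ordering `l ≤ m ≤ u` valid
without sign flips; it requires strictly positive cost scores, so zero or
negative cost cells are rejected with a suggestion to pre-shift. After
normalization every support lies in `[0, 1]`, every column has one
alternative attaining upper support 1, and all columns behave as benefit
criteria.

A cell missing for *any* alternative drops the whole column (an MCDA
comparison is meaningless on evidence that covers only one comparator);
the surviving columns' weights are renormalized and the event is logged
and echoed in the report.

## Ranking engines

**Fuzzy TOPSIS.** On the weighted normalized matrix `v_ij = w_j r_ij`, the
per-column fuzzy positive ideal is `(w_j, w_j, w_j)` and the negative
ideal `(0, 0, 0)`. Distances use the vertex metric
`d(a,b) = sqrt(((Δl)² + (Δm)² + (Δu)²)/3)`, summed over columns into
`d⁺_i` and `d⁻_i`. The reported index is `d⁺/(d⁺ + d⁻)` — the *distance
share to the ideal* — rather than the classical closeness coefficient, so
lower is better like the other two engines. If `d⁺ + d⁻ = 0` (single-point
degenerate matrix) the index is 0.5 by convention and a warning is logged.

**Fuzzy VIKOR.** Default route: defuzzify cells (graded mean
`(l + 4m + u)/6` by default; centroid `(l + m + u)/3` optional), then
crisp VIKOR: `S_i = Σ_j w_j (f*_j − x_ij)/(f*_j − f⁻_j)` (direction-aware
best `f*` and worst `f⁻`), `R_i` the largest summand, and
`Q_i = v(S_i − S*)/(S⁻ − S*) + (1 − v)(R_i − R*)/(R⁻ − R*)` with `v = 0.5`
("consensus") by default. A constant column contributes 0; if all
alternatives tie on S (or R) that Q term is dropped, and fully identical
alternatives give `Q = 0` for everyone, logged. An alternative route
(`vikor_fuzzy_arithmetic=True`) keeps TFN arithmetic in the per-criterion
deviations and defuzzifies at the end; the two routes coincide on crisp
inputs. VIKOR's acceptable-advantage and acceptable-stability conditions
are computed and reported as booleans but never alter the indices.

**Goal programming.** Goals are the per-column direction-aware best
defuzzified scores on the normalized scale; the index is
`Σ_j w_j |g_j − x_ij| / (g_j − b_j)` with `b_j` the per-column worst (a
column with `g_j = b_j` contributes 0). Because the per-alternative LP
with deviation variables `d⁺, d⁻ ≥ 0` and constraints
`x_ij + d⁻ − d⁺ = g_j` decouples across alternatives and criteria, its
optimum equals this closed form; an LP route (`solver="lp"`, HiGHS via
scipy) is kept purely as a cross-check oracle and is verified against the
closed form to 1e-9 in the test suite.

Ranks are 1 = best by ascending index, ties broken by document order of
the alternatives. Reports print indices to 3 decimals; full precision is
kept internally.

## The synthetic generator

`SyntheticSpec` fixes the emulated study conditions: a 12-person panel by
default, judgment noise `a_ij = (w_i/w_j)·exp(ε)` with
`ε ~ Normal(0, σ²)` and σ = 0.1 by default (each pair judged once, the
reciprocal mirrored, so matrices are valid by construction), optional
snapping of ratios to the nearest Saaty level in log space (on by
default, emulating questionnaire output), a 50/20/30 numeric/binary/
linguistic column mix, and a 15% share of numeric leaves scored as costs.
Binary and linguistic leaves are always benefit-directed: a `no` (0) or a
bottom-of-scale term in a cost column would make reciprocal normalization
undefined, and in practice cost criteria are numeric.

With σ = 0 the generated matrices are exactly consistent (snapping is
skipped at σ = 0 so the consistent-matrix identity holds to machine
precision). Without snapping, the pooled-weight error shrinks
monotonically as σ → 0; with snapping the error floors at the Saaty
quantization level, so σ-convergence is asserted on unsnapped judgments.

What the generator does **not** emulate: correlated or biased
respondents, incomplete questionnaires, real evidence distributions, or
criteria interactions. Green tests therefore certify the algebra and the
pipeline, not the behaviour of any real panel.

## The packaged dialysis-style fixture

`table1_hierarchy()` and `dialysis_fixture()` package a **synthetic**
stand-in for the peritoneal dialysis (PD) vs hemodialysis (HD)
application. The original criteria tree, evidence matrix and elicited
weights are not openly available beyond summary tables, so the fixture
reconstructs everything that those summaries pin down and
draws the rest deterministically (seed 3608):

* per-domain criteria counts over levels 2–4 exactly as published
  (totals 9 / 45 / 115 / 113);
* an attachment pattern chosen by balanced allocation so the elicitation
  plan has exactly **85** pairwise matrices grouped into **10**
  questionnaires, with no matrix above order 9 (level-3 parent counts per
  domain: 7, 12, 1, 5, 0, 2, 2, 3, 1);
* weights from a full synthetic 12-respondent elicitation (σ = 0.15,
  Saaty-snapped, geometric-mean pooled);
* evidence drawn so PD scores at least as well as HD on most benefit
  criteria while HD scores better on the cost-domain criteria — the
  qualitative structure of the original finding (PD best despite higher
  societal cost) — with all three kinds of cells present.

### Reproduction status of the reported worked-example indices

Because the fixture's evidence values are synthetic, the index values
reported for the original application are **not reproduced**; each is
listed here as a documented discrepancy, and the property suite (oracle
equivalence, dominance consistency, VIKOR limits, consistency identity,
parameter recovery) is the authoritative gate for the engines themselves.
The fixture's own indices are recomputed at run time by
`scripts/acceptance.py` (`*_index` entries), never stored.

| method           | alternative | reported index | reproduced? |
|------------------|-------------|----------------|-------------|
| fuzzy VIKOR      | PD          | 0.018          | no — synthetic evidence |
| fuzzy VIKOR      | HD          | 0.978          | no — synthetic evidence |
| fuzzy TOPSIS     | PD          | 0.309          | no — synthetic evidence |
| fuzzy TOPSIS     | HD          | 0.677          | no — synthetic evidence |
| goal programming | PD          | 0.191          | no — synthetic evidence |
| goal programming | HD          | 0.327          | no — synthetic evidence |

Two structural remarks. With only two alternatives, crisp VIKOR drives Q
to the extremes {0, 1} unless the S- and R-orderings disagree, so the
reported intermediate pair 0.018/0.978 implies a mild S/R conflict in the
original evidence that a synthetic table has no way (and no right) to
re-create. The TOPSIS and GP scales depend directly on the unpublished
evidence spreads.

## Numerical choices and problem sizes

* power iteration: tol 1e-12, cap 10,000; reciprocity symmetrized
  algebraically after geometric-mean pooling;
* weight-sum and TFN-ordering invariants enforced at 1e-9;
* defuzzification default: graded mean (common in fuzzy-VIKOR practice);
* degenerate conventions: TOPSIS 0.5, VIKOR all-zero Q, GP zero-span
  columns contribute 0 — each logged;
* test suite sizes: 100 random consistent matrices, 500 dominance
  problems, 100 instances each for the GP-LP, TOPSIS brute-force and
  VIKOR-limit oracles, 15–25 panels per noise level for recovery; the
  whole suite and the acceptance script each run in well under a minute
  on one CPU.

## Known limitations

* The fixture is a structural stand-in; nothing numerical about the
  original evidence or elicited weights should be inferred from it.
* Fuzzy AHP, trapezoidal/type-2 fuzzy numbers, interval judgments,
  incomplete-matrix completion and outranking methods (ELECTRE,
  PROMETHEE) are out of scope.
* Crisp TOPSIS/VIKOR exist only implicitly (degenerate TFNs), not as
  first-class outputs.
* VIKOR's compromise conditions are informative only; no sensitivity
  analysis beyond re-running with perturbed inputs is built in.
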