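# price-cea

Cost-effectiveness analysis of multi-tier diagnostic workflows, modelled as
recursive decision–action–result trees — with support for both expert-alone
and AI-delegated decision-making.

Rare-disease diagnosis (the bundled case study covers developmental delay and
multiple congenital anomalies, DD & MCA) typically proceeds through tiers of
genetic testing: chromosomal microarray (CMA) first, then a targeted gene
panel (GP) and/or exome sequencing (ES), each tier ordered after an expert
review of the previous result. Which sequence is the best value depends on
test costs, diagnostic yields, turnaround times and how much a family weighs
accuracy against speed. This package is for health-economics analysts and
clinical-genomics researchers who want those trade-offs computed per pathway
rather than from static population averages.

## Model

A diagnostic process is a rooted tree `T = (N, E)` of decision, action,
result and exit nodes. Node `n_i` carries a cost `C_i` and turnaround time
`T_i` (weeks); edge `(i, j)` carries a transition probability `P_ij` with
`Σ_j P_ij = 1`. Three quantities summarise a strategy:

* **Expected cost** via the leaf-to-root recursion (BECC)

  `EC⁺_i = C_i` at leaves, `EC⁺_i = C_i + Σ_j P_ij · EC⁺_j` otherwise;
  the root value is the expected cost of the whole process.

* **Expected effectiveness**: each root-to-exit path ends in an outcome
  state `(O, TAT)` with utility

  `U(S) = α · EGU + (1 − α) · e^(−λ·TAT)`,

  where `EGU = PPV·U_TP + (1 − PPV)·U_FP` for a positive final result (NPV
  analogue for a negative one), PPV/NPV derive from prevalence and the final
  test's sensitivity/specificity, and λ penalises diagnostic delay.
  Effectiveness is the probability-weighted sum of `U(S)` over all paths.

* **Effective cost** = expected cost / expected effectiveness — the
  cost per unit of effectiveness used to rank strategies.

Under **AI delegation**, a decision node is replaced by an AI action node
that predicts whether the cheaper test will succeed. Above a confidence
threshold `r*` the test is ordered automatically — the branch carries no
expert fees or consultation delays and the test's yield becomes the AI's
precision `P_AI = P(positive | predicted positive)`; below `r*` the workflow
falls back to the human decision.

## Worked example

Build the two-tier CMA + GP strategy and evaluate it at α = 0.5, λ = 0.03:

```bash
price casestudy --scenario 1 --out scenario1.json
price cea scenario1.json --alpha 0.5 --lambda 0.03
```

```json
{
  "effective_cost": 3554.7232951216356,
  "expected_cost": 2620.665,
  "expected_effectiveness": 0.7372345981462183,
  "expected_tat": 16.404
}
```

The strategy costs $2 620.67 in expectation (entry consult, an $825 CMA,
and — for the 90 % of patients with a negative CMA — a further consult and a
$1 500 gene panel), takes 16.4 expected weeks, and delivers 0.737 units of
effectiveness, i.e. $3 554.72 per effectiveness unit. The same library calls
are available in Python:

```python
from price import build_scenario, default_utility_params, cost_effectiveness_report
report = cost_effectiveness_report(build_scenario(1), default_utility_params(alpha=0.5))
print(report.effective_cost)   # 3554.72...
```

Ask at what AI precision the delegated CMA→(AI)→GP→ES pathway becomes a
better value than both multi-tier expert strategies:

```bash
price crossover --baselines 2,3 --alpha 0.5
```

```json
{
  "alpha": 0.5,
  "baselines": "2,3",
  "crossover_precision": 0.41429687500000006,
  "gate_prob": 1.0
}
```

Once the AI predicts positive gene panels with precision above ≈ 0.41–0.43,
automation beats both expert-alone alternatives on effective cost.

Other subcommands: `price validate`, `price cost` (per-node expected costs),
`price simulate` (Monte-Carlo cohort), `price delegate` (restructure any
tree), `price sweep` (parameter grids as CSV) and `price psa` (probabilistic
sensitivity analysis over the parameter priors). All stochastic commands
require `--seed` and are bit-reproducible.

## Layout

* `price.tree_model` — tree schema, validation, path enumeration, JSON (de)serialization
* `price.cost_engine` — BECC expected cost/TAT, cohort simulator, random-tree generator
* `price.effectiveness` — predictive values, utility model, effective cost
* `price.ai_delegation` — delegation transform, crossover search
* `price.case_study` — DD & MCA parameter registry, scenario builders, sweep engine
* `price.uncertainty` — distribution specs, sampling, probabilistic sensitivity analysis
* `price.cli` — the `price` command

See `docs/methods.md` for modelling assumptions and numerical choices.
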