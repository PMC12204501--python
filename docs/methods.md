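# Methods

## Model structure

A diagnostic workflow is a finite rooted tree. Decision nodes are expert
judgment points (office visits: fee `C_E`, consultation turnaround `T_E`);
action nodes execute a test or consultation (test cost and turnaround);
result nodes carry the dichotomous outcome of the preceding test and are
free and instantaneous; exit nodes terminate the process. The recursive
"decision–action–result" character of real workflows is represented by
explicit unrolling: the structure must be acyclic, and cycles are rejected
at validation, because the expected-cost recursion only terminates on
acyclic structures. Every non-root node has exactly one parent, outgoing
transition probabilities sum to one (absolute tolerance 1e-9 — inputs are
hand-written decimals), and result→decision transitions are trivial (one
child). Trivial decision nodes (a single option) are permitted and carry
whatever cost the document assigns; automation expresses fee waivers by
setting the cost to zero, not by changing the schema. Result values are
categorical; a numeric variant is reserved in the schema but rejected by
the utility model (continuous-valued tests have no utility mapping here).

## Expected cost and TAT

Expected cost is computed by an explicit post-order (leaf-to-root)
traversal of the recursion `EC⁺_i = C_i + Σ_j P_ij EC⁺_j`, rather than
call-stack recursion, so depth is not bounded by interpreter limits.
Expected TAT reuses the identical recursion with `T_i` substituted for
`C_i`, which is valid because expectation is linear along paths; per-path
TATs used by the utility model come from path enumeration, not from this
aggregate. Two independent checks ship with the package: exhaustive path
enumeration (`Σ_path prob · cost`) and a multinomial-cascade cohort
simulator that splits `n` patients among children at every node — exact
equality to 1e-9 relative for the former, 3-standard-error agreement at
n = 200 000 for the latter.

## Effectiveness

Outcome-state utility is `U = α·EGU + (1−α)·e^(−λ·TAT)` with the TAT
accumulated over *all* nodes on the path, including decision-node
consultation times; α ∈ [0, 1] weighs accuracy against timeliness and λ
(per week) tunes urgency, restricted to [0.01, 0.1] in sweeps for a
clinically gradual decay. EGU weighs `U_TP` against `U_FP` via the PPV for
positive final results, and `U_TN` against `U_FN` via the NPV for negative
ones. NPV is the standard Bayes complement `Sp(1−p)/(Sp(1−p)+(1−Se)p)` —
the unique formula consistent with the term "negative predictive value".
The EGU for a positive result is read as a sum, `PPV·U_TP + (1−PPV)·U_FP`,
with `U_FP ≤ 0` carrying the disutility sign.

Two predictive-value modes exist. The default, `final_test`, evaluates the
final test's Se/Sp at the baseline prevalence — how PPV/NPV are usually
entered into a dashboard from published per-test values. `serial_bayes`
instead updates the prevalence by Bayes' rule after every preceding
negative result on the path, compounding information across tiers; it is
exposed as an option because which convention a given published analysis
used is rarely stated. Positive intermediate results are not updated on
(they terminate the pathway in all bundled scenarios). Paths that exit
without any test result — and AI gate labels, which are not diagnostic
outcomes — receive a configurable neutral EGU (default 0) while still
earning the timeliness term. Effective cost is expected cost divided by
expected effectiveness; a non-positive effectiveness raises an explicit
error rather than returning ±inf.

## AI delegation

The transform replaces one expert decision node: an AI action node (cost
and TAT zero by default, both configurable) splits into two result nodes at
threshold r*. The gate probability q = P(r ≥ r*) is a free parameter: at
the population level it lies in (0, 1); conditioned on one patient the
score is fixed, so q ∈ {0, 1}. Case-study sweeps default to q = 1 (the
automated branch active), since the reference comparison plots a single
AI-mode curve against the expert strategies without stating a population
gate rate; sensitivity to q is exposed through the sweep and delegate
interfaces. The automated branch is fully automated: every decision node
inside it becomes an AI actor with zero cost and TAT, so no expert fee or
consultation delay is incurred between the gate and the exit. The automated
test's *yield* becomes the AI precision, but its Se/Sp — and hence PPV/NPV —
are unchanged: the AI alters which patients take the test, not the test's
accuracy. Degenerate gates leave the dead branch in place with zero mass,
flagged in the tree's metadata, so the structure stays inspectable.

The precision crossover is found by bisection to tolerance 1e-4 after a
101-point monotonicity pre-scan (ties broken toward the smaller precision);
a non-monotone objective raises an error directing the caller to a dense
grid scan instead of silently bisecting a non-bracketing interval.

## Case-study parameterization

Point values: expert fee 165, CMA 825, gene panel 1500, ES 4589.4 (USD);
turnarounds 2/4/8 weeks for CMA/GP/ES and 4 weeks per expert consult; AI
decisions take 0 weeks. Yields: CMA 0.1; GP 0.11; ES 0.37/0.35/0.33 as a
first/second/third-tier test (the yield of a deeper tier conditions on the
earlier negatives and is approximated by the marginal yield of that tier).
Prevalence 0.1665; reference AI precision 0.87; utilities U_TP = U_TN = 1,
U_FP = U_FN = −1. Decisions whose only option is to exit still carry the
expert fee — the terminal review is billed like any office visit — with a
`free_exit_decisions` toggle for sensitivity analysis.

Known registry tension, preserved deliberately: the GP-yield beta prior
Beta(24, 89) has mean ≈ 0.21 while the deterministic point value is 0.11.
Deterministic runs use the point values throughout; the priors feed only
the probabilistic sensitivity analysis.

## Uncertainty analysis

Priors: CMA cost Gamma(shape 2010, rate 2.44) — the shape/rate reading has
mean ≈ 823.8, consistent with the 825 point value, whereas shape/scale
(mean ≈ 4904) would contradict every printed CMA cost; ES cost
Normal(4589.4, sd 45) truncated at 0; GP cost Uniform(1450, 1750); yields
Beta with the published pseudo-counts (naturally confined to (0, 1), no
extra truncation). Truncation is enforced by rejection with a cap of 1000
resamples per value. The PSA redraws all parameters jointly and
independently, rebuilds the tree per draw and recomputes all three metrics;
draws with non-positive effectiveness are retained with an undefined
effective cost, excluded from that metric's summary, and counted. The whole
pipeline is bit-reproducible under a fixed seed (a single numpy Generator
drives all sampling). Because expected cost is multilinear in the
independent draws, the PSA cost mean converges to the cost at the
distribution means — used as a convergence check at 2000 draws.

## What the simulators do and do not show

The cohort simulator and the random-tree generator (alternating node kinds,
Dirichlet edge probabilities, uniform costs, fixed seeds) exercise the
algebraic contracts of the engine — recursion vs. enumeration vs. sampling
on thousands of structures. They emulate the *model's* randomness, not
clinical reality: transition probabilities are population marginals, tests
are conditionally independent given disease status, utilities are fixed
constants, and costs are point prices rather than payer-negotiated amounts.
Passing tests therefore certify internal consistency and faithful
implementation of the model, not the external validity of any particular
parameter registry.

## Numerical and scale choices

Probability sums and path-probability totals use absolute tolerance 1e-9;
oracle-equivalence checks use 1e-9 relative. Property-test problem sizes —
1000 random trees for recursion/enumeration equivalence, 200 000-patient
cohorts, 100 000-draw sampler-moment checks, 2000-draw PSA convergence — are
the package's own test-design choices balancing statistical power against a
fast default suite. Serialization is canonical JSON (sorted keys, two-space
indent, nodes sorted by id) so that documents are byte-stable and
diff-friendly; parsing re-applies defaults, making round-trips exact
identities.

## Known limitations

No discounting of future costs, half-cycle corrections, or infinite-horizon
(Markov) processes — the tree model targets short-horizon diagnostic
episodes. No utilities for continuous-valued test results. No learning of
patient-conditional transition probabilities: personalised probabilities
enter as user-supplied parameters. Parameter draws are independent;
correlated PSA and value-of-information analysis are out of scope.
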