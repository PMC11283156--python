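# Methods

## Problem and model

`fedcopd` simulates a federated-averaging (FedAvg) system for a binary
clinical classification task: predicting whether an acute exacerbation of
COPD (AECOPD) admission belongs to the mild (label 0) or severe (label 1)
group from ~40 tabular clinical features. The motivating scenario is the
"data island" problem: patient records are scattered across hospitals that
cannot pool raw data for legal and privacy reasons, so K simulated hospitals
train a shared model by exchanging only parameters.

The classifier is a small fully connected network (default
40 → 32 → 16 → 1, ReLU hidden units, logistic-sigmoid output) trained by
plain minibatch gradient descent on mean binary cross-entropy

L(θ) = −(1/N) Σ_j [ y_j log p_j + (1 − y_j) log(1 − p_j) ],   θ ← θ − η ∇L(θ),

with no momentum, weight decay, or adaptive rates. Each communication round
r, every client runs E local epochs from a copy of the broadcast global
parameters, and the server replaces the global model with the **unweighted
elementwise arithmetic mean** of the K uploads,
θ^{r+1} = (1/K) Σ_k θ_k^r. A sample-size-weighted mean is available behind
`FLConfig(weighted=True)` but is off by default, since clients hold
equal-sized shards in the default design. After each aggregation every
client scores its own held-out test set with the new global model; this
per-round prediction log (`RES`) is the evaluation substrate, and headline
metrics use the final round.

The comparison arm (reported as "CML", which in this system's usage means
*isolated per-site training*) trains the identical network on each client's
shard alone. Its budget is matched: `total_epochs = r·E`, exactly the number
of gradient passes a federated client performs across all rounds, consumed
in blocks of E epochs with the same derived per-(client, round) seeds. This
makes the federated advantage attributable to parameter sharing rather than
extra optimisation, and makes a K=1 federation *bitwise identical* to local
training (a tested invariant).

## Hyperparameters

| symbol | meaning               | default | notes                              |
|--------|-----------------------|---------|------------------------------------|
| K      | number of clients     | 3       | all clients participate each round |
| r      | communication rounds  | 350     | scaled-down batteries use 50       |
| E      | local epochs / round  | 5       |                                    |
| B      | minibatch size        | 10      | last short batch kept              |
| η      | learning rate         | 0.001   | plain SGD                          |
| T      | train:test split      | 7:3     | train size = floor(share·n)        |

Probabilities are clipped to [1e−7, 1 − 1e−7] before logs for numerical
stability; the analytic gradient uses the exact sigmoid/cross-entropy
cancellation ∂L/∂z = (p − y)/N, so clipping affects reported losses only.
Weights are initialised N(0, 1/fan_in) with zero biases, seeded.

Each client standardises features with its **own** training-set mean and sd
(applied unchanged to its test set). No cross-client statistics are shared,
preserving the data-locality premise.

## Synthetic cohort generator

The source data are private hospital records, so the generator emulates
their published summary structure rather than any record-level property:

- 220 mild + 188 severe records (408 total), shuffled, with exact per-group
  sex counts (188/157 male), reproducing the 345 male / 63 female totals
  deterministically rather than in expectation.
- Eight vitals (age, hospitalization count, systolic/diastolic pressure,
  temperature, pulse, respiratory rate) whose per-group means are published
  as normal-theory 95% CIs. The generator inverts each CI at the group size
  (z = 1.959964): mean = midpoint, sd = (half-width/z)·√n, and draws from a
  normal truncated to broad physiological bounds.
- Filler columns of standard-normal noise, identically distributed in both
  groups, pad the schema to 40 features; all discriminative signal therefore
  comes from the published vitals. The real feature list beyond the
  summarised vitals is unknown, so the fillers are a declared convention,
  not an inference.

Truncation bounds are chosen so the truncated mean stays far inside the
Monte-Carlo tolerance of the CI-recovery check (all default bounds lie
≥ 3.4 sd from the group means). Two consequences of taking the published
intervals at face value are worth stating. First, the hospitalization-count
CI inverts to sd ≈ 7 at mean ≈ 6.5 (severe group): a nonnegative truncated
normal cannot have a coefficient of variation above 1, so this feature is
left unbounded by default and can produce negative draws — a known
unrealism of the normal marginal model for a skewed count. Second, only
marginal intervals are published, so features are drawn independently;
real vitals are correlated, and nothing here models that. Passing the
generator-fidelity tests therefore shows the marginal sampling model is
self-consistent, not that the cohort is clinically realistic.

Cleaning filters mirror the described preprocessing: features with a
missing fraction **strictly greater than** 10% are dropped first (a feature
at exactly 10% survives — the literal reading of "greater than"), then any
record with a remaining missing cell is excluded; counts for both stages
are reported. Hospitals are simulated by simple random sampling without
replacement into K disjoint equal shards (136 each at defaults; the real
per-hospital sizes are unstated, so equal thirds are assumed).

## Determinism

Every run is a pure function of one master seed. Stage seeds (cohort,
partition, per-client split, initialisation, per-(client, round) minibatch
order) are derived via `numpy.random.SeedSequence([master, stream, ...])`.
Aggregation sums uploads over clients sorted by identifier, so client-order
permutation invariance is exact, not approximate.

## Experiment batteries and problem sizes

`run_comparison` executes generate → clean → partition → split → both arms
on identical shards and initialisation → the metric battery (accuracy,
precision, recall, F1 via the standard confusion-count formulas; AUC by the
rank/Mann–Whitney formulation with ties credited 0.5; decision threshold
0.5 with ties predicted positive). Improvements are reported as absolute
percentage points (federated minus isolated).

Sweeps cover per-client sample size (50–350 in steps of 50; the cohort is
scaled up proportionally when K·size exceeds 408, preserving the 220:188
group ratio), communication rounds, and the five split ratios 5:5 … 9:1.
Repeated randomized trials rerun the full pipeline m times (m=100 by
default) and summarise each metric per arm as mean ± 1.959964·sd/√m.

The directional federated-vs-isolated comparison is checked at the default
convergent operating point (r=350) over 20 master seeds with a
percentile-bootstrap 95% CI of the mean accuracy improvement; running it at
a heavily reduced round count would test the method where it is known not
to have converged (an under-communicated federation has no edge — the
rounds-effect check verifies exactly that by comparing mean advantage at
r=350 vs r=10 over 10 seeds). These sizes are the package's chosen
desk-scale operating points; at them, the federated arm's advantage is a
reproduced *direction*, not a reproduction of any particular published
magnitude, since the synthetic cohort shares only summary statistics with
the real one.

## Degenerate inputs and tie-breaks

- Precision/recall/F1 with a zero denominator return 0 and emit a
  `DegenerateMetricWarning` (tiny test sets in sweeps would otherwise
  abort); accuracy on an all-zero tally is an error.
- ROC requires at least one positive and one negative; the traced curve
  always starts at (0,0) and ends at (1,1), and its trapezoidal area equals
  the rank AUC exactly when scores are tie-free.
- Train/test splits clamp so both sides are nonempty whenever a shard has
  at least two records.
- A federation with r=0 returns its initial parameters and an empty
  prediction log; comparisons then score the untrained model directly, so a
  forced self-comparison yields exactly zero improvement.

One expected-but-unverifiable pattern deserves a note: federation should
help *most* where shards are smallest. At desk scale this trend is not
resolvable — with 50 records per client the 15-record test sets make the
per-seed advantage swing by several points, and a 10-seed comparison of
per-client sizes 50 vs 136 showed no separation beyond noise — so the test
suite asserts the existence of the advantage and its growth with rounds,
not its growth with scarcity.

## Known limitations

- No real network transport, encryption, differential privacy, secure
  aggregation, stragglers, or client dropout: federation is in-process and
  privacy is by data locality only.
- Marginal-only, correlation-free synthetic features; negative draws
  possible for the hospitalization count (see above).
- The backbone's hidden sizes, activation, and initialisation are declared
  package conventions; the original system documents only "a fully
  connected network".
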