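# quorumpool

Quorum voting by signal-detection-optimal decision-makers.

Groups everywhere pool independent binary judgements — flocks deciding
whether a predator is present, diagnostic panels screening for disease,
classifier ensembles fusing votes. The textbook guidance comes from the
Condorcet Jury Theorem: give each voter a single accuracy *a*, use
simple majority rule, and group accuracy converges to 1 when *a* > ½
(and to 0 when *a* < ½). But real binary decisions admit **two** error
types. An optimal individual facing Gaussian cues with an asymmetric
prior or asymmetric error costs ends up with distinct state-wise
accuracies — a true positive rate *a*₊ and a true negative rate *a*₋ —
and once these straddle ½, majority voting is suboptimal and the
Condorcet predictions fail in systematic ways. Choosing a **quorum**
*q* strictly inside the interval (1 − *a*₋, *a*₊) restores convergence
of group accuracy to 1.

`quorumpool` is for quantitative biologists, decision scientists and
ensemble-learning practitioners who want to compute, exactly and by
simulation, what quorum-voting groups of optimal individuals achieve.

## The model

**Individual.** A scalar cue is drawn from N(μ₋, σ²) in state "−" and
N(μ₊, σ²) in state "+" (μ₊ > μ₋); state "+" has prior probability *p*;
outcomes carry costs C_TP, C_TN, C_FP, C_FN (errors costlier than
correct outcomes). The cost-minimising rule decides "+" when the cue
exceeds

```
x* = (μ₊ + μ₋)/2 + σ² ln β / (μ₊ − μ₋),   β = (1 − p)(C_FP − C_TN) / [p (C_FN − C_TP)]
```

giving *a*₊ = 1 − Φ((x* − μ₊)/σ) and *a*₋ = Φ((x* − μ₋)/σ), a point on
the ROC curve. Expected individual accuracy is
*a* = p·*a*₊ + (1 − p)·*a*₋.

**Group.** N voters are conditionally independent given the state; the
group decides "+" when the "+"-vote count strictly exceeds q·N (exact
ties, possible only when q·N is an integer, are coin-flipped by
default). Exact group accuracy follows from binomial tails; as N → ∞ it
converges to

```
p·1{a₊ > q} + (1 − p)·1{1 − a₋ < q}
```

which equals 1 exactly when 1 − *a*₋ < q < *a*₊. At q = ½ with
mixed-sign accuracies the limit is *p* or 1 − *p*: the three Condorcet
predictive failures are **Error Ia** (predicted → 1, converges to the
limit instead), **Error Ib** (Ia, and the limit is below the individual
accuracy, so groups are *worse* than individuals) and **Error II**
(predicted → 0, converges to a positive limit). A fourth combination —
predicted → 0 yet groups beating individuals — is algebraically
impossible.

## Worked example

A high-prior, costly-false-positive ecology (μ₋ = 0, μ₊ = σ = 1,
p = 0.9, C_FP = 4, C_FN = 1, C_TP = C_TN = 0):

```python
from quorumpool import (DecisionEcology, optimal_operating_point, expected_accuracy,
                        GroupRule, group_accuracy_exact, quorum_bounds,
                        recommend_quorum, classify_scenario)

eco = DecisionEcology(mu_minus=0.0, mu_plus=1.0, sigma=1.0, p=0.9,
                      c_tp=0.0, c_tn=0.0, c_fp=4.0, c_fn=1.0)
point = optimal_operating_point(eco)
majority = group_accuracy_exact(point, eco.p, GroupRule(n=1001, q=0.5))
q, label = recommend_quorum(point)
quorum = group_accuracy_exact(point, eco.p, GroupRule(n=1001, q=q))
```

prints (via the accompanying formatting statements):

```
threshold x* = -0.3109
a_plus (TPR) = 0.9051, a_minus (TNR) = 0.3779
individual accuracy a = 0.8523
majority group (N=1001, q=0.5): accuracy = 0.9000
quorum interval = (0.6221, 0.9051); recommend q = 0.7636 (super_majority)
quorum group (N=1001, q=0.7636): accuracy = 1.000000
error class = error_ia, prediction = to_one, actual limit = 0.90
```

Reading: the optimal individual tolerates a poor true negative rate
(0.378) because state "−" is rare and false positives are costly. Each
voter is 85% accurate, so classic reasoning predicts a 1001-strong
majority group is essentially perfect — in fact it converges to the
prior 0.9 (Error Ia): the group always picks "+", and is right exactly
as often as "+" occurs. A super-majority quorum inside
(0.622, 0.905) makes the same group perfect.

The same computations are available from the shell:

```sh
quorumpool optimal-rates --mu-minus 0 --mu-plus 1 --sigma 1 --p 0.9 \
    --c-tp 0 --c-tn 0 --c-fp 4 --c-fn 1
quorumpool group-accuracy --a-plus 0.9051 --a-minus 0.3779 --p 0.9 --q 0.5 --n 1001
quorumpool simulate --panel a --reps 10000 --seed 42 --out curve.csv
quorumpool figure2 --out-dir maps/
```

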