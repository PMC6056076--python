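# Methods

## Model family

All classifiers factorise the joint distribution of a discrete attribute
vector x = (x₁, …, xₙ) and class y as P(x, y) = P(y) ∏ᵢ P(xᵢ | Πᵢ, y),
where Πᵢ is attribute i's parent set, and classify by the posterior
P(y | x) ∝ P(x, y). The members differ only in how Πᵢ is chosen:

* **NB**: Πᵢ = ∅ (0-dependence).
* **TAN**: |Πᵢ| ≤ 1; the parents form the maximum spanning tree of the
  complete graph weighted by conditional mutual information I(Xᵢ; Xⱼ | Y),
  rooted at the lowest attribute index with arcs directed away.
* **AODE**: an ensemble of n superparent models; member j conditions every
  other attribute on (Xⱼ, Y). Prediction averages member joints over
  superparents whose value occurs in the training data, then normalises.
* **KDB**: attributes sorted by I(Xᵢ; Y) descending; the attribute at rank
  r takes the min(r−1, k) higher-ranked attributes with largest
  I(Xᵢ; Xⱼ | Y) as parents. The arc count is deterministic:
  Σᵣ min(r−1, k).
* **KDB_P** (lazy): the same rules with the local measures — ordering by
  I(xᵢ; Y) and parent choice by I(xᵢ; xⱼ | Y) — evaluated at one test
  instance's attribute values, yielding a structure per instance.
* **KDB_O**: KDB_P after redundant dependency elimination (below).
* **AKDB / PKDB**: uniform posterior averages (KDB + KDB_P) / (KDB + KDB_O).
  Uniform weights are deliberate: neither member has a principled prior
  claim to more weight.

## Information measures

Six measures are computed from raw (unsmoothed) co-occurrence frequencies:
MI and CMI; their per-value summands LMI and CLMI (so Σ LMI = MI and
Σ CLMI = CMI, identities enforced by tests); and the class-free pointwise
measures PMI I(xᵢ; xⱼ) = log P(xᵢ,xⱼ)/(P(xᵢ)P(xⱼ)) and PCMI
I(xᵢ; xₖ | xⱼ).

Sign conventions deserve care. MI and CMI are mutual informations and LMI
is P(x)·KL(P(Y|x) ‖ P(Y)); all three are non-negative and tested as such.
CLMI and the pointwise measures are *signed*: CLMI is a single summand of
a per-class mutual information and can be negative (with a single class,
CLMI(a, d) on the packaged example table is (1/6)·log(3/4) < 0). No
non-negativity is asserted for them; structure learning only uses their
ranking.

Zero conventions: summed measures let zero-probability terms contribute 0.
A pointwise measure on a zero joint count is undefined; it returns 0 with
a `defined=False` flag, which the redundancy filter reads as "no evidence"
and skips. A zero *conditioning* count in PCMI is an error.

The log base (default 2, bits) cancels in every ordering, argmax and in
the redundancy ratio; base-e output is available and all measures rescale
by ln 2 exactly (tested).

## Redundant dependency elimination

RDE is defined for k = 2. The pointwise chain rule
I(xᵢ; xⱼ, xₖ) = I(xᵢ; xⱼ) + I(xᵢ; xₖ | xⱼ) motivates the criterion: a
second parent is only worth keeping if its conditional term is a
non-trivial fraction of the leading term. For each attribute at rank
≥ k+2 in the lazy order:

1. rank all higher-ranked attribute values by CLMI descending (list L′;
   ties toward the smaller attribute index);
2. always retain L′[1], the strongest parent;
3. scan j = 2, 3, … in L′ order and take the *first* candidate with
   PCMI(xᵢ; L′[j] | L′[1]) ≥ δ · PMI(xᵢ; L′[1]) as the sole second
   parent; if none qualifies the attribute keeps one parent.

Attributes at rank < k+2 are untouched (the rank-(k+1) attribute keeps its
two parents: the redundancy question only arises where there was a
choice among ≥ k+1 candidates). Design choices where the procedure is
underdetermined:

* **Candidate pool**: L′ ranges over *all* higher-ranked attribute values,
  not only the current two parents — substitution may promote a previously
  non-parent attribute, which is the filter's point.
* **First-qualifying wins**: scanning stops at the first candidate that
  passes, implementing "keep the attribute value with the smallest index"
  in L′ order.
* **Degenerate reference**: if PMI(xᵢ; L′[1]) ≤ 0 or is undefined, the
  ratio criterion is meaningless; a candidate then qualifies iff its PCMI
  is strictly positive (preserving the "provides extra information"
  intent).
* **δ = ∞** is an explicit remove-all sentinel that also overrides the
  degenerate-reference rule: no candidate ever qualifies.

These choices make the filter idempotent and arc-monotone (tested
properties), and the δ = 0 edge keeps any candidate with defined PCMI ≥ 0.

δ defaults to 0.5 on a [0, 1] grid in steps of 0.1 when selected;
selection minimises leave-one-out cross-validated zero-one loss of PKDB
on the training set, ties toward the smaller δ. The LOOCV loop decrements
the count tables per held-out instance rather than recounting; a test
verifies exact equality with naive refitting.

## Parameter estimation and inference

Classification-time tables are add-one (Laplace) smoothed:
P(xᵢ | π, y) = (c + 1)/(c_π + arityᵢ) and P(y) = (c_y + 1)/(N + m). A
never-observed parent configuration therefore backs off to uniform
1/arityᵢ, as does any unseen attribute value at test time (consistent
with the policy of coding missing values, `?`, as ordinary categories
rather than imputing). Joints are accumulated in log space and posteriors
normalised by log-sum-exp; log-space and direct products agree to 1e-10
on small domains (tested).

## Data handling

CSV with a header row; every column integer-coded in first-appearance
order for reproducibility without a global dictionary. Quantitative
columns (declared in a YAML schema) are discretised by Fayyad–Irani MDLP
(class-aware, default) or equal-frequency binning (default 3 bins); MDLP
candidate cuts are midpoints between adjacent distinct values, the best
cut maximises information gain (ties to the smallest cut) and recursion
stops when the gain fails the MDL inequality. Fitted cut points are
exportable so train and test share identical bins. Both discretisers are
offered because either is a defensible default for clinical covariates;
MDLP is preferred as the class-aware choice.

Cross-validation folds are stratified: within each class instances are
shuffled by the seeded generator and dealt round-robin with a counter
carried across classes, so fold sizes differ by at most one overall and
within every class.

## Evaluation stack

Zero-one loss; rank-based AUC (midranks, exactly equivalent to pair
counting with ties worth ½ — cross-checked against both a brute-force
oracle and scikit-learn); the Friedman rank test (rank 1 = lowest loss,
average ranks on ties, χ² critical value with t−1 degrees of freedom from
scipy; cross-checked against `scipy.stats.friedmanchisquare` on tie-free
matrices).

Bias/variance uses the Kohavi–Wolpert decomposition of zero-one loss
under a deterministic-target assumption (class noise is unobservable from
a single dataset): 10 repetitions of seeded random 50/50 train/test
splits by default; each instance's predicted-label distribution p̂(·|x)
is accumulated over the repetitions in which it was a test point, and

    bias(x) = ½ Σ_y′ (p̂(y′|x) − 1{y′=y_x})²,
    variance(x) = ½ (1 − Σ_y′ p̂(y′|x)²).

Their sum equals the expected zero-one loss at x, a consistency the tests
verify to 0.05 by direct Monte-Carlo measurement.

## Synthetic generator

`random_bayes_net` emulates discrete clinical data: the class is the root,
attributes follow in a fixed topological order, the attribute at rank r
receives exactly min(r−1, k) parents sampled uniformly among higher-ranked
attributes, and every conditional distribution (class prior included) is a
symmetric Dirichlet draw. Defaults: arities uniform on {2, 3}, two
classes, concentration 1.0 (uniform over the simplex — a mix of strong and
weak dependencies; lower values give near-deterministic ones). Sampling is
ancestral and deterministic per seed.

What the generator does *not* emulate: real-data marginals (e.g. the
heavily skewed '?' rates of screening data), attribute-dependent
missingness, label noise, or continuous measurements beyond what
discretisation produces. Passing tests on this generator therefore
demonstrate correctness of the algorithms and calibrated behaviour under
a known dependence structure, not clinical performance.

## Problem sizes in the shipped experiments

The packaged experiments use n = 6 attributes with N = 5000 samples ×
20 seeds for structure recovery, 2000/1000 train/test rows for the
independence-data comparison and 500/500 for the 2-dependent comparison —
small enough to run routinely while keeping the Monte-Carlo error of the
compared losses near ±0.01.

## Known limitations

* **Exact structure recovery is not guaranteed.** KDB's mutual-information
  ordering need not match a generating network's topological order, and
  when it does not, some true parent sets are unreachable by construction;
  even under a compatible ordering the greedy pairwise-CMI choice can
  prefer a grandparent over a true parent, since it deliberately drops the
  joint conditioning of the exact chain-rule expansion. On
  generator-sampled data the learner recovers roughly 40% of parent sets
  exactly at N = 5000 (the corresponding distributional fit is what the
  loss experiments measure). KDB-family learners should be read as
  classifier-structure heuristics, not causal-discovery methods.
* RDE is restricted to k = 2; other k values raise an error.
* AUC is binary-only; multi-class datasets report loss (and bias/variance)
  but no AUC.
* Continuous attributes are supported only through discretisation; there
  is no density-based redundancy filtering.
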