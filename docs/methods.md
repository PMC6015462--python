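# Methods

## The generative model behind the synthetic cohorts

Every test and the acceptance script run against a planted linear-Gaussian
model. Per sample `s`, each TF `t` carries a latent activity
`a_{t,s} ~ N(0, 1)`. Observed expression is

- TF genes: `x_{t,s} = a_{t,s} + σ ε`,
- targets: `y_{g,s} = Σ_{t → g} β · mode(t, g) · a_{t,s} + σ ε`,
- unregulated genes: `σ ε`,

with `ε ~ N(0, 1)` i.i.d., `mode ∈ {+1, −1}` (positive with probability
0.7 by default) and a single effect size `β` stored per edge. Disease
cohorts are identical except that selected TFs have their activity
shifted by `+δ` (activated) or `−δ` (repressed). Closed-form
consequences used as oracles: a target regulated by `k` TFs has variance
`kβ² + σ²`; the expected case-minus-control logFC of a target of a
perturbed TF is `±δ·β·mode`, so a repressed TF's positive-mode targets
fall and its negative-mode targets rise.

TF expression is deliberately a *noisy readout of activity* rather than
the activity itself: coexpression network inference implicitly assumes
the TF transcript tracks its regulatory activity, and the simulation
makes that assumption explicit and tunable through `σ`.

Default study conditions (the "reference scenario"): 10 TFs among 500
genes, 30 targets per TF, `β = 1`, `σ = 0.25`, a 200-sample reference
cohort, four case-control studies of 50 vs 50 samples with two activated
and two repressed TFs at `δ = 2`, and a drug database of 3 therapeutic,
3 mimetic and 44 neutral compounds with 5 instances each. These sizes
make every downstream contrast decisively detectable while keeping a
full end-to-end run in the tens of seconds on one core.

The drug generator scores genes as `∓signal + noise·ε` (therapeutic
reverses the disease signature, mimetic reproduces it), where `signal`
is a linear ramp down the tag list, and ranks descending; neutral drugs
are uniform random permutations. Rank noise defaults to 0.25, enough to
decorrelate instances of the same compound without masking the planted
direction.

What the generator does **not** emulate: microarray batch effects, probe
saturation, heavy-tailed noise, correlated TF activities,
autoregulation, or combinatorial (non-additive) regulation. Passing
tests therefore demonstrate that the chain recovers structure *under its
own modelling assumptions*, not that it would perform identically on any
particular public dataset.

## Mutual information and the network chain

MI is estimated on an equal-frequency (rank-based) joint histogram:
each profile is ranked (stable tie-break by sample position), cut into
`b` equal-occupancy bins, and `MI = Σ p_ij ln(p_ij / (p_i q_j))` in nats.
This estimator is symmetric and invariant under strictly monotone
transforms of either profile.

**Bin count.** The default is `b = ⌊n^{1/3}⌋` (5 bins at n = 200). Under
independence the histogram MI has positive bias ≈ `(b−1)²/(2n)` nats; at
`b = ⌊√n⌋` that bias (~0.42 nats at n = 200) is the same order as the MI
of genuinely but moderately dependent pairs — e.g. a target shared by
two TFs, whose per-TF correlation is diluted by `1/√2` — and recovery of
multi-regulated targets collapses. The cube-root rule keeps the bias an
order of magnitude below the signal while leaving enough resolution to
detect monotone dependence. `estimate_mi` accepts any `b ≥ 2` for
callers who want the classical choices.

**Permutation threshold.** The null pools `n_perm` draws of (random TF,
random other gene, permuted sample order); the threshold is the
empirical `1 − p` quantile (`method="higher"`), defaults `n_perm = 1000`,
`p = 0.001`. The cutoff is applied to the pooled-null quantile directly,
without a further multiplicity adjustment.

**Bootstrap consensus.** Samples are resampled with replacement
`n_boot = 100` times and edges kept when present in ≥ 95% of replicates.
A subtlety dominates here: a bootstrap replicate repeats samples, and a
repeated observation lands in the same joint-histogram cell for *every*
gene pair, inflating MI across the board (measured at n = 200: the null
mean rises from ~0.48 to ~0.76 nats with √n bins). Reusing the full-data
threshold therefore floods the consensus with false edges. The
per-replicate cutoff is instead recalibrated against a resampling-aware
null: permute one profile first (destroying any real dependence), then
apply a shared bootstrap index to both (preserving the duplicate-pairing
structure). Bootstrapping is treated as a pruning step: its survivors
are intersected with the full-data raw network, so the stage chain is
monotone (raw ⊇ bootstrap ⊇ DPI).

**DPI.** For each closed triplet (TF_i, TF_j, target k), edge (i, k) is
removed when `mi(i,k) < (1 − tol)·min(mi(i,j), mi(j,k))` with `tol = 0`;
ties keep the edge, only TF–target edges are removable, and all
decisions are evaluated against the pre-DPI set, so the output is
order-independent. TF–TF edges participate in triplets but are excluded
from the final regulons.

**Modes and size tiers.** Each surviving edge's mode is the sign of the
TF–target Pearson correlation in the reference cohort (an exact zero —
a measure-zero event — is logged and assigned +1 to stay deterministic).
Regulon size filters are configurable with two conventional tiers: a
reporting tier (size > 25) and an analysis tier (size ≥ 100) for MRA on
genome-scale data. The synthetic scenario plants 30-target regulons, so
its configs use an analysis tier of 10; the genome-scale defaults are
unchanged.

## Differential expression

Two-group moderated t with `d = n − 2` pooled degrees of freedom. The
prior `(d₀, s₀²)` is fitted by method of moments on `log s²_g` via
trigamma inversion; a non-positive excess variance falls back to
`d₀ = ∞` (fully pooled variance, logged). `d0_override = 0` reproduces
the ordinary pooled-variance t exactly, and the implementation is
cross-checked against limma in the test suite. logFC is the difference
of group means on the assumed-log-scale input. Genes flat in both groups
carry no evidence and are forced to `p = 1`. BH adjustment is the exact
step-up, validated against statsmodels and a hand computation.

## Master regulator analysis

Per study, the universe is the intersection of the network's gene space
(the reference cohort's genes) with the study's measured genes — the
most conservative common choice. Each regulon (both modes pooled;
mode-specific direction is the next stage's job) is tested with the
upper-tail hypergeometric `P(X ≥ k)`, BH-adjusted across TFs within the
study; candidates need significance in ≥ 3 studies.

## Two-tail GSEA

Ranked phenotype: genes sorted by descending logFC, ties broken
lexicographically so results are fully deterministic. The enrichment
score is the classic weighted KS running sum (hits weighted by
`|logFC|^exponent`, exponent 1 by default, 0 available); `Es⁺` and `Es⁻`
are computed independently for the two mode subsets (an empty subset
contributes 0) and `dES = Es⁺ − Es⁻`. Significance uses a gene-label
permutation null — disjoint random subsets of the two sizes — because
only summary logFC values enter this stage; `p = (1 + #{|dES_null| ≥
|dES_obs|}) / (1 + n_perm)`, `n_perm = 1000`. States: BH ≤ 0.05 and
`dES > 0` → activated, `dES < 0` → repressed, otherwise ns. Three
significance thresholds are deliberately kept separate and configurable:
the computation cutoff (0.05), the state-call FDR (0.05), and the
stricter raw-p filter (0.01) feeding the connectivity query.

## Connectivity map

The query signature unions the regulon targets of candidates with
two-tail p ≤ 0.01 for the study, keeps those differentially expressed
(BH < 0.05), splits by logFC sign and orders by |logFC| (capped at 1000
tags per direction, the classic web-tool input limit; both activation
states are pooled, with a per-state option). Instance scoring is the KS
tag statistic `a if a > b else −b` with
`a = max_j[j/t − V(j)/n]`, `b = max_j[V(j)/n − (j−1)/t]`; the raw
instance score is `ks_up − ks_down`, zeroed when both share a sign.
Scores are scaled per study (positives by the max positive, negatives by
|min negative|).

Per-compound significance resamples instance subsets of the same size
from all of the study's instances (`n_perm = 10000` by default). Each
compound gets its own independent null draws: sharing one null set
across compounds correlates the 200-odd p-values and makes any
uniformity diagnostic unstable. The `≥` tie convention keeps the test
exact but conservative; compounds whose every instance scores an exact 0
(the same-sign rule) form an atom near p = 1, so calibration checks read
uniformity off the continuous, nonzero-score part. Consensus requires
the same direction at p ≤ 0.05 in ≥ 2 studies; compounds significant in
opposite directions anywhere are excluded and logged. A study whose
candidates yield no query signature is skipped with a warning rather
than aborting the cross-study run.

## Reporting

The MR subnetwork connects state-significant candidates with edges
weighted by the Jaccard coefficient of their target sets; the default
edge rule is any nonzero overlap (a threshold flag exists, since
reasonable cutoffs are application-specific). Degree mean ± sd uses the
population sd.

## Determinism and numerics

All randomness flows through `numpy.random.default_rng`; one global seed
derives independent per-stage streams via `SeedSequence.spawn`, so
stages are decoupled and a rerun with the same config reproduces every
artifact byte for byte (content-hashed manifests verify this). Output
floats are written with `%.10g`. Empirical quantiles use
`method="higher"`, making degenerate nulls behave exactly (all-equal
null → that value).

## Problem sizes in the test suite

The suite and the acceptance script use the reference scenario above for
recovery checks; calibration experiments use 2000-gene null designs
(moderated t), a 300-gene / 150-sample β = 0 cohort with 4000
permutations (threshold retention), and 200 neutral compounds × 5
instances (p-value uniformity); the byte-identity check reruns a
reduced scenario (80 genes, 3 studies) twice. A full suite run completes
in well under a minute on one core.

## Known limitations

- The MI estimator is histogram-based by design; kernel or k-NN
  estimators would be more sample-efficient at small n but lose the
  exact combinatorial oracle used for testing.
- The moderated t supports the two-group contrast only — no covariates,
  array weights or duplicate correlation.
- Mode assignment is a hard sign; near-zero correlations get a mode with
  no confidence measure attached.
- Consensus rules (≥ 3 studies for MRs, ≥ 2 for drugs) are counts, not
  meta-analytic combinations of evidence.
- The synthetic drug database plants one global disease signature;
  cell-line-specific responses are not modelled.
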