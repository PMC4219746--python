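# Methods

This note documents the models, estimators and design choices behind
`grnbench`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Evidence integration

**Canonical sign.**  An observation is the response of a target to a
perturbation of a regulator.  With s(gain) = +1, s(loss) = −1, s(up) = +1,
s(down) = −1 and "no change" forcing 0, the canonical sign is
s(perturbation) · s(effect): a knockout that lowers its target (+1)
supports activation, an over-expression that lowers it (−1) supports
inhibition.

**Conflict filter.**  A pair whose evidence multiset contains both +1 and
−1 — in any tissue or developmental stage — is removed before model
fitting.  Sign 0 is neutral and never constitutes opposition.  Context is
carried on every observation and a per-context mode table is available
(`context_mode_table`) for tissue-specificity reporting, but the pooled
model deliberately ignores it: tissue-specific disagreement is a finding,
not noise to be averaged.

**Likelihood model.**  The conditional matrix P(obs | M) has columns

|        | activating | none      | inhibiting |
|--------|-----------|-----------|------------|
| obs +1 | α         | (1−α)/2   | 1−α−β      |
| obs 0  | β         | α         | β          |
| obs −1 | 1−α−β     | (1−α)/2   | α          |

α is the probability of a correct observation, β the probability of a
missed effect (detection insensitivity).  Only these two parameters are
scientifically meaningful; the remaining mass is the simplest
column-stochastic completion (wrong-sign mass 1−α−β under a causal mode, a
symmetric split of the spurious-change mass under mode none).  Defaults
α = 0.9, β = 0.05; both configurable.  Feasibility requires α > β ≥ 0 and
α + β ≤ 1.  The suite verifies that mode calls on decisive multisets are
stable over α ∈ [0.8, 0.95], β ∈ [0.02, 0.1] (feasible corners); multisets
on the tie manifold β = (1−α)/2, such as {+1, 0}, genuinely flip there and
are reported as ties at the boundary.

**Numerics.**  Log-likelihoods are accumulated from sign *counts*, which
makes them exactly invariant to observation order; zero-count terms are
skipped (0 · (−∞) is NaN in IEEE arithmetic) and zero-probability factors
propagate −∞.  Ties (detected with relative tolerance 1e−9; genuine ties
are float-exact symmetric swaps) resolve to mode "none" with status
``tie`` — the model never asserts causality on ambiguous evidence.  Every
record counts once regardless of technique or molecule; the model has no
per-technique weights.

## Expression analysis

Matrices are consumed on log2 scale as given; no re-normalization.  The
low-signal filter removes probes by mean intensity; because absolute
thresholds are platform-specific, the default is the matrix-wide 20th
percentile of probe means (configurable).  Network inference operates on
the union of the top-5000 most variable probes and all probes annotated to
literature genes; variance ties at the k-boundary are all retained
(deterministic superset rather than an arbitrary exact-k cut).

Differential expression is a per-probe Welch two-sample t-test with
Benjamini–Hochberg adjustment (statsmodels) across the contrast's probes —
a deliberately plain stand-in for moderated-t pipelines, adequate because
everything downstream depends on fold-change magnitude and FDR *ranking*
rather than on shrinkage details.  An optional variance floor (pool toward
the median within-group variance) is available for very small n.  Default
FDR 0.05.

Fold changes from loss-of-function contrasts are sign-flipped so +1 always
means "supports activation", the same convention as evidence
canonicalization.  When several probes map to one gene the probe with the
largest |log2FC| represents the pair (the permissive choice, logged); the
same max-|score| rule collapses probe-level networks to gene level.  The
fold-change classifier calls a pair at cutoff τ (observed sign =
sign(log2FC) if |log2FC| ≥ τ else 0); sweeping τ over [0, 3] produces the
consistency curve, whose TP rate counts only sign-concordant causal pairs
while the FP rate counts any no-effect pair that fires.  An empty negative
set yields a missing FP rate, never a fabricated 0.

## Network inference

*Correlation*: Pearson/Spearman on row-standardized profiles; constant
probes are excluded (never scored 0); representative threshold 0.5 on
|r|.  *Mutual information*: equal-frequency binning with ⌈√n⌉ bins by
default (pandas `qcut`; a constant profile is a degenerate-binning error),
plug-in estimator in nats with optional Miller–Madow correction.  The
plug-in null bias is approximately (k₁−1)(k₂−1)/(2n) nats and is common to
all pairs, so rankings and DPI comparisons are unaffected; the suite
checks the bias against this closed form.  *DPI pruning*: in every
triangle the strictly weakest edge is marked and all marked edges removed
simultaneously; tied minima are left untouched (with tolerance eps = 0 a
non-strict rule would annihilate tied cliques).  *Tree importance*: one
random-forest regression per target on variance-standardized profiles
(scikit-learn, `max_features="sqrt"`, full-depth trees), importance =
normalized total variance reduction, directed regulator → target; a seed
is mandatory and results are bitwise reproducible.  The candidate-regulator
set defaults to all probes in the end-to-end workflow: restricting
candidates to literature regulators makes every edge emanate from an
evaluated-pair source, which inflates path-matching rates relative to a
node-label permutation null for purely structural reasons.  Edge-count
standardization retrieves the top-N importance edges where N is the size
of the unrestricted DPI-pruned network (boundary ties all retained).

## Evaluation

Path-tolerant matching counts a literature pair (u, v) as recovered at
path length k when a directed (tree networks) or undirected (correlation,
MI, DPI) path of ≤ k edges connects u to v; for undirected candidates a
match in either orientation counts, because literature pairs are directed
claims while co-expression carries no direction.  Pairs with a gene absent
from the candidate's node universe are excluded from numerator and
denominator, with counts reported.  Distances come from BFS (SciPy
csgraph) memoized per source.

The permutation null shuffles node labels uniformly over the candidate's
full node universe, preserving topology exactly.  Because a pair (a, b) is
matched in the relabeled network exactly when the pre-images of a and b
are connected in the original, the all-pairs distance matrix is computed
once and each permutation reduces to index lookups; 1000 permutations are
effectively free and bitwise reproducible from one master seed.  The
summary reports per-k null mean/sd, z-scores (z = 0 when a degenerate null
coincides with the observation, ±∞ otherwise) and empirical quantiles, so
both mean-based and envelope-based readings are available.

AUROC is computed by threshold sweep with trapezoidal area (scikit-learn),
which equals Mann–Whitney concordance with half-weight ties; the suite
verifies the equality to 1e−12 and the invariance under monotone score
transforms.  External-network overlap restricts the universe to genes
present in both resources and reports the restriction; an entirely empty
external edge set recovers nothing over the full pair set, whereas a
non-empty set sharing no genes with the literature is an error.

## Synthetic data generator

The generator's defaults define the benchmark's study conditions; they are
chosen to emulate the scale and statistical structure of curated
embryonic-organ studies and are not tuned per analysis.

**Ground-truth GRN.**  Curated developmental GRNs are shallow: a minority
of genes are regulators, most curated genes are pure targets.  Edges are
sampled with sources in a regulator subset (35% of genes) and land on
another regulator with probability 0.05; this keeps directed reachability
subcritical, so path-free (regulator, gene) pairs — the verified no-effect
negatives — exist at the curated composition.  Signs are negative at rate
`frac_inhibiting` (tooth-scale preset 0.26, heart-scale 0.18, matching the
activating-dominated composition of curated sets); weight magnitudes are
uniform in [0.15, 0.4]; |W| is rescaled to spectral radius ≤ 0.9 if
needed.  Every edge carries a per-tissue activity mask (active in each
tissue with probability 0.5, at least one tissue).  No-effect pairs are
verified path-free in the *union* network at generation time by transitive
closure.

**Expression.**  Steady states of a linear Gaussian SEM in deviations from
baseline: x = b0 + d, d = (I − Wₜᵀ)⁻¹(drive + ε), where Wₜ is the
tissue-masked weight matrix, so regulators transmit their deviation from
typical level — the natural reading on a log scale (propagating absolute
levels instead pins targets against any saturation bound, which is why the
deviation form is used).  The exogenous drive is L·φ(t) + tissue offset,
with φ smooth sinusoidal latent developmental programs of pseudotime and
loadings L ~ N(0, 0.7²): shared programs with independent loadings create
exactly the co-expression-without-causation background that confounds
correlation methods.  Biological noise ε ~ N(0, 0.35²) propagates through
the network; measurement noise N(0, 0.15²) does not.  An optional
saturating transfer clips each gene's deviation to ±1.5 (solved by damped
fixed-point iteration; clipping is non-expansive, so the spectral condition
makes it a contraction).  150 background genes respond to the latent
programs only.  Perturbations are clamp-and-resolve: the perturbed gene's
deviation is fixed at −2.5 (loss) or +2.5 (gain) and the steady state
recomputed, so downstream genes shift with the product of edge signs along
active paths, while matched controls share the same drive.

Under the linear two-gene chain u → v with weight w and equal i.i.d.
noise, corr(u, v) = w/√(1 + w²); the suite checks the simulator against
this closed form and checks that saturation attenuates it.  With the
preset confounders on (latent programs, tissue masks, saturation), the
observational correlation between true pairs is swamped while
clamp-and-resolve perturbations remain well above noise — the generator's
designed regime, in which fold change discriminates causal from no-effect
pairs and thresholded co-expression networks sit inside their permutation
nulls.

**Evidence.**  For each pair with true mode M, 1–3 observations (uniform)
are drawn from P(obs | M) — the same matrix the likelihood model inverts —
and de-canonicalized into (perturbation, effect) records with context
labels from the pair's active tissues.  Conflicts and mode-"none" ties
therefore arise at their analytic rates, which the suite checks in closed
form.

**Presets.**  `tooth_like`: 100 network genes, ~445 signed edges, 460
no-effect pairs, two tissues, 94 arrays (8-stage × 2-tissue × 3-replicate
time series; 10 highest-out-degree regulators perturbed in both tissues
with 2 replicates; 3 matched controls per tissue), ~1800 evidence records.
`heart_like`: 60 genes, ~200 edges (18% inhibiting), 80 no-effect pairs,
one tissue, ~70 arrays.  These scales keep the full pipeline — including
1000-permutation nulls and tree ensembles — around a minute on one core;
tree ensembles default to 100 trees per target in the workflow (rankings
are stable well below the customary 1000, which remains the API default
for standalone use).

## Sample metadata conventions

Sample metadata carries `condition_class` ∈ {time_series,
genetic_perturbation, signalling_stimulation, phenotype_difference,
control}, tissue, stage, `perturbed_entity` (non-empty exactly for
perturbation/stimulation samples), `replicate_group`, and optionally
`perturbation_direction` (gain/loss), which drives the sign orientation of
fold-change calls.  Perturbation contrasts pair each perturbation
replicate group with control samples matched on tissue and stage.
Controlled vocabulary is case-folded on input; gene symbols never are.

## What passing tests do and do not show

The generator reproduces the *mechanisms* that decouple causation from
co-expression (shared programs, context-specific regulation, saturation)
but not everything about real compendia: probe-level artifacts,
batch/platform effects, non-steady-state dynamics, unmeasured regulators,
and curation biases in which pairs get tested are all absent, and the
no-effect negatives are clean by construction while real "no effect" calls
are censored observations.  Passing the benchmark therefore demonstrates
that the pipeline's statistics behave as designed under those mechanisms —
not that any particular real dataset will show the same effect sizes.

## Known limitations

- The evidence model treats observations as exchangeable and independent
  given the mode; repeated reports from one laboratory or one technique are
  not down-weighted.
- The DE stand-in (Welch t) is anti-conservative for n = 2 vs 3 replicate
  contrasts relative to moderated-t approaches; the variance-floor option
  mitigates but does not replace shrinkage.
- Path-tolerant matching treats all paths equally; it does not require sign
  consistency along the path.
- The SIF reader supports the common three-token dialect only (one
  interaction per line).
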