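# Methods

This note documents the models, estimators and numerical choices behind
`coregrn`, the assumptions they rest on, and what the synthetic-data tests do
and do not establish.

## 1. Context-specific TF-target database

Per TF, open-chromatin targets with binding probability strictly above the
threshold are kept in full when fewer than `n_tsh` (default 50) qualify;
beyond that only the top `n_tsh + (n_genes − n_tsh)·top_fraction`
(default 0.01) by descending probability. The count is rounded half away from
zero (no rounding rule is standard here; half-away is unbiased for the
boundary case), and probability ties at the selection boundary break by
lexicographic gene id so the selection is deterministic. The ATAC-derived and
curated databases are merged by per-TF set union, retaining both provenances
per target (curated wins for display). TFs with fewer than eight targets are
dropped; the count is taken *after* restricting targets to genes present in
the expression matrix, since only those targets can inform activity.

## 2. TF activity

The activity of a TF in a sample is the mean over its targets of the target's
z-scored expression, each target weighted ±1 by the sign of its Spearman
correlation with the TF's own expression row. The rationale: coordinated
movement of a regulon tracks the regulator's latent activity even when the
regulator's transcript does not change. When the TF is absent from the
matrix, the leading principal direction of its target block anchors the
orientation, with an overall flip so the activity agrees with the majority of
targets. The estimator sits behind a single function so alternative activity
models can replace it without touching the rest of the pipeline. Activities
are computed jointly on all samples (the two groups share one standardization).

Constant target rows z-score to zero; a TF whose targets are all constant
therefore has constant-zero activity, and its rank correlations are recorded
as 0 with a warning rather than NaN.

Differential expression is a deliberately simple stand-in — Welch's t with
Benjamini–Hochberg adjustment at adjusted p < 0.05 — because the microarray
moderated-variance machinery is upstream of this package's scope. Measured
consequence (30-replicate oracle): at a 2-SD planted shift with ~10 samples
per group the expected recall is 0.85 ± 0.03, not higher; users wanting
moderated tests can supply a precomputed DEG table.

## 3. Candidate networks

Edge rule: A→B exists iff B is in A's merged target set, both are selected
TFs, and |ρ(activity_A, activity_B)| strictly exceeds the cutoff; sign(ρ)
gives activation/inhibition. Self-loops are excluded by default: a row's rank
correlation with itself is 1, which would force every self-edge to be an
activation regardless of the underlying regulation. Weak connectivity
(directions ignored) defines components; the largest is kept when it holds
strictly more than 80% of the connected TFs, and candidates with fewer than
15 TFs are discarded. Candidate edge sets are non-increasing in the cutoff,
and identical topologies reached from different hyperparameter triples are
simulated once with back-references.

## 4. Ensemble ODE simulation

Dynamics use shifted-Hill regulation with the production rate normalized by
the product of incoming excitatory fold changes, so `G` is the true maximum
production rate. Sampling ranges (uniform): G ∈ (1, 100), k ∈ (0.1, 1),
integer Hill coefficients 1–6, excitatory fold change (1, 100), inhibitory
fold change the reciprocal of a (1, 100) draw, threshold
(0.02·M, 1.98·M).

**Half-functional rule.** M is the Monte-Carlo median of G/k over the
sampling ranges — the *unregulated* median reading. The refinement that
accounts for regulator modulation of the median is not implemented; for the
default ranges the unregulated median (~52.9) is the conventional anchor and
makes each link functional in roughly half the models.

**Integrator.** Fixed-step Euler with dt = 0.02 for t_max = 100 time units;
convergence when max over genes of |dY/dt| / max(Y, 1e−9) < 1e−3, checked
every 25 steps with converged models frozen; one retry from a fresh random
initial condition, then the model is flagged non-converged and excluded
downstream (typical non-convergence < 1%). Initial conditions are log-uniform
between (G/k)·Πλ⁻/Πλ⁺ and G/k per gene. A compiled (numba) per-model kernel
and a vectorized numpy integrator implement identical arithmetic; an adaptive
RK45 path exists for single-model cross-checks. Reported steady states are
re-verified post hoc by direct evaluation of the right-hand side,
independently of the integrator. dt = 0.02 is stable for the sampled
degradation range (k·dt ≤ 0.02); these integrator constants are declared
defaults of this package, not facts of the underlying model.

**Normalization contract.** Simulated steady states are log2-transformed then
z-scored per gene across converged models; experimental activities are
z-scored per TF across samples. All distance comparisons and the ridge mapper
operate in this shared standardized space; knockdown ensembles reuse the
*unperturbed* log2 mean/sd so perturbed and unperturbed profiles remain
comparable.

**Knockdowns** multiply the perturbed gene's G by (1 − kd_factor), default
0.95, keep every other parameter and the original initial condition, and
re-integrate — preserving the 1:1 model pairing (kd_factor = 0 reproduces the
unperturbed ensemble bitwise).

## 5. State assignment, accuracy, flexibility, ranking

Per model and state, the statistic is the Euclidean distance to the nearest
same-state sample profile. The null shuffles the model's own gene labels
(`n_null` = 1000 permutations, drawn once per model and shared across the two
states); p is the fraction of null distances ≤ observed, with no +1
smoothing. The model joins the argmin-p state when that p ≤ α = 0.05, else it
is unassigned; a p tie breaks by the smaller observed distance, then control.
Proportions are over all (converged) models, so control + case + unassigned
= 1 and accuracy = 1 − unassigned exactly.

Flexibility averages √(Δm_control² + Δm_case²) over all single-TF knockdowns
of the network, each knockdown's proportions obtained by the same
distance/null assignment (the ridge mapper is reserved for the perturbation
screen). Range: 0 to √2.

Ranking: rank 1 = highest accuracy and, independently, highest flexibility;
the combined index is the sum, smallest first. Ties break by higher accuracy,
then fewer edges, then candidate id — a stated convention, since ties are
otherwise order-dependent. The stability check re-scores the top candidates
over repeated ensembles and compares combined indices by a two-sided t-test;
note that with very few candidates the combined index is nearly discrete, so
stability verdicts are most meaningful with ~10 candidates and ~10 repeats.

## 6. Perturbation screen

A ridge regression (penalty 1.0 on standardized profiles — the penalty is a
declared default) maps expression to the class indicator with threshold 0.5,
trained only on assigned unperturbed models; all knockdown models are then
classified (no unassigned class), matching a two-way proportion readout.
Significance uses Pearson's chi-squared without continuity correction on the
2×2 (condition × state) count table — the correction is immaterial at
ensemble-scale counts — with zero-margin tables reported as p = 1 with a
warning. Destabilizers are ordered by control-state proportion, descending;
pairs are all unordered pairs among the union of the top-5 and bottom-5
single knockdowns. PCA projections fit loadings and centering on the
unperturbed matrix only. Training-accuracy caveat: with permuted labels the
ridge mapper's training accuracy sits at 0.5 + O(√(genes/models)), so
chance-level checks require models ≫ genes.

## 7. Pathway annotation

Each TF's regulon ({TF} ∪ targets) restricted to the DEGs is tested per
pathway by a one-sided (enrichment) Fisher's exact test over a 2×2 table on a
common universe; the TF takes the smallest-p pathway when p ≤ 0.1, else stays
unannotated. The universe defaults to the union of all regulon and pathway
genes under test (the background is otherwise unspecified; it is configurable
and logged). p ties break alphabetically, making annotation independent of
pathway input order. No multiple-testing correction is applied across TFs —
the p ≤ 0.1 rule is a labelling heuristic, not an inference.

## 8. Synthetic world

The generator plants a bistable core of two TF modules (default 10 + 10):
each gene is inhibited by two genes of the opposite module and activated by
its intra-module ring predecessor. Inhibition dominance is essential —
constitutively-on genes silenced by the rival module give a random-parameter
ensemble two well-populated antagonistic states, whereas purely
activation-driven modules almost never self-ignite when each link is
functional in only ~half the models (measured: within-module expression
correlation ~0.02 for activation rings vs ~0.24 for this motif).

Around the core: 10 dedicated targets per TF; expression with
effect_size = 2 noise-SDs of centroid separation and noise sd 0.5 on log2
scale over 11 control + 9 case samples (a typical small two-group microarray
design); a curated database with 10% per-entry dropout and 1% spurious
entries; a binding table with planted pairs ~U(0.5, 1) and 30 random
background pairs per TF ~U(0, 0.3); five decoy TFs with background-only
binding; three ranked lists with planted TFs on top and small rank jitter.

What the generator does *not* emulate: probe/batch effects, correlated noise,
indirect regulation, TF cooperativity, and realistic database incompleteness
structure. A green end-to-end test therefore establishes that the pipeline
recovers a planted core under honest noise, dropout and decoys — not that it
would do so on real microarray/ATAC data.

Known interaction of metrics with scale: the accuracy and flexibility metrics
both favour smaller networks, so a grid whose TF counts sit below the planted
core size selects a subnetwork and caps edge recall. The end-to-end
configuration therefore brackets the core size in its TF-count grid (a k
value ≥ n_tfs is also the only way the ranked-list union can cover the
planted core, and k below the 15-TF rule can yield no candidate at all).

## 9. Reproducibility

All randomness flows from explicit integer seeds through `numpy` generators.
Each candidate topology's simulation seed derives from (master seed, topology
id) via `SeedSequence`, so scores are identical regardless of evaluation
order or parallelization; reruns with the same config and seed produce
bit-identical manifests, and every run carries a provenance block (config
hash, seeds, grid versions).

## 10. Limitations

- Only two experimental states; no intermediate-state assignment.
- Steady states only (no stochastic dynamics, signals, or time courses).
- One initial condition per model samples the state landscape; exhaustive
  stable-state enumeration per model is available but not used by the
  pipeline.
- The activity estimator is a documented variant, not a re-implementation of
  any published activity-inference package.
- Upstream read processing, motif scanning and the external TF-ranking
  methods are out of scope; their outputs are inputs here.
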