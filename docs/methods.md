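# Methods

## Model and assumptions

The method treats a prior pathway signature — a map from gene identifiers
to a sign of regulation upon pathway activation, σ_i ∈ {+1, −1} — as a
hypothesis about the correlation structure of expression data in a new
cohort. If the pathway shows differential activity across the samples and
the prior is relevant there, genes regulated in the same direction should
correlate positively and genes regulated in opposite directions negatively.
Three assumptions are load-bearing: expression is on a roughly continuous
(log) scale so that Pearson correlation is meaningful; samples are
exchangeable (no hidden batch or family structure, which would inflate
correlations); and the cohort is large enough for the Fisher-transform
normal null (we require n_S ≥ 4 and in practice n_S in the dozens to
hundreds).

### Edge significance

For each gene pair, y_ij = arctanh(c_ij) is compared to N(0, 1/√(n_S−3)),
giving a two-sided p-value. Pairs with p ≤ `p_threshold` become network
edges. The default threshold is 1e-4; at that level a pure-noise matrix of
100 genes × 100 samples yields about 0.5 false edges in expectation (the
acceptance script measures this). Because gene-pair tests are not
independent, the false-positive burden is estimated empirically
(`estimate_edge_fdr`): each Monte Carlo run permutes every gene's profile
independently across samples — destroying all gene–gene correlation while
preserving marginals — and counts surviving edges. `select_p_threshold`
walks a candidate grid from permissive to strict and returns the largest
threshold whose average count meets a target. Thresholding on the p-value
is equivalent to thresholding on |y_ij|, so the procedure does not actually
lean on the normality of the null.

Perfectly collinear pairs (|c| = 1, e.g. duplicated probes) would make the
transform infinite; they are retained as edges with p = 0 and a
`collinear` flag rather than crashing network construction. Zero-variance
genes are dropped with a warning before any correlation.

### Consistency and its null

The prior predicts each edge sign as σ_i·σ_j; the consistency score is the
fraction of edges matching. The null redraws each edge's sign as +1 with
probability q = the observed fraction of positive signs among this
network's own edges — the null must share the data's sign imbalance,
otherwise a globally positive correlation structure would look
"consistent" by default. q can be overridden (`prob_positive=`) when a
better estimate exists, e.g. from all signature pairs rather than only
significant ones. The p-value counts null scores strictly greater than the
observed one, over 1000 randomisations by default; the add-one option
(k+1)/(n+1) avoids reporting exactly zero. A note on symmetry: a *global*
flip of all prior signs leaves every predicted product σ_i·σ_j — and hence
the consistency fraction — unchanged, while negating the activity scores;
what complements the fraction (f → 1−f) is inverting the observed
correlation signs.

### Pruning and activity

Pruning removes inconsistent edges only; nodes stay, and genes isolated by
pruning drop out of the largest connected component, which is the denoised
module. Component ties (equal node counts) break by edge count and then by
smallest gene identifier so extraction is deterministic. Activity per
sample is computed on z-scored expression (population SD, denominator n;
configurable to n−1 — the choice only rescales scores) with either the
simple signed average (Eq. over M genes) or the degree-weighted average
normalised by 1/√(Σ k_i²). That normalisation is the unique scaling that
keeps the weighted score unit-variance when gene profiles are independent
unit-variance variables; the test suite verifies the variance empirically
at n = 10⁴ samples. Degrees count all neighbours in the component
regardless of direction of regulation.

When a training and a test cohort are both given, only the network
topology (component membership and degrees) transfers; z-scoring is always
performed within the cohort being scored, since absolute expression scales
are not comparable across cohorts. When the consistency check is not
significant (default cutoff p ≤ 0.05) the scores are still returned but
flagged unreliable; when pruning leaves no component the caller may opt
into a fallback to the unpruned average.

## Synthetic scenarios

The generators produce a 24-gene × 100-sample matrix with 40 inactive
samples and three 20-sample blocks of increasing activity. Three block
indicator patterns (1-based sample index s): pattern 1 on for s > 40,
pattern 2 on for 40 < s ≤ 60 or s > 80, pattern 3 on for s > 80; an "on"
block adds mean μ = 2. A sample's true level is the number of patterns on:
level 0 (40 samples), then 2 / 1 / 3 for the three blocks — so 40/20/20/20
samples at levels 0–3. Genes 1–3 carry patterns 1–3 with SD σ1 = 0.25
(faithful reporters). In SimSet1 genes 4–24 cycle through the same three
patterns with SD σ2 = 3; in SimSet2 genes 4–6 carry the patterns with σ2
and genes 7–24 are i.i.d. N(0, 2) noise. The sources do not state which
pattern each non-faithful gene follows; cycling through the three patterns
is this package's reading and is recorded here. Each gene draws from its
own seeded sub-stream, so a gene's values are stable under changes to the
gene count. Down-regulated genes are not simulated separately: they are
the mirror image of upregulated ones and enter the metrics only through
σ_i.

What the generators deliberately do not emulate: heavy-tailed expression
noise, gene–gene correlation outside the pathway, batch structure,
missingness, or signatures containing genes absent from the matrix. Tests
passing on these scenarios therefore show that the machinery is correct
under the stated model, not that the method is robust to real-data
pathologies.

## Evaluation

Activity profiles are clustered with a 1-D variational-Bayes Gaussian
mixture (scikit-learn `BayesianGaussianMixture`), max 5 components (enough
to cover the 4 true levels), tolerance 1e-4, 500 iterations, 3 restarts
keeping the best bound, seeded. The profile is standardised before fitting
because the estimators differ in scale but not meaning, and clustering of
a 1-D profile should be affine-invariant. On the standardised scale the
component-variance prior is fixed at 1/16 (prior component SD one quarter
of the profile SD): the library default — the data variance — makes the
prior far wider than any plausible component and was verified on a known
four-component mixture to collapse well-separated clusters. Components
with no samples under the maximum-responsibility assignment are dropped;
the occupied component with the lowest mean is the ground state of no
activation. Ground-state accuracy counts inactive samples assigned to the
ground state and active samples assigned anywhere else — no level matching
— and is invariant to component relabelling.

`benchmark_simulation` repeats draw → score (all three estimators, sharing
one network per replicate) → cluster → accuracy, 100 replicates by
default, and compares methods with the two-sided paired Wilcoxon
signed-rank test (p = 1 by convention when all paired differences are
zero). Replicates where pruning leaves no component fall back to the
unpruned average and are counted. With the default scenario parameters the
pruned estimators beat the unpruned average by a wide margin in SimSet2
(where 18 of 24 genes are pure noise) and the degree-weighted metric gives
the best mean accuracy in SimSet1. One structural caveat this package's
experiments make explicit: at the default edge threshold the SimSet2
component is usually just the three faithful genes, where the weighted and
simple averages coincide up to scale, so the two pruned estimators perform
near-identically there.

Inter-pathway correlation hypotheses use the regression slope t-statistic
between two pathways' activity profiles (pathway pairs must be made
mutually exclusive — shared genes dropped from both signatures — before
scoring, or the correlation is an artefact). Pairs with training p < 0.05
are hypotheses; the V score sums |t| over validation cohorts, gated on
p ≤ 0.05 there and signed by agreement with the training direction.
Phenotype association offers a one-tailed two-sample t-test (binary
groups, stated direction) and a permutation test on the regression
t-statistic with the add-one convention (k+1)/(n_perm+1), whose null
calibration is checked by KS test in the suite.

## Numerical choices and limitations

- Correlations are computed in double precision via `numpy.corrcoef`;
  |c| ≥ 1 − 1e−12 is treated as collinear.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give bit-identical outputs (the CLI records seed,
  configuration and version in `run_info.json` per run).
- Problem sizes used in the shipped tests and the acceptance script (100
  replicates per benchmark scenario, 1000 Monte-Carlo FDR runs on a
  100×100 matrix, 200-replicate calibration checks) were chosen as the
  smallest sizes at which the Monte-Carlo error is clearly below the
  effects being measured.
- The method assumes the signature's identifiers match the matrix's
  exactly (whitespace-trimmed string equality); probe-to-gene mapping and
  platform normalisation are out of scope.
- Single-component activity estimation only: when the true pathway splits
  into several consistent modules, all but the largest are ignored.
- The consistency p-value is Monte Carlo, with granularity 1/n_rand; exact
  enumeration is feasible for small networks and is used as a test oracle,
  not as an output path.
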