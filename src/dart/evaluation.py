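"""Evaluation machinery for the activity estimators.

* 1-D variational-Bayes Gaussian mixture clustering of activity profiles,
  with the lowest-mean occupied component taken as the "ground state" of
  no pathway activity, and a ground-state accuracy against known labels.
* Simulation benchmark: repeated draws of a synthetic scenario, all three
  estimators scored per draw, accuracies compared by paired Wilcoxon.
* Inter-pathway correlation consistency: significant pathway-pathway
  activity correlations found in a training cohort are hypotheses; the
  V score sums, over validation cohorts, the absolute t-statistic of each
  hypothesis, signed by directional agreement with the training cohort and
  gated on p <= 0.05 in the validation cohort.
* Phenotype association tests: one-tailed t-test for binary groups and a
  permutation test for regression associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import BayesianGaussianMixture

from .activity import METHODS, ActivityProfile, estimate_activity, run_dart
from .simulate import SimConfig, simulate

__all__ = [
    "ClusteringResult",
    "BenchmarkResult",
    "vb_cluster_1d",
    "ground_state_accuracy",
    "benchmark_simulation",
    "interpathway_correlation",
    "consistency_score_V",
    "compare_methods_V",
    "phenotype_association",
    "paired_wilcoxon",
]

VB_TOL = 1e-4
VB_MAX_ITER = 500
VB_N_INIT = 3
DEFAULT_MAX_COMPONENTS = 5
# Prior expectation for the within-component variance of a standardised
# profile.  The data-variance default would make the Wishart prior much wider
# than any plausible component and collapse well-separated clusters; 1/16
# (prior component SD = a quarter of the profile SD) lets up to ~5 distinct
# activity levels be resolved.
VB_COVARIANCE_PRIOR = 1.0 / 16.0


@dataclass
class ClusteringResult:
    assignments: np.ndarray          # component id per sample
    component_means: dict[int, float]  # occupied components only
    ground_state: int                # occupied component with lowest mean
    n_effective_components: int

    @property
    def in_ground_state(self) -> np.ndarray:
        return self.assignments == self.ground_state


@dataclass
class BenchmarkResult:
    scenario: str
    accuracies: pd.DataFrame         # replicates x methods
    wilcoxon: dict[tuple[str, str], float]
    n_fallbacks: int = 0

    @property
    def mean_accuracy(self) -> pd.Series:
        return self.accuracies.mean()

    @property
    def sd_accuracy(self) -> pd.Series:
        return self.accuracies.std()


def vb_cluster_1d(
    scores: ActivityProfile | np.ndarray,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    seed: int | None = None,
) -> ClusteringResult:
    """Variational-Bayes Gaussian mixture fit to a 1-D activity profile.

    The variational treatment selects the effective number of components
    automatically: components that receive no samples under the
    maximum-responsibility assignment are dropped.  The occupied component
    with the lowest mean is the ground state (no pathway activity).

    The profile is standardised before fitting so the result is invariant
    to affine rescaling of the scores (the three estimators differ in
    scale but not meaning), and the component-variance prior is fixed on
    that standardised scale (see ``VB_COVARIANCE_PRIOR``).
    """
    x = np.asarray(scores.scores if isinstance(scores, ActivityProfile) else scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D profile with at least 2 samples")
    if np.ptp(x) == 0:
        return ClusteringResult(
            assignments=np.zeros(x.size, dtype=int),
            component_means={0: float(x[0])},
            ground_state=0,
            n_effective_components=1,
        )
    mu, sd = x.mean(), x.std()
    xs = (x - mu) / sd
    gmm = BayesianGaussianMixture(
        n_components=max_components,
        weight_concentration_prior_type="dirichlet_process",
        covariance_prior=np.array([[VB_COVARIANCE_PRIOR]]),
        tol=VB_TOL,
        max_iter=VB_MAX_ITER,
        n_init=VB_N_INIT,
        random_state=seed,
    )
    labels = gmm.fit_predict(xs.reshape(-1, 1))
    occupied = np.unique(labels)
    means = {int(k): float(gmm.means_[k, 0] * sd + mu) for k in occupied}
    ground = min(means, key=means.get)
    return ClusteringResult(
        assignments=labels,
        component_means=means,
        ground_state=ground,
        n_effective_components=len(occupied),
    )


def ground_state_accuracy(cluster: ClusteringResult, active) -> float:
    """Fraction of samples on the right side of the ground state.

    Inactive samples are correct when assigned to the ground state; active
    samples are correct when assigned to any higher-activity component (no
    level matching).  Invariant to component relabelling.
    """
    active = np.asarray(active, dtype=bool)
    if active.size != cluster.assignments.size:
        raise ValueError("label/assignment length mismatch")
    in_ground = cluster.in_ground_state
    correct = (~active & in_ground) | (active & ~in_ground)
    return float(np.mean(correct))


def paired_wilcoxon(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value; 1.0 when all pairs tie."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


def benchmark_simulation(
    scenario: str,
    methods: tuple[str, ...] = METHODS,
    n_reps: int = 100,
    seed: int | None = None,
    cfg: SimConfig | None = None,
    p_threshold: float = 1e-4,
    max_components: int = DEFAULT_MAX_COMPONENTS,
) -> BenchmarkResult:
    """Repeated-simulation benchmark of the activity estimators.

    For each replicate a fresh dataset is drawn, each estimator scores the
    samples (the pruned estimators share one network/component per
    replicate; replicates where pruning leaves no component fall back to
    the unpruned average, counted in ``n_fallbacks``), the profile is
    VB-clustered, and ground-state accuracy recorded.  Method pairs are
    compared with the two-sided paired Wilcoxon test across replicates.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    acc = np.zeros((n_reps, len(methods)))
    n_fallbacks = 0
    for r, s in enumerate(rep_seeds):
        data = simulate(scenario, seed=int(s), cfg=cfg)
        sig = data.signature()
        result = run_dart(
            data.X, sig, p_threshold=p_threshold, n_rand=100,
            seed=int(s), fallback_unpruned=True,
        )
        n_fallbacks += int(result.fallback_used)
        for m, method in enumerate(methods):
            if method.upper() == "DART" and not result.fallback_used:
                profile = result.activity
            elif method.upper() == "UPR-AV" or result.fallback_used:
                profile = estimate_activity(data.X, sig, "UPR-AV")
            else:
                profile = estimate_activity(data.X, sig, method, comp=result.component)
            cluster = vb_cluster_1d(profile, max_components=max_components, seed=int(s) % 2**31)
            acc[r, m] = ground_state_accuracy(cluster, data.active)
    accuracies = pd.DataFrame(acc, columns=list(methods))
    wilcoxon = {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            wilcoxon[(m1, m2)] = paired_wilcoxon(accuracies[m1], accuracies[m2])
    return BenchmarkResult(
        scenario=scenario, accuracies=accuracies, wilcoxon=wilcoxon, n_fallbacks=n_fallbacks
    )


_T_CAP = 1e6


def interpathway_correlation(
    act_i: ActivityProfile | np.ndarray, act_j: ActivityProfile | np.ndarray
) -> tuple[float, float]:
    """t-statistic and two-sided p of the regression slope between two profiles.

    Overlapping genes between the two pathways must have been excluded
    upstream (mutually exclusive gene sets), otherwise the correlation is
    partly an artefact of shared genes.
    """
    x = np.asarray(act_i.scores if isinstance(act_i, ActivityProfile) else act_i, dtype=float)
    y = np.asarray(act_j.scores if isinstance(act_j, ActivityProfile) else act_j, dtype=float)
    if x.size != y.size:
        raise ValueError("profiles cover different numbers of samples")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    res = stats.linregress(x, y)
    if res.stderr == 0:
        t = np.sign(res.slope) * _T_CAP if res.slope != 0 else 0.0
        return float(t), 0.0 if res.slope != 0 else 1.0
    return float(res.slope / res.stderr), float(res.pvalue)


def consistency_score_V(
    t_train: float,
    p_train: float,
    validation: list[tuple[float, float]],
    alpha: float = 0.05,
) -> float:
    """Cross-cohort consistency score for one pathway-pair hypothesis.

    V = sum over validation sets of sign_agreement * |t| * S(p), where
    S(p) = 1 if p <= alpha else 0 and sign_agreement is +1 when the
    validation t has the training sign, -1 otherwise.  Only pairs
    significant in training (p_train < alpha) qualify as hypotheses.
    """
    if not (p_train < alpha):
        raise ValueError(f"pair is not a hypothesis: p_train={p_train} >= {alpha}")
    v = 0.0
    for t_d, p_d in validation:
        if p_d > alpha:
            continue
        agree = 1.0 if np.sign(t_d) == np.sign(t_train) else -1.0
        v += agree * abs(t_d)
    return v


def compare_methods_V(v1, v2) -> float:
    """Paired Wilcoxon p comparing two methods' V scores on common hypotheses."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.size != v2.size or v1.size < 2:
        raise ValueError("need >= 2 common hypotheses")
    return paired_wilcoxon(v1, v2)


def _regression_t(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Slope t-statistics of x against each row of Y (vectorised)."""
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Yc @ xc / denom, 0.0)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
    return t


def phenotype_association(
    scores: ActivityProfile | np.ndarray,
    covariate,
    test: str = "permutation_regression",
    direction: str = "two-sided",
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Association p-value between activity scores and a phenotype.

    ``t_one_tailed``: one-tailed two-sample t-test on a binary group label;
    ``direction`` states which group is expected higher ('greater' means
    group 1 > group 0).  ``permutation_regression``: empirical p from
    permuting the covariate across samples and comparing regression
    t-statistics, with the add-one convention (k+1)/(n_perm+1), so the
    smallest reportable p is 1/(n_perm+1).
    """
    x = np.asarray(scores.scores if isinstance(scores, ActivityProfile) else scores, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if x.size != cov.size:
        raise ValueError("scores/covariate length mismatch")
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")

    if test == "t_one_tailed":
        groups = np.unique(cov)
        if groups.size != 2:
            raise ValueError("one-tailed t-test needs a binary group label")
        g0, g1 = x[cov == groups[0]], x[cov == groups[1]]
        alt = {"greater": "greater", "less": "less"}.get(direction)
        if alt is None:
            raise ValueError("one-tailed t-test needs direction 'greater' or 'less'")
        return float(stats.ttest_ind(g1, g0, alternative=alt).pvalue)

    if test == "permutation_regression":
        rng = np.random.default_rng(seed)
        t_obs = _regression_t(cov, x[None, :])[0]
        perms = np.stack([rng.permutation(cov) for _ in range(n_perm)])
        t_null = np.array([_regression_t(p, x[None, :])[0] for p in perms])
        if direction == "two-sided":
            k = int(np.count_nonzero(np.abs(t_null) >= abs(t_obs)))
        elif direction == "greater":
            k = int(np.count_nonzero(t_null >= t_obs))
        elif direction == "less":
            k = int(np.count_nonzero(t_null <= t_obs))
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return (k + 1) / (n_perm + 1)

    raise ValueError(f"unknown test {test!r}")
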