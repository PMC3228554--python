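"""Per-sample pathway activity metrics and the full DART pipeline.

Three estimators are provided, all operating on z-score normalised
expression (each gene mean 0, SD 1 across the samples being scored):

* UPR-AV — simple signed average over the unpruned signature gene set:
  score_s = (1/M) * sum_i sigma_i * z_is.
* PR-AV  — the same average restricted to the largest connected component
  of the pruned (consistent-edge) relevance network.
* DART   — degree-weighted average over that component:
  score_s = (1/sqrt(sum_i k_i^2)) * sum_i sigma_i * k_i * z_is,
  where k_i is the node degree; the normalisation makes the score unit
  variance when the gene z-profiles are independent unit-variance
  variables, and gives correlation hubs proportionally more weight.

``run_dart`` chains the pipeline: relevance network -> consistency check
-> pruning -> maximal component -> activity.  The network topology can be
learned on a training cohort and applied to an independent test cohort;
z-scoring is always done within the cohort being scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consistency import (
    DEFAULT_CONSISTENCY_CUTOFF,
    DEFAULT_N_RANDOMISATIONS,
    ConsistencyReport,
    EmptyNetworkError,
    consistency_pvalue,
)
from .io import PathwaySignature, RelevanceNetwork, logger
from .network import DEFAULT_P_THRESHOLD, build_network
from .pruning import EmptyComponentError, PrunedComponent, max_connected_component, prune_inconsistent

__all__ = [
    "ActivityProfile",
    "DartResult",
    "zscore",
    "activity_unweighted",
    "activity_weighted",
    "estimate_activity",
    "run_dart",
]

METHODS = ("UPR-AV", "PR-AV", "DART")


@dataclass
class ActivityProfile:
    """One pathway activity score per sample."""

    sample_ids: list[str]
    scores: np.ndarray
    method: str
    genes_used: dict[str, int]  # gene -> prior sign
    weights: dict[str, int] | None = None  # gene -> degree (DART only)
    normalization_stats: pd.DataFrame | None = field(repr=False, default=None)
    reliable: bool = True

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name=self.method)


@dataclass
class DartResult:
    network: RelevanceNetwork
    consistency: ConsistencyReport | None
    component: PrunedComponent | None
    activity: ActivityProfile
    test_activity: ActivityProfile | None = None
    fallback_used: bool = False


def zscore(X: pd.DataFrame, genes=None, ddof: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score normalise gene rows (mean 0, SD 1; population SD by default).

    Returns the normalised sub-matrix and a per-gene table of the mean/SD
    used.  Zero-SD genes are dropped with a warning.
    """
    sub = X.loc[[g for g in X.index if g in set(genes)]] if genes is not None else X
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        logger.warning("zscore: dropping %d constant genes", int((~keep).sum()))
    sub, mu, sd = sub.loc[keep], mu[keep], sd[keep]
    if sub.empty:
        raise ValueError("no gene with positive variance to normalise")
    Z = sub.sub(mu, axis=0).div(sd, axis=0)
    stats = pd.DataFrame({"mean": mu, "sd": sd})
    return Z, stats


def activity_unweighted(
    Z: pd.DataFrame, signs: dict[str, int], method: str = "PR-AV"
) -> ActivityProfile:
    """Simple signed-average activity: score_s = (1/M) sum_i sigma_i z_is."""
    genes = [g for g in Z.index if g in signs]
    if not genes:
        raise ValueError("no genes shared between Z and the sign map")
    sigma = np.array([signs[g] for g in genes], dtype=float)
    scores = sigma @ Z.loc[genes].to_numpy() / len(genes)
    return ActivityProfile(
        sample_ids=list(Z.columns),
        scores=scores,
        method=method,
        genes_used={g: signs[g] for g in genes},
    )


def activity_weighted(Z: pd.DataFrame, comp: PrunedComponent) -> ActivityProfile:
    """Degree-weighted activity over a pruned component.

    score_s = (1/sqrt(sum_i k_i^2)) * sum_i sigma_i * k_i * z_is.  The
    1/sqrt(sum k_i^2) normalisation is the unique scaling under which the
    score has unit variance for independent unit-variance gene profiles.
    """
    degrees = comp.degrees
    genes = [g for g in Z.index if g in degrees]
    if not genes:
        raise ValueError("no component gene present in the normalised matrix")
    k = np.array([degrees[g] for g in genes], dtype=float)
    sigma = np.array([comp.signs[g] for g in genes], dtype=float)
    norm = np.sqrt(np.sum(k**2))
    scores = (sigma * k) @ Z.loc[genes].to_numpy() / norm
    return ActivityProfile(
        sample_ids=list(Z.columns),
        scores=scores,
        method="DART",
        genes_used={g: comp.signs[g] for g in genes},
        weights={g: degrees[g] for g in genes},
    )


def estimate_activity(
    X: pd.DataFrame,
    sig: PathwaySignature,
    method: str,
    comp: PrunedComponent | None = None,
    ddof: int = 0,
) -> ActivityProfile:
    """Score samples in X with one of the three estimators.

    ``comp`` (the component learned on a training cohort) is required for
    the pruned estimators; z-scoring uses X itself.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method == "UPR-AV":
        Z, stats = zscore(X, sig.genes, ddof=ddof)
        profile = activity_unweighted(Z, dict(sig.signs), method="UPR-AV")
    else:
        if comp is None:
            raise ValueError(f"{method} needs a pruned component")
        Z, stats = zscore(X, comp.nodes, ddof=ddof)
        if method == "PR-AV":
            profile = activity_unweighted(Z, comp.signs, method="PR-AV")
        else:
            profile = activity_weighted(Z, comp)
    profile.normalization_stats = stats.loc[[g for g in stats.index if g in profile.genes_used]]
    return profile


def run_dart(
    X_train: pd.DataFrame,
    sig: PathwaySignature,
    X_test: pd.DataFrame | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_rand: int = DEFAULT_N_RANDOMISATIONS,
    consistency_cutoff: float = DEFAULT_CONSISTENCY_CUTOFF,
    seed: int | None = None,
    method: str = "DART",
    fallback_unpruned: bool = False,
    ddof: int = 0,
) -> DartResult:
    """Full pipeline: network -> consistency -> prune -> component -> activity.

    The relevance network and pruned component are learned on ``X_train``;
    if ``X_test`` is given the same component scores the test cohort
    (z-scored within the test cohort, so only topology transfers).  When
    the consistency check is not significant the prior is deemed
    unreliable in this data: a warning is emitted and the returned scores
    are flagged, but still computed.  If pruning leaves no connected
    component, ``fallback_unpruned=True`` degrades to the unpruned
    simple-average estimator instead of raising.
    """
    method = method.upper()
    net = build_network(X_train, sig, p_threshold=p_threshold)

    report: ConsistencyReport | None = None
    reliable = True
    try:
        report = consistency_pvalue(net, sig, n_rand=n_rand, seed=seed)
        if report.p_value > consistency_cutoff:
            reliable = False
            logger.warning(
                "consistency score %.3f not significant (p=%.3g > %.3g): "
                "prior information may be irrelevant in this data set; "
                "activity scores are flagged unreliable",
                report.fraction_consistent, report.p_value, consistency_cutoff,
            )
    except EmptyNetworkError:
        reliable = False
        logger.warning("relevance network has no edges; prior unevaluable")

    comp: PrunedComponent | None = None
    fallback = False
    if method == "UPR-AV":
        pass
    else:
        try:
            pruned = prune_inconsistent(net, sig)
            comp = max_connected_component(pruned, sig)
        except (EmptyNetworkError, EmptyComponentError):
            if not fallback_unpruned:
                raise
            fallback = True
            logger.warning("empty pruned component; falling back to UPR-AV")

    eff_method = "UPR-AV" if (method == "UPR-AV" or fallback) else method
    profile = estimate_activity(X_train, sig, eff_method, comp=comp, ddof=ddof)
    profile.reliable = reliable
    test_profile = None
    if X_test is not None:
        test_profile = estimate_activity(X_test, sig, eff_method, comp=comp, ddof=ddof)
        test_profile.reliable = reliable
    return DartResult(
        network=net,
        consistency=report,
        component=comp,
        activity=profile,
        test_activity=test_profile,
        fallback_used=fallback,
    )
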