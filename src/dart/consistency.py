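"""Consistency of observed correlation signs with the prior signature.

The prior predicts the sign of every gene-gene correlation: genes regulated
in the same direction upon pathway activation (both up or both down) should
correlate positively, genes regulated in opposite directions negatively —
i.e. the predicted edge sign is the product sigma_i * sigma_j.  The
consistency score of a relevance network is the fraction of its edges whose
observed correlation sign matches this prediction, and its significance is
assessed against a binomial randomisation null in which each edge's sign is
redrawn with the empirical probability of a positive correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PathwaySignature, RelevanceNetwork

__all__ = [
    "EmptyNetworkError",
    "ConsistencyReport",
    "predicted_edge_sign",
    "annotate_consistency",
    "consistency_score",
    "consistency_pvalue",
]

DEFAULT_N_RANDOMISATIONS = 1000
DEFAULT_CONSISTENCY_CUTOFF = 0.05


class EmptyNetworkError(ValueError):
    """Consistency of a network with no edges is undefined."""


@dataclass
class ConsistencyReport:
    n_edges: int
    fraction_consistent: float
    p_value: float
    binom_prob_positive: float
    n_randomisations: int
    null_scores: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value <= DEFAULT_CONSISTENCY_CUTOFF


def predicted_edge_sign(sig: PathwaySignature, gene_i: str, gene_j: str) -> int:
    """Sign the prior predicts for the correlation of two signature genes."""
    for g in (gene_i, gene_j):
        if g not in sig.signs:
            raise KeyError(f"gene {g!r} absent from signature {sig.name!r}")
    return sig.signs[gene_i] * sig.signs[gene_j]


def annotate_consistency(net: RelevanceNetwork, sig: PathwaySignature) -> RelevanceNetwork:
    """Attach ``predicted_sign`` and ``consistent`` to every edge, in place."""
    for u, v, d in net.graph.edges(data=True):
        pred = predicted_edge_sign(sig, u, v)
        d["predicted_sign"] = pred
        d["consistent"] = int(d["observed_sign"] == pred)
    return net


def _edge_signs(net: RelevanceNetwork, sig: PathwaySignature) -> tuple[np.ndarray, np.ndarray]:
    obs, pred = [], []
    for u, v, d in net.graph.edges(data=True):
        obs.append(d["observed_sign"])
        pred.append(predicted_edge_sign(sig, u, v))
    return np.asarray(obs, dtype=int), np.asarray(pred, dtype=int)


def consistency_score(net: RelevanceNetwork, sig: PathwaySignature) -> tuple[float, int]:
    """Fraction of network edges whose observed sign matches the prior.

    Returns ``(fraction_consistent, n_edges)``; raises
    :class:`EmptyNetworkError` on an edgeless network, in which case the
    pathway is unevaluable in this data set.
    """
    obs, pred = _edge_signs(net, sig)
    if obs.size == 0:
        raise EmptyNetworkError("network has no edges; consistency score undefined")
    return float(np.mean(obs == pred)), int(obs.size)


def consistency_pvalue(
    net: RelevanceNetwork,
    sig: PathwaySignature,
    n_rand: int = DEFAULT_N_RANDOMISATIONS,
    seed: int | None = None,
    prob_positive: float | None = None,
    add_one_smoothing: bool = False,
) -> ConsistencyReport:
    """Randomisation p-value for the network consistency score.

    Each randomisation redraws every edge's observed sign as +1 with
    probability ``prob_positive`` (by default the fraction of positive
    correlation signs among this network's significant edges — the null
    must share the empirical sign imbalance) and recomputes the consistency
    fraction.  The p-value is the fraction of randomisations scoring
    strictly higher than the observed network; ``add_one_smoothing`` uses
    (k+1)/(n+1) instead to avoid reporting exactly zero.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    obs, pred = _edge_signs(net, sig)
    if obs.size == 0:
        raise EmptyNetworkError("network has no edges; consistency p-value undefined")
    observed_score = float(np.mean(obs == pred))
    q = float(np.mean(obs == 1)) if prob_positive is None else float(prob_positive)
    rng = np.random.default_rng(seed)
    drawn = np.where(rng.random((n_rand, obs.size)) < q, 1, -1)
    null_scores = np.mean(drawn == pred[None, :], axis=1)
    k = int(np.count_nonzero(null_scores > observed_score))
    p = (k + 1) / (n_rand + 1) if add_one_smoothing else k / n_rand
    return ConsistencyReport(
        n_edges=int(obs.size),
        fraction_consistent=observed_score,
        p_value=float(p),
        binom_prob_positive=q,
        n_randomisations=n_rand,
        null_scores=null_scores,
        seed=seed,
    )
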