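"""Relevance correlation networks over signature genes.

Two genes are joined by an edge when their Pearson correlation is
significant under the Fisher z-transform null: y = arctanh(c) is
approximately Normal(0, 1/sqrt(n_s - 3)) for uncorrelated genes, so each
pair gets a two-sided p-value and pairs with p at or below a threshold
(default 1e-4) become edges.  Because gene-pair correlations are not
independent tests, the expected number of false-positive edges is
estimated by Monte Carlo: permute every gene's profile across samples
(destroying all gene-gene correlation while preserving marginals) and
count edges that still pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwaySignature, RelevanceNetwork, logger

__all__ = [
    "CollinearityError",
    "FdrEstimate",
    "fisher_statistic",
    "pairwise_correlations",
    "estimate_edge_fdr",
    "select_p_threshold",
    "build_network",
]

DEFAULT_P_THRESHOLD = 1e-4

_COLLINEAR_TOL = 1e-12


class CollinearityError(ValueError):
    """Raised when |c| >= 1 makes the Fisher statistic infinite."""


@dataclass
class FdrEstimate:
    """Result of the Monte Carlo edge false-positive estimate."""

    n_monte_carlo: int
    p_threshold: float
    per_run_counts: np.ndarray
    seed: int | None = None

    @property
    def avg_false_positives(self) -> float:
        return float(np.mean(self.per_run_counts))


def fisher_statistic(c: float, n_samples: int) -> tuple[float, float]:
    """Fisher z-statistic and two-sided p-value for a Pearson correlation.

    y = arctanh(c) = (1/2) log((1+c)/(1-c)); under the null of no
    correlation y ~ Normal(0, 1/sqrt(n_samples - 3)).

    Raises :class:`CollinearityError` for |c| >= 1 (perfectly collinear
    genes); callers that tolerate duplicated profiles assign p = 0 and flag
    the pair instead of propagating the error.
    """
    if n_samples < 4:
        raise ValueError(f"need n_samples >= 4 for the Fisher null SD, got {n_samples}")
    if abs(c) >= 1:
        raise CollinearityError(f"|c| = {abs(c)} >= 1: Fisher statistic infinite")
    y = float(np.arctanh(c))
    sd = 1.0 / np.sqrt(n_samples - 3)
    p = float(2.0 * stats.norm.sf(abs(y), scale=sd))
    return y, p


def _fisher_pvalues(c: np.ndarray, n_samples: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Fisher p-values; collinear pairs get p = 0 and a flag."""
    collinear = np.abs(c) >= 1.0 - _COLLINEAR_TOL
    safe = np.clip(c, -1.0 + 1e-15, 1.0 - 1e-15)
    y = np.arctanh(safe)
    sd = 1.0 / np.sqrt(n_samples - 3)
    p = 2.0 * stats.norm.sf(np.abs(y), scale=sd)
    p = np.where(collinear, 0.0, p)
    return y, p, collinear


def _usable_genes(X: pd.DataFrame, genes) -> list[str]:
    present = [g for g in X.index if g in set(genes)] if genes is not None else list(X.index)
    sub = X.loc[present]
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        logger.warning("dropping %d zero-variance genes: %s%s",
                       len(zero_var), zero_var[:5], "..." if len(zero_var) > 5 else "")
    return [g for g in present if g not in set(zero_var)]


def pairwise_correlations(X: pd.DataFrame, genes=None) -> pd.DataFrame:
    """All-pairs Pearson correlation statistics among the given genes.

    Returns one row per unordered pair with columns ``gene_i``, ``gene_j``,
    ``corr``, ``y``, ``p``, ``observed_sign``, ``collinear``.  Zero-variance
    genes are dropped with a warning before correlation.
    """
    n_s = X.shape[1]
    if n_s < 4:
        raise ValueError(f"need at least 4 samples, got {n_s}")
    usable = _usable_genes(X, genes)
    if len(usable) < 2:
        raise ValueError(f"fewer than 2 usable genes (got {len(usable)})")
    V = X.loc[usable].to_numpy(dtype=float)
    C = np.corrcoef(V)
    iu, ju = np.triu_indices(len(usable), k=1)
    c = C[iu, ju]
    y, p, collinear = _fisher_pvalues(c, n_s)
    names = np.asarray(usable)
    return pd.DataFrame(
        {
            "gene_i": names[iu],
            "gene_j": names[ju],
            "corr": c,
            "y": y,
            "p": p,
            "observed_sign": np.where(c > 0, 1, -1).astype(int),
            "collinear": collinear,
        }
    )


def _critical_abs_corr(p_threshold: float, n_samples: int) -> float:
    """|c| cut-off equivalent to the two-sided Fisher p-value threshold."""
    if p_threshold >= 1.0:
        return 0.0
    y_crit = stats.norm.isf(p_threshold / 2.0) / np.sqrt(n_samples - 3)
    return float(np.tanh(y_crit))


def estimate_edge_fdr(
    X: pd.DataFrame,
    genes=None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_runs: int = 1000,
    seed: int | None = None,
) -> FdrEstimate:
    """Monte Carlo estimate of false-positive edges at a p-value threshold.

    Each run independently permutes every gene's expression profile across
    samples and counts the gene pairs whose correlation p-value still falls
    at or below ``p_threshold``.  The average count over runs estimates the
    expected number of false-positive edges in a network built at that
    threshold.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    usable = _usable_genes(X, genes)
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable genes")
    V = X.loc[usable].to_numpy(dtype=float)
    n_s = V.shape[1]
    crit = _critical_abs_corr(p_threshold, n_s)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(V.shape[0], k=1)
    counts = np.empty(n_runs, dtype=int)
    for r in range(n_runs):
        perm = rng.permuted(V, axis=1)
        C = np.corrcoef(perm)
        counts[r] = int(np.count_nonzero(np.abs(C[iu, ju]) >= crit))
    return FdrEstimate(n_monte_carlo=n_runs, p_threshold=p_threshold,
                       per_run_counts=counts, seed=seed)


def select_p_threshold(
    X: pd.DataFrame,
    genes=None,
    target_false_positives: float = 1.0,
    candidates=(1e-2, 1e-3, 1e-4, 1e-5, 1e-6),
    n_runs: int = 100,
    seed: int | None = None,
) -> tuple[float, list[FdrEstimate]]:
    """Pick the largest candidate threshold meeting a false-positive target.

    Walks the candidate thresholds from most to least permissive and
    returns the first whose Monte Carlo average false-positive count is at
    or below ``target_false_positives`` (the least permissive candidate if
    none qualifies).
    """
    estimates = []
    chosen = min(candidates)
    for p in sorted(candidates, reverse=True):
        est = estimate_edge_fdr(X, genes, p_threshold=p, n_runs=n_runs, seed=seed)
        estimates.append(est)
        if est.avg_false_positives <= target_false_positives:
            chosen = p
            break
    return chosen, estimates


def build_network(
    X: pd.DataFrame,
    sig: PathwaySignature,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> RelevanceNetwork:
    """Build the relevance correlation network of signature genes.

    Nodes are the signature genes present in the matrix (minus any
    zero-variance genes); edges are the pairs whose Fisher-transform
    p-value is at or below ``p_threshold``.  Collinear pairs (|c| = 1) are
    retained with p = 0 and a ``collinear`` flag.
    """
    present = [g for g in sig.genes if g in X.index]
    if not present:
        missing = [g for g in sig.genes if g not in X.index]
        raise ValueError(
            f"no signature gene found in the expression matrix "
            f"(first missing: {missing[:5]})"
        )
    if len(present) < 2:
        raise ValueError(f"need at least 2 signature genes in the matrix, got {len(present)}")
    edges = pairwise_correlations(X, present)
    usable = _usable_genes(X, present)
    g = nx.Graph()
    for gene in usable:
        g.add_node(gene, prior_sign=sig.signs[gene])
    keep = edges[edges["p"] <= p_threshold]
    for row in keep.itertuples(index=False):
        g.add_edge(
            row.gene_i,
            row.gene_j,
            corr=float(row.corr),
            y=float(row.y),
            p=float(row.p),
            observed_sign=int(row.observed_sign),
            collinear=bool(row.collinear),
        )
    return RelevanceNetwork(graph=g, p_threshold=p_threshold, n_samples=X.shape[1])
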