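"""Synthetic expression data with known per-sample pathway activity.

Two scenarios over a 24-gene x 100-sample toy matrix, with 40 inactive
samples and 60 samples carrying variable pathway activity (3 levels).
Three block-indicator patterns drive the activation signal (sample index s
is 1-based):

* pattern 1: mean mu (=2) for s > 40, else 0
* pattern 2: mean mu for 40 < s <= 60 or s > 80, else 0
* pattern 3: mean mu for s > 80, else 0

A sample's true activity level is the number of patterns switched on:
level 0 for samples 1-40, then 2 / 1 / 3 for the three 20-sample blocks.

SimSet1: every gene carries a pattern, but only genes 1-3 do so with low
noise (SD sigma1 = 0.25); genes 4-24 carry the same patterns with SD
sigma2 = 3 and are therefore unfaithful reporters.  SimSet2: only genes
1-6 carry a pattern (genes 1-3 with sigma1, genes 4-6 with sigma2); genes
7-24 are pure N(0, 2) noise, not discriminatory at all.

Down-regulated genes are not simulated separately: a gene downregulated on
activation is the mirror image of an upregulated one, and the activity
metrics carry direction explicitly through the prior sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import PathwaySignature

__all__ = ["SimConfig", "SimulatedDataset", "simset1", "simset2", "simulate"]


@dataclass(frozen=True)
class SimConfig:
    """Generative settings for the synthetic scenarios."""

    n_genes: int = 24
    n_samples: int = 100
    n_inactive: int = 40
    mu_active: float = 2.0
    sigma1: float = 0.25  # low-noise "faithful" genes
    sigma2: float = 3.0   # high-variability pattern genes
    noise_sd: float = 2.0  # non-discriminatory genes (SimSet2 only)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.n_inactive < self.n_samples):
            raise ValueError("need 0 < n_inactive < n_samples")
        if self.n_genes < 6:
            raise ValueError("need at least 6 genes")


@dataclass
class SimulatedDataset:
    X: pd.DataFrame                 # genes x samples
    active: np.ndarray              # bool per sample
    level: np.ndarray               # int in {0,1,2,3} per sample
    scenario: str
    config: SimConfig

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.X.columns, "active": self.active.astype(int), "level": self.level}
        )

    def signature(self) -> PathwaySignature:
        """All simulated genes, annotated upregulated upon activation."""
        return PathwaySignature(self.scenario, {g: +1 for g in self.X.index})


def _patterns(cfg: SimConfig) -> np.ndarray:
    """Three 0/1 block-indicator rows over the samples."""
    s = np.arange(1, cfg.n_samples + 1)
    n0 = cfg.n_inactive
    width = (cfg.n_samples - n0) / 3.0
    b1, b2 = n0 + width, n0 + 2 * width
    p1 = s > n0
    p2 = ((s > n0) & (s <= b1)) | (s > b2)
    p3 = s > b2
    return np.vstack([p1, p2, p3]).astype(float)


def _labels(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    level = patterns.sum(axis=0).astype(int)
    return level > 0, level


def _gene_rngs(cfg: SimConfig) -> list[np.random.Generator]:
    # one sub-stream per gene so a gene's draws are stable under config changes
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_genes)
    return [np.random.default_rng(c) for c in children]


def _frame(values: np.ndarray, cfg: SimConfig) -> pd.DataFrame:
    genes = [f"g{i + 1:02d}" for i in range(cfg.n_genes)]
    samples = [f"s{j + 1:03d}" for j in range(cfg.n_samples)]
    return pd.DataFrame(values, index=genes, columns=samples)


def simset1(cfg: SimConfig | None = None) -> SimulatedDataset:
    """All genes carry an activation pattern; only genes 1-3 are low-noise.

    Genes 1-3 follow patterns 1-3 with SD ``sigma1``; genes 4..n cycle
    through the same three patterns with SD ``sigma2``.
    """
    cfg = cfg or SimConfig()
    pats = _patterns(cfg) * cfg.mu_active
    rngs = _gene_rngs(cfg)
    rows = []
    for i in range(cfg.n_genes):
        mean = pats[i % 3]
        sd = cfg.sigma1 if i < 3 else cfg.sigma2
        rows.append(mean + rngs[i].normal(0.0, sd, size=cfg.n_samples))
    active, level = _labels(_patterns(cfg))
    return SimulatedDataset(_frame(np.vstack(rows), cfg), active, level, "SimSet1", cfg)


def simset2(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Only 6 genes carry the activation pattern; the rest are noise.

    Genes 1-3 follow patterns 1-3 with SD ``sigma1``, genes 4-6 the same
    patterns with SD ``sigma2``; genes 7..n are i.i.d. N(0, noise_sd) and
    carry no pathway signal.
    """
    cfg = cfg or SimConfig()
    pats = _patterns(cfg) * cfg.mu_active
    rngs = _gene_rngs(cfg)
    rows = []
    for i in range(cfg.n_genes):
        if i < 6:
            mean = pats[i % 3]
            sd = cfg.sigma1 if i < 3 else cfg.sigma2
            rows.append(mean + rngs[i].normal(0.0, sd, size=cfg.n_samples))
        else:
            rows.append(rngs[i].normal(0.0, cfg.noise_sd, size=cfg.n_samples))
    active, level = _labels(_patterns(cfg))
    return SimulatedDataset(_frame(np.vstack(rows), cfg), active, level, "SimSet2", cfg)


def simulate(scenario: str, seed: int | None = None, cfg: SimConfig | None = None) -> SimulatedDataset:
    """Dispatch by scenario name ('simset1' or 'simset2')."""
    cfg = replace(cfg or SimConfig(), seed=seed) if seed is not None else (cfg or SimConfig())
    key = scenario.lower().replace("_", "")
    if key == "simset1":
        return simset1(cfg)
    if key == "simset2":
        return simset2(cfg)
    raise ValueError(f"unknown scenario {scenario!r}")
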