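"""Plain-text input/output for expression matrices, signatures and networks.

Expression matrices travel as tab- or comma-delimited text with one header
row of sample identifiers and one leading column of gene identifiers; the
in-memory container is a :class:`pandas.DataFrame` in genes x samples
orientation.  Pathway signatures are two-column tables mapping a gene
identifier to its sign of regulation upon pathway activation (+1 up, -1
down).  Networks are interchanged as an edge-list TSV plus a node TSV so
that every artefact is inspectable and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("dart")

__all__ = [
    "PathwaySignature",
    "RelevanceNetwork",
    "ExpressionLoadError",
    "SignatureError",
    "read_expression",
    "read_signature",
    "read_signature_lists",
    "write_expression",
    "write_signature",
    "write_network",
    "read_network",
    "write_activity",
]

_UP_TOKENS = {"1", "+1", "up"}
_DOWN_TOKENS = {"-1", "down"}


class ExpressionLoadError(ValueError):
    """Raised when an expression table cannot be parsed into a clean matrix."""


class SignatureError(ValueError):
    """Raised for malformed pathway signatures (conflicts, unknown tokens)."""


@dataclass(frozen=True)
class PathwaySignature:
    """Prior pathway information: gene -> sign of regulation upon activation.

    ``signs`` maps each gene identifier to +1 (upregulated when the pathway
    is active) or -1 (downregulated).  Either direction may be empty, but
    the signature must contain at least two genes for any correlation work.
    """

    name: str
    signs: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.signs.items() if s not in (+1, -1)}
        if bad:
            raise SignatureError(f"signature signs must be +1 or -1, got {bad}")
        if len(self.signs) < 2:
            raise SignatureError(
                f"signature '{self.name}' needs at least 2 genes, got {len(self.signs)}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.signs)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, s in self.signs.items() if s == +1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, s in self.signs.items() if s == -1]

    @property
    def n_up(self) -> int:
        return len(self.up_genes)

    @property
    def n_down(self) -> int:
        return len(self.down_genes)

    def flipped(self) -> "PathwaySignature":
        """Signature with every sign negated (used in symmetry checks)."""
        return PathwaySignature(self.name + "_flipped", {g: -s for g, s in self.signs.items()})

    def restricted(self, genes: Iterable[str], name: str | None = None) -> "PathwaySignature":
        keep = set(genes)
        return PathwaySignature(
            name or self.name, {g: s for g, s in self.signs.items() if g in keep}
        )


@dataclass
class RelevanceNetwork:
    """Undirected correlation network over signature genes.

    Edge attributes: ``corr`` (Pearson correlation), ``y`` (Fisher
    z-statistic), ``p`` (two-sided p-value under the normal null),
    ``observed_sign`` (+1/-1 from the correlation sign), ``collinear``
    (bool), and — once annotated against a signature — ``predicted_sign``
    and ``consistent``.
    """

    graph: nx.Graph
    p_threshold: float
    n_samples: int

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
            a, b = sorted((u, v))
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "correlation": d.get("corr"),
                    "observed_sign": d.get("observed_sign"),
                    "predicted_sign": d.get("predicted_sign"),
                    "consistent": d.get("consistent"),
                }
            )
        cols = ["gene_a", "gene_b", "correlation", "observed_sign", "predicted_sign", "consistent"]
        return pd.DataFrame(rows, columns=cols)


def _sniff_sep(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()
    first = head[0] if head else ""
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Load an expression matrix into genes x samples orientation.

    Parameters
    ----------
    path
        Tab- or comma-delimited text; one header row, one identifier column.
    orientation
        ``genes_in_rows`` (default) or ``samples_in_rows``; the latter is
        transposed on load so the result is always genes x samples.
    impute_missing
        If True, missing cells are filled with the per-gene median (the
        number imputed is logged); otherwise any missing value is an error.
        Complete pairwise vectors are assumed by all correlation work, so
        rejection is the default policy.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    # read the header ourselves: pandas silently renames duplicate columns
    with open(path, encoding="utf-8") as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)[1:]]
    df = pd.read_csv(path, sep=sep, index_col=0, header=None, skiprows=1)
    df.columns = header
    df.index = df.index.astype(str).str.strip()
    if orientation == "samples_in_rows":
        df = df.T

    if pd.Index(df.columns).duplicated().any():
        dups = pd.Index(df.columns)
        dups = dups[dups.duplicated()].unique().tolist()
        raise ExpressionLoadError(f"duplicate sample identifiers: {dups[:5]}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # a row with no numeric cell at all is junk (e.g. a stray annotation row)
    all_bad = numeric.isna().all(axis=1) & df.notna().all(axis=1)
    if all_bad.any():
        logger.warning("dropping %d entirely non-numeric rows", int(all_bad.sum()))
        numeric = numeric.loc[~all_bad]
        df = df.loc[~all_bad]

    bad_cells = numeric.isna() & df.notna()
    if bad_cells.any().any():
        r = bad_cells.any(axis=1).idxmax()
        c = bad_cells.loc[r].idxmax()
        raise ExpressionLoadError(f"unparseable value at row {r!r}, column {c!r}: {df.loc[r, c]!r}")

    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()

    if numeric.isna().any().any():
        if impute_missing:
            n_missing = int(numeric.isna().sum().sum())
            numeric = numeric.apply(lambda row: row.fillna(row.median()), axis=1)
            logger.warning("imputed %d missing values with per-gene medians", n_missing)
        else:
            r = numeric.isna().any(axis=1).idxmax()
            raise ExpressionLoadError(
                f"missing values (first offending gene: {r!r}); "
                "pass impute_missing=True to fill with per-gene medians"
            )

    if numeric.shape[0] < 1:
        raise ExpressionLoadError("no usable gene rows")
    return numeric


def write_expression(X: pd.DataFrame, path: str | Path) -> None:
    X.to_csv(Path(path), sep="\t", index_label="gene_id", lineterminator="\n")


def _parse_sign(token: str) -> int:
    t = str(token).strip().lower()
    if t in _UP_TOKENS:
        return +1
    if t in _DOWN_TOKENS:
        return -1
    raise SignatureError(f"unrecognised sign token {token!r} (expected 1/-1/up/down)")


def read_signature(path: str | Path, name: str | None = None) -> PathwaySignature:
    """Read a two-column gene/sign table into a :class:`PathwaySignature`.

    Duplicate genes with the same sign are deduplicated; conflicting signs
    for one gene are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SignatureError(f"{path}: expected two columns (gene, sign)")
    signs: dict[str, int] = {}
    for _, (gene, tok) in df.iloc[:, :2].iterrows():
        g = str(gene).strip()
        s = _parse_sign(tok)
        if g in signs and signs[g] != s:
            raise SignatureError(f"conflicting sign for gene {g!r}")
        signs[g] = s
    if not signs:
        raise SignatureError(f"{path}: empty signature")
    return PathwaySignature(name or path.stem, signs)


def read_signature_lists(
    up_path: str | Path | None, down_path: str | Path | None, name: str = "signature"
) -> PathwaySignature:
    """Build a signature from one plain gene list per direction (either may be absent)."""
    signs: dict[str, int] = {}
    for p, s in ((up_path, +1), (down_path, -1)):
        if p is None:
            continue
        for line in Path(p).read_text(encoding="utf-8").splitlines():
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g in signs and signs[g] != s:
                raise SignatureError(f"conflicting sign for gene {g!r}")
            signs[g] = s
    if not signs:
        raise SignatureError("empty signature")
    return PathwaySignature(name, signs)


def write_signature(sig: PathwaySignature, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g, s in sig.signs.items():
            fh.write(f"{g}\t{s}\n")


# ---------------------------------------------------------------------------
# network round trip: edges.tsv + nodes.tsv in a directory


def write_network(net, outdir: str | Path, signs: Mapping[str, int] | None = None) -> None:
    """Write a network (or pruned component) as ``edges.tsv`` + ``nodes.tsv``.

    Topology, correlations and signs round-trip losslessly through
    :func:`read_network`.  ``signs`` supplies prior signs for the node table
    when the network object does not carry them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = net.graph
    node_signs = dict(getattr(net, "signs", None) or signs or {})

    edges = net.edge_table() if hasattr(net, "edge_table") else None
    if edges is None:
        rows = []
        for u, v, d in graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((a, b, d.get("corr"), d.get("observed_sign"),
                         d.get("predicted_sign"), d.get("consistent")))
        edges = pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "correlation", "observed_sign",
                     "predicted_sign", "consistent"],
        ).sort_values(["gene_a", "gene_b"])
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.17g",
                 lineterminator="\n")

    nodes = pd.DataFrame(
        {
            "gene": sorted(graph.nodes),
            "degree": [graph.degree(g) for g in sorted(graph.nodes)],
            "prior_sign": [node_signs.get(g) for g in sorted(graph.nodes)],
        }
    )
    nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False, lineterminator="\n")

    meta = {}
    for k in ("p_threshold", "n_samples"):
        v = getattr(net, k, None)
        if v is not None:
            meta[k] = v
    if meta:
        pd.Series(meta).to_csv(outdir / "meta.tsv", sep="\t", header=False,
                               lineterminator="\n")


def read_network(indir: str | Path) -> RelevanceNetwork:
    """Read a network written by :func:`write_network`."""
    indir = Path(indir)
    edges = pd.read_csv(indir / "edges.tsv", sep="\t")
    nodes = pd.read_csv(indir / "nodes.tsv", sep="\t")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        attrs = {}
        if pd.notna(row.get("prior_sign")):
            attrs["prior_sign"] = int(row["prior_sign"])
        g.add_node(str(row["gene"]), **attrs)
    for _, row in edges.iterrows():
        attrs = {"corr": float(row["correlation"]),
                 "observed_sign": int(row["observed_sign"])}
        for k in ("predicted_sign", "consistent"):
            if pd.notna(row.get(k)):
                attrs[k] = int(row[k])
        g.add_edge(str(row["gene_a"]), str(row["gene_b"]), **attrs)
    p_threshold, n_samples = float("nan"), 0
    meta_path = indir / "meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", header=None, index_col=0).iloc[:, 0]
        p_threshold = float(meta.get("p_threshold", float("nan")))
        n_samples = int(meta.get("n_samples", 0))
    return RelevanceNetwork(graph=g, p_threshold=p_threshold, n_samples=n_samples)


def write_activity(profile, path: str | Path) -> None:
    """Write an activity profile as TSV: sample_id, score, method, flags."""
    flags = "" if getattr(profile, "reliable", True) else "unreliable_prior"
    df = pd.DataFrame(
        {
            "sample_id": profile.sample_ids,
            "score": profile.scores,
            "method": profile.method,
            "flags": flags,
        }
    )
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.17g",
              lineterminator="\n")
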