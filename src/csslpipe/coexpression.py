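"""Gene co-expression network at a hard correlation cutoff, and hub genes.

Given a gene x sample expression matrix and a set of seed genes (here, the
SNP-bearing genes from the introgression scan), pairwise Pearson correlations
are computed for every pair involving a seed gene; pairs passing the cutoff
(default r >= 0.95, positive co-expression only) become edges of an
undirected network.  "Major nodes" — hub genes — are the seed genes of
highest degree, selected either as a top-k or by a minimum-degree rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class NetworkConfig:
    """Network construction and hub selection parameters.

    The cutoff is inclusive (an edge is kept at r exactly equal to the
    cutoff).  ``correlation_mode`` is ``"positive"`` (edge iff r >= cutoff)
    or ``"absolute"`` (edge iff |r| >= cutoff).  Hubs are chosen by
    ``hub_rule``: ``"top_k"`` keeps the ``hub_param`` highest-degree seed
    genes; ``"degree_min"`` keeps every seed gene with degree >=
    ``hub_param``.
    """

    correlation_cutoff: float = 0.95
    correlation_mode: str = "positive"
    min_samples: int = 3
    hub_rule: str = "top_k"
    hub_param: int = 18

    def __post_init__(self) -> None:
        if not (0 < self.correlation_cutoff <= 1):
            raise ValueError("correlation_cutoff must be in (0, 1]")
        if self.correlation_mode not in ("positive", "absolute"):
            raise ValueError("correlation_mode must be 'positive' or 'absolute'")
        if self.hub_rule not in ("top_k", "degree_min"):
            raise ValueError("hub_rule must be 'top_k' or 'degree_min'")
        if self.hub_param < 1:
            raise ValueError("hub_param must be >= 1")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV (first column gene ids, header row samples)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(matrix)
    return matrix


def validate_expression(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    finite = np.isfinite(matrix.to_numpy(dtype=float)).sum(axis=1)
    bad = matrix.index[finite < 3].tolist()
    if bad:
        raise ValueError(f"genes with fewer than 3 finite values: {bad}")


def pearson_correlations(
    matrix: pd.DataFrame,
    seed_genes: Sequence[str] | None = None,
    min_samples: int = 3,
) -> dict[tuple[str, str], float]:
    """Pearson r for every gene pair involving at least one seed gene.

    With ``seed_genes=None`` all pairs are computed (intended for small
    matrices).  Correlations use pairwise-complete samples; a pair with
    fewer than ``min_samples`` complete observations, or involving a
    zero-variance profile, is skipped with a warning.  Keys are sorted
    (a, b) tuples with a < b.
    """
    validate_expression(matrix)
    gene_ids = list(matrix.index)
    if seed_genes is None:
        seeds = gene_ids
    else:
        missing = [g for g in seed_genes if g not in set(gene_ids)]
        if missing:
            warnings.warn(f"seed genes absent from matrix, skipped: {missing}")
        seeds = [g for g in seed_genes if g in set(gene_ids)]
    values = matrix.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    finite = np.isfinite(values)
    clean = np.all(finite, axis=1)
    out: dict[tuple[str, str], float] = {}
    seed_set = set(seeds)

    # fast path: fully observed rows, vectorized seed-vs-all correlation
    centered = values - np.nanmean(values, axis=1, keepdims=True)
    centered[~finite] = np.nan
    norms = np.sqrt(np.nansum(centered**2, axis=1))
    degenerate_warned = set()
    for a in seeds:
        ia = index[a]
        for b in gene_ids:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key in out:
                continue
            if b in seed_set and key[0] != a:
                continue  # the other seed will own this pair
            ib = index[b]
            if clean[ia] and clean[ib]:
                if norms[ia] == 0 or norms[ib] == 0:
                    flat = a if norms[ia] == 0 else b
                    if flat not in degenerate_warned:
                        degenerate_warned.add(flat)
                        warnings.warn(f"zero-variance gene {flat}: pairs skipped")
                    continue
                r = float(np.dot(centered[ia], centered[ib]) / (norms[ia] * norms[ib]))
            else:
                mask = finite[ia] & finite[ib]
                if mask.sum() < min_samples:
                    continue
                x, y = values[ia, mask], values[ib, mask]
                if np.std(x) == 0 or np.std(y) == 0:
                    warnings.warn(f"zero-variance pair ({a}, {b}) skipped")
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
            out[key] = max(-1.0, min(1.0, r))
    return out


def build_network(
    correlations: Mapping[tuple[str, str], float],
    cfg: NetworkConfig | None = None,
    seed_genes: Iterable[str] = (),
) -> nx.Graph:
    """Threshold a correlation map into an undirected co-expression network.

    Nodes carry ``is_seed``; edges carry ``r``.  Seed genes are always
    present as nodes even when isolated.
    """
    cfg = cfg or NetworkConfig()
    net = nx.Graph()
    seed_set = set(seed_genes)
    for g in sorted(seed_set):
        net.add_node(g, is_seed=True)
    for (a, b), r in correlations.items():
        passing = (abs(r) >= cfg.correlation_cutoff
                   if cfg.correlation_mode == "absolute"
                   else r >= cfg.correlation_cutoff)
        if passing:
            for g in (a, b):
                if g not in net:
                    net.add_node(g, is_seed=g in seed_set)
            net.add_edge(a, b, r=float(r))
    return net


def find_major_nodes(
    net: nx.Graph, cfg: NetworkConfig | None = None
) -> list[tuple[str, int]]:
    """Rank seed genes by degree and select hubs.

    Returns (gene, degree) pairs sorted by degree descending, ties broken
    lexicographically by gene id.  If the network has no seed annotations at
    all, every node is eligible.
    """
    cfg = cfg or NetworkConfig()
    if net.number_of_nodes() == 0:
        return []
    has_seeds = any(d.get("is_seed") for _, d in net.nodes(data=True))
    eligible = [
        n for n, d in net.nodes(data=True) if d.get("is_seed") or not has_seeds
    ]
    ranked = sorted(((g, net.degree(g)) for g in eligible),
                    key=lambda t: (-t[1], t[0]))
    if cfg.hub_rule == "top_k":
        return ranked[: cfg.hub_param]
    return [(g, d) for g, d in ranked if d >= cfg.hub_param]


# ---------------------------------------------------------------------------
# output


def edges_to_tsv(net: nx.Graph, path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tr"]
    for a, b, data in sorted(net.edges(data=True)):
        a, b = sorted((a, b))
        lines.append(f"{a}\t{b}\t{data['r']:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def network_to_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def hubs_to_tsv(hubs: Sequence[tuple[str, int]], path: str | Path) -> None:
    lines = ["gene_id\tdegree"]
    for g, d in hubs:
        lines.append(f"{g}\t{d}")
    Path(path).write_text("\n".join(lines) + "\n")
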