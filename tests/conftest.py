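"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by the most naive route
(per-window recounting, all-pairs interval checks, clique-based letter
grouping) so they stay independent of the implementation paths they verify.
"""

from __future__ import annotations

import numpy as np
import pytest

from csslpipe.introgression import GenomicWindow, SnpRecord, SnpSet

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr01,length=100000>
##contig=<ID=chr02,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1
"""


def write_vcf_text(path, body_lines):
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return path


def snpset(positions, chrom="chr01", genotype="hom", line_name="x"):
    """SnpSet with A->G SNPs at the given 1-based positions."""
    return SnpSet(
        [SnpRecord(chrom, p, "A", "G", genotype) for p in positions], line_name=line_name
    )


def brute_force_window_counts(positions, length, window, step):
    """O(n * w) recount: for each window, count SNPs it contains."""
    out = []
    start = 0
    while start < length:
        end = min(start + window, length)
        count = sum(1 for p in positions if start < p <= end)  # p is 1-based
        out.append((start, end, count))
        start += step
    return out


def brute_force_gene_hits(snp_positions_by_chrom, genes):
    """All-pairs interval containment, 1-based inclusive."""
    per_gene = {}
    hit = set()
    for g in genes:
        for p in snp_positions_by_chrom.get(g.chromosome, []):
            if g.start <= p <= g.end:
                per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
                hit.add((g.chromosome, p))
    return per_gene, len(hit)


_Q_MEMO: dict = {}


def oracle_duncan_partition(groups, alpha=0.05):
    """Letter partition by an independent route: pairwise Duncan decisions
    computed by direct enumeration of enclosing spans, then grouping as
    maximal cliques of the non-significant graph.

    Returns a set of frozensets of group indices (letter membership sets),
    which is comparable across letter-naming conventions.
    """
    import networkx as nx
    from scipy import stats as ss

    arrays = [np.asarray(g, float) for g in groups]
    k = len(arrays)
    all_values = np.concatenate(arrays)
    df = all_values.size - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
    n_h = k / sum(1.0 / a.size for a in arrays)
    order = sorted(range(k), key=lambda i: -arrays[i].mean())
    means = [arrays[i].mean() for i in order]

    def span_ns(i, j):
        span = j - i + 1
        key = (alpha, span, df)
        if key not in _Q_MEMO:
            _Q_MEMO[key] = ss.studentized_range.ppf((1 - alpha) ** (span - 1), span, df)
        return (means[i] - means[j]) <= _Q_MEMO[key] * np.sqrt(mse / n_h)

    ns = np.zeros((k, k), bool)
    for i in range(k):
        for j in range(i, k):
            # non-significant iff ANY enclosing span (including itself) is
            ns[i, j] = i == j or any(
                span_ns(i2, j2)
                for i2 in range(0, i + 1)
                for j2 in range(j, k)
            )
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if ns[i, j]:
                g.add_edge(i, j)
    cliques = {frozenset(order[i] for i in c) for c in nx.find_cliques(g)}
    return cliques


def partition_from_letters(grouping, labels):
    """Letter membership sets (as group indices) from a DmrtGrouping."""
    letters = grouping.letters
    used = sorted(set("".join(letters.values())))
    return {
        frozenset(i for i, lab in enumerate(labels) if ch in letters[lab])
        for ch in used
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
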