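"""Candidate prioritization: QTL intersection, homolog join, ranking.

Hub genes from the co-expression stage are intersected with marker-flanked
drought-tolerance QTL intervals, joined to a rice-to-Arabidopsis homolog
table, and ranked into the final candidate report.  Marker coordinates come
from a user-supplied marker map because published QTLs are usually defined
by flanking marker names, not assembly coordinates.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .introgression import GeneModel, IntrogressionSegment

RICE_ID = re.compile(r"^LOC_Os\d{2}g\d{5}$")
ARABIDOPSIS_ID = re.compile(r"^AT[1-5CM]G\d{5}$")


@dataclass(frozen=True)
class QtlInterval:
    """A marker-flanked QTL interval, 1-based inclusive."""

    qtl_id: str
    chromosome: str
    left_marker: str
    right_marker: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.qtl_id}: start > end")


def read_marker_map(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a marker map TSV (marker, chromosome, position)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df["marker"].duplicated().any():
        raise ValueError("duplicate marker names in marker map")
    out = {}
    for _, r in df.iterrows():
        pos = int(r["position"])
        if pos < 1:
            raise ValueError(f"marker {r['marker']}: position must be >= 1")
        out[str(r["marker"])] = (str(r["chromosome"]), pos)
    return out


def read_qtl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def resolve_qtl_intervals(
    qtl_defs: pd.DataFrame | Sequence[Mapping],
    markers: Mapping[str, tuple[str, int]],
) -> list[QtlInterval]:
    """Resolve marker-flanked QTL definitions into genomic intervals.

    Each definition needs qtl_id, left_marker, right_marker and optionally a
    source tag.  The interval spans [min, max] of the two marker positions
    (so marker order does not matter).  Missing markers, or flanking markers
    on different chromosomes, raise with the offending names.
    """
    if isinstance(qtl_defs, pd.DataFrame):
        qtl_defs = qtl_defs.to_dict("records")
    intervals = []
    for row in qtl_defs:
        for m in (row["left_marker"], row["right_marker"]):
            if m not in markers:
                raise ValueError(f"QTL {row['qtl_id']}: marker {m!r} not in marker map")
        (c1, p1) = markers[row["left_marker"]]
        (c2, p2) = markers[row["right_marker"]]
        if c1 != c2:
            raise ValueError(
                f"QTL {row['qtl_id']}: markers {row['left_marker']}/{row['right_marker']} "
                f"on different chromosomes ({c1} vs {c2})"
            )
        intervals.append(
            QtlInterval(
                str(row["qtl_id"]), c1, str(row["left_marker"]),
                str(row["right_marker"]), min(p1, p2), max(p1, p2),
                source=str(row.get("source", "")),
            )
        )
    return intervals


def genes_in_qtl(
    genes: Sequence[GeneModel], qtls: Sequence[QtlInterval]
) -> dict[str, list[str]]:
    """Map each gene to the QTLs its body overlaps (any overlap, inclusive
    bounds: a gene abutting a QTL boundary coordinate is a member)."""
    membership: dict[str, list[str]] = {}
    for g in genes:
        hits = [
            q.qtl_id
            for q in qtls
            if q.chromosome == g.chromosome and g.start <= q.end and g.end >= q.start
        ]
        if hits:
            membership[g.gene_id] = sorted(hits)
    return membership


# ---------------------------------------------------------------------------
# homologs


def load_homolog_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a rice-to-Arabidopsis homolog table.

    Without a path, the packaged table of the 18 candidate loci and their
    Arabidopsis homologs is used.  Malformed locus ids produce row-level
    warnings, not errors.
    """
    if path is None:
        source = resources.files("csslpipe.data").joinpath("rice_arabidopsis_homologs.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col, pattern in (("rice_locus_id", RICE_ID), ("arabidopsis_locus_id", ARABIDOPSIS_ID)):
        bad = df[~df[col].astype(str).str.match(pattern)][col].tolist()
        if bad:
            warnings.warn(f"malformed {col} values: {bad}")
    return df


def join_homologs(candidates: pd.DataFrame, homologs: pd.DataFrame) -> pd.DataFrame:
    """Left-join homolog annotation onto candidate rows by rice locus id.

    Every candidate is preserved; a rice gene with several Arabidopsis
    homologs expands into several rows; unmatched candidates keep empty
    homolog fields.
    """
    merged = candidates.merge(
        homologs, how="left", left_on="gene_id", right_on="rice_locus_id"
    )
    return merged.drop(columns=["rice_locus_id"])


# ---------------------------------------------------------------------------
# report


def build_candidate_report(
    hubs: Sequence[tuple[str, int]],
    segments: Sequence[IntrogressionSegment] = (),
    genes: Sequence[GeneModel] = (),
    qtl_membership: Mapping[str, Sequence[str]] | None = None,
    homologs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble per-candidate provenance rows from the pipeline stages."""
    qtl_membership = qtl_membership or {}
    gene_index = {g.gene_id: g for g in genes}
    rows = []
    for gene_id, degree in hubs:
        g = gene_index.get(gene_id)
        in_segment = False
        if g is not None:
            in_segment = any(
                s.chromosome == g.chromosome and g.start <= s.end and g.end >= s.start + 1
                for s in segments
            )
        rows.append(
            {
                "gene_id": gene_id,
                "hub_degree": int(degree),
                "in_segment": in_segment,
                "qtl_ids": ",".join(qtl_membership.get(gene_id, [])),
                "in_qtl": bool(qtl_membership.get(gene_id)),
            }
        )
    report = pd.DataFrame(
        rows, columns=["gene_id", "hub_degree", "in_segment", "qtl_ids", "in_qtl"]
    )
    if homologs is not None and len(report):
        report = join_homologs(report, homologs)
    return report


def rank_candidates(report: pd.DataFrame) -> pd.DataFrame:
    """Deterministically rank candidates.

    Lexicographic order: QTL members first, then hub degree descending, then
    gene id ascending.  Stable under any permutation of the input rows.
    """
    ordered = report.sort_values(
        by=["in_qtl", "hub_degree", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered.insert(0, "rank", range(1, len(ordered) + 1))
    return ordered


def report_to_tsv(report: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# ranked by: in_qtl desc, hub_degree desc, gene_id asc\n")
        report.to_csv(fh, sep="\t", index=False)


def report_to_json(report: pd.DataFrame, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict("records"), indent=2) + "\n")
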