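"""Introgression detection by differential-SNP density scanning.

A chromosome segment substitution line (CSSL) carries a donor segment in an
otherwise recurrent-parent background.  Against a common reference genome the
donor segment shows up as a run of SNPs present in the substitution line but
not in the recurrent parent.  This module finds those runs: it reads variant
calls, discards SNPs shared by both lines, counts the remaining differential
SNPs in fixed-width windows along each chromosome, flags windows whose count
exceeds a threshold, and merges flagged runs into candidate introgression
segments.  SNPs are also assigned to overlapping gene models so downstream
stages can work with gene lists.

Coordinates are 0-based half-open internally; user-facing tables (TSV/BED
output, VCF/GFF input) follow their formats' own conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One variant observation for a line against the reference.

    ``position`` is 1-based (VCF convention).  ``genotype`` is the call for
    this alternate allele: ``"hom"`` (all called alleles are this alt) or
    ``"het"`` (a subset are).
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    genotype: str = "hom"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


class SnpSet:
    """Position-sorted, unique collection of SNPs for one line.

    Uniqueness is on (chromosome, position, alt allele); adding a duplicate
    key with a conflicting genotype raises.
    """

    def __init__(self, records: Iterable[SnpRecord] = (), line_name: str = "") -> None:
        self.line_name = line_name
        by_chrom: dict[str, dict[tuple[int, str], SnpRecord]] = {}
        for rec in records:
            chrom = by_chrom.setdefault(rec.chromosome, {})
            key = (rec.position, rec.alt_allele)
            if key in chrom and chrom[key] != rec:
                raise ValueError(
                    f"conflicting records at {rec.chromosome}:{rec.position} "
                    f"alt={rec.alt_allele}"
                )
            chrom[key] = rec
        self._by_chrom: dict[str, list[SnpRecord]] = {
            c: sorted(d.values()) for c, d in sorted(by_chrom.items())
        }

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def by_chromosome(self, chromosome: str) -> list[SnpRecord]:
        return self._by_chrom.get(chromosome, [])

    def positions(self, chromosome: str) -> np.ndarray:
        """1-based positions on a chromosome, sorted (duplicates possible
        when one position has several alt alleles)."""
        return np.array([r.position for r in self.by_chromosome(chromosome)], dtype=np.int64)

    def __iter__(self):
        for recs in self._by_chrom.values():
            yield from recs

    def __len__(self) -> int:
        return sum(len(r) for r in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SnpSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __repr__(self) -> str:
        return f"SnpSet({self.line_name!r}, n={len(self)})"


@dataclass
class ScanConfig:
    """Window-scan parameters.

    The default matches the published procedure: differential SNPs counted in
    5,000 bp windows, a window flagged when it holds strictly more than 100.
    ``step`` defaults to the window size (non-overlapping tiles), which makes
    window counts conserve the per-chromosome SNP total; a smaller step gives
    a true sliding scan.
    """

    window_size: int = 5000
    step: int = 5000
    flag_threshold: int = 100

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step >= 1):
            raise ValueError("require window_size >= step >= 1")
        if self.flag_threshold < 0:
            raise ValueError("flag_threshold must be >= 0")


@dataclass(frozen=True)
class GenomicWindow:
    """One scan window; ``start``/``end`` are 0-based half-open."""

    chromosome: str
    start: int
    end: int
    snp_count: int
    flagged: bool


@dataclass(frozen=True)
class IntrogressionSegment:
    """A maximal run of flagged windows, merged.  0-based half-open."""

    chromosome: str
    start: int
    end: int
    total_snps: int = 0
    n_windows: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic footprint; ``start``/``end`` 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str | Path, line_name: str | None = None) -> SnpSet:
    """Read SNP records for one line from a VCF (v4.x, plain or bgzipped).

    Multi-allelic sites are split into one record per alternate allele; the
    per-alt genotype is ``hom`` when every called allele is that alt, ``het``
    otherwise (including alts listed but absent from the genotype, which are
    retained as ``het`` observations).  Indels (ref/alt longer than 1 bp) are
    skipped: this scan is about SNPs.
    """
    path = Path(path)
    records: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        name = line_name or (vcf.header.samples[0] if len(vcf.header.samples) else path.stem)
        n_seen = 0
        try:
            for rec in vcf:
                n_seen += 1
                if rec.alts is None:
                    continue
                gt: tuple | None = None
                if len(rec.samples):
                    gt = rec.samples[0].get("GT")
                for alt_index, alt in enumerate(rec.alts, start=1):
                    if alt is None or len(rec.ref) != 1 or len(alt) != 1 or alt == "*":
                        continue
                    genotype = "hom"
                    if gt is not None:
                        called = [a for a in gt if a is not None]
                        n_alt = sum(1 for a in called if a == alt_index)
                        genotype = "hom" if called and n_alt == len(called) else "het"
                    records.append(
                        SnpRecord(rec.chrom, rec.pos, rec.ref, alt, genotype)
                    )
        except (ValueError, OSError) as exc:  # pragma: no cover - malformed input
            raise VcfParseError(
                f"malformed VCF record in {path} near data line {n_seen + 1}: {exc}"
            ) from exc
    return SnpSet(records, line_name=name)


def chrom_lengths_from_vcf(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from the ``##contig`` header lines of a VCF."""
    with pysam.VariantFile(str(path)) as vcf:
        return {name: contig.length for name, contig in vcf.header.contigs.items()}


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) TSV of chromosome lengths."""
    lengths: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, length = line.split("\t")[:2]
        lengths[name] = int(length)
    return lengths


def read_genes_gff3(path: str | Path, featuretype: str = "gene") -> list[GeneModel]:
    """Load gene models from a GFF3 file (via an in-memory gffutils db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(featuretype):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    return sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED (>= 4 columns; BED is 0-based half-open)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5] if len(fields) > 5 else "+"
        genes.append(GeneModel(name, chrom, start + 1, end, strand))
    return sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))


# ---------------------------------------------------------------------------
# the scan


def differential_snps(
    line: SnpSet, parent: SnpSet, genotype_aware: bool = True
) -> SnpSet:
    """SNPs present in exactly one of the two lines (symmetric difference).

    Both call sets must be against the same reference; a position where the
    two sets disagree on the reference allele raises.  With
    ``genotype_aware=True`` (default) a site carried hom in one line and het
    in the other counts as differential — a substitution-line/parent
    comparison asks where the lines differ, not merely which alleles exist.
    """
    ref_at: dict[tuple[str, int], str] = {}
    for snp in list(line) + list(parent):
        key = (snp.chromosome, snp.position)
        if ref_at.setdefault(key, snp.ref_allele) != snp.ref_allele:
            raise ValueError(
                f"inconsistent reference allele at {key[0]}:{key[1]}; "
                "the two call sets are not against the same reference"
            )

    def keyset(s: SnpSet) -> dict[tuple, SnpRecord]:
        if genotype_aware:
            return {
                (r.chromosome, r.position, r.alt_allele, r.genotype): r for r in s
            }
        return {(r.chromosome, r.position, r.alt_allele): r for r in s}

    a, b = keyset(line), keyset(parent)
    # one record per differential locus: when the two lines disagree only on
    # genotype, the line's record represents the locus
    diff: dict[tuple[str, int, str], SnpRecord] = {}
    for k, rec in a.items():
        if k not in b:
            diff[(rec.chromosome, rec.position, rec.alt_allele)] = rec
    for k, rec in b.items():
        if k not in a:
            diff.setdefault((rec.chromosome, rec.position, rec.alt_allele), rec)
    return SnpSet(diff.values(), line_name=f"{line.line_name}~{parent.line_name}")


def window_scan(
    snps: SnpSet,
    chrom_lengths: Mapping[str, int],
    cfg: ScanConfig | None = None,
) -> list[GenomicWindow]:
    """Count SNPs in windows tiling each chromosome and flag dense ones.

    Windows start every ``cfg.step`` bp and span ``cfg.window_size`` bp
    (truncated at the chromosome end).  A SNP is counted in every window
    containing it, so with ``step == window_size`` the counts sum to the
    per-chromosome SNP total.  A window is flagged iff its count is strictly
    greater than ``cfg.flag_threshold``.
    """
    cfg = cfg or ScanConfig()
    missing = set(snps.chromosomes) - set(chrom_lengths)
    if missing:
        raise ValueError(f"no chromosome length given for: {sorted(missing)}")
    windows: list[GenomicWindow] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        pos0 = snps.positions(chrom) - 1  # 0-based
        if pos0.size and pos0.max() >= length:
            raise ValueError(
                f"SNP at {chrom}:{pos0.max() + 1} beyond chromosome length {length}"
            )
        starts = np.arange(0, length, cfg.step, dtype=np.int64)
        ends = np.minimum(starts + cfg.window_size, length)
        counts = np.searchsorted(pos0, ends, side="left") - np.searchsorted(
            pos0, starts, side="left"
        )
        for s, e, c in zip(starts, ends, counts):
            windows.append(
                GenomicWindow(chrom, int(s), int(e), int(c), bool(c > cfg.flag_threshold))
            )
    return windows


def merge_flagged(windows: Sequence[GenomicWindow]) -> list[IntrogressionSegment]:
    """Merge maximal runs of flagged windows into introgression segments.

    Adjacent (touching) or overlapping flagged windows on the same chromosome
    merge; segment bounds are the min start / max end of the run.  With an
    overlapping sliding scan a SNP may be counted by several merged windows,
    so ``total_snps`` is exact only for non-overlapping tiles.
    """
    flagged = sorted(
        (w for w in windows if w.flagged), key=lambda w: (w.chromosome, w.start)
    )
    segments: list[IntrogressionSegment] = []
    run: list[GenomicWindow] = []

    def close_run() -> None:
        if run:
            segments.append(
                IntrogressionSegment(
                    run[0].chromosome,
                    run[0].start,
                    max(w.end for w in run),
                    total_snps=sum(w.snp_count for w in run),
                    n_windows=len(run),
                )
            )

    for w in flagged:
        if run and w.chromosome == run[-1].chromosome and w.start <= max(x.end for x in run):
            run.append(w)
        else:
            close_run()
            run = [w]
    close_run()
    return segments


def snps_to_genes(
    snps: SnpSet, genes: Sequence[GeneModel]
) -> tuple[dict[str, int], dict[str, int]]:
    """Assign SNPs to gene bodies and summarize.

    A SNP is credited to every gene whose 1-based inclusive [start, end]
    interval contains its position (nested and overlapping genes each count
    it).  Returns ``(per_gene_counts, totals)`` where totals report
    ``n_snps`` — distinct SNPs falling in at least one gene — and
    ``n_genes_hit`` — distinct genes with at least one SNP.
    """
    per_gene: dict[str, int] = {}
    hit_snps = 0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        pos = snps.positions(chrom)
        if pos.size == 0:
            continue
        covered = np.zeros(pos.size, dtype=bool)
        for g in chrom_genes:
            lo = np.searchsorted(pos, g.start, side="left")
            hi = np.searchsorted(pos, g.end, side="right")
            if hi > lo:
                per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + int(hi - lo)
                covered[lo:hi] = True
        hit_snps += int(covered.sum())
    totals = {"n_snps": hit_snps, "n_genes_hit": len(per_gene)}
    return per_gene, totals


# ---------------------------------------------------------------------------
# output


def plot_chromosome_density(
    windows: Sequence[GenomicWindow],
    out_path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Render per-chromosome ideograms with flagged windows as vertical marks.

    Returns the flagged spans actually drawn, keyed by chromosome, so callers
    (and tests) can check the plotted coordinates against merged segments.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chroms = sorted({w.chromosome for w in windows})
    if chrom_lengths:
        chroms = sorted(set(chroms) | set(chrom_lengths))
    drawn: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.2 * n + 1), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        cw = [w for w in windows if w.chromosome == chrom]
        length = chrom_lengths[chrom] if chrom_lengths else (max((w.end for w in cw), default=1))
        ax.add_patch(
            plt.Rectangle((0, 0.3), length, 0.4, facecolor="0.85", edgecolor="0.4")
        )
        for w in cw:
            if w.flagged:
                ax.axvspan(w.start, w.end, ymin=0.25, ymax=0.75, color="tab:blue")
                drawn[chrom].append((w.start, w.end))
        ax.set_xlim(0, length)
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
    if chroms:
        axes.ravel()[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return drawn


def windows_to_tsv(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    """Write windows as TSV with 1-based inclusive coordinates."""
    lines = ["chromosome\tstart\tend\tsnp_count\tflagged"]
    for w in windows:
        lines.append(f"{w.chromosome}\t{w.start + 1}\t{w.end}\t{w.snp_count}\t{int(w.flagged)}")
    Path(path).write_text("\n".join(lines) + "\n")


def segments_to_bed(segments: Sequence[IntrogressionSegment], path: str | Path) -> None:
    """Write segments as BED (0-based half-open, BED's native convention)."""
    lines = [
        f"{s.chromosome}\t{s.start}\t{s.end}\tsegment_{i + 1}\t{s.total_snps}\t."
        for i, s in enumerate(segments)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def gene_hits_to_tsv(per_gene: Mapping[str, int], path: str | Path) -> None:
    lines = ["gene_id\tsnp_count"]
    for gene_id in sorted(per_gene):
        lines.append(f"{gene_id}\t{per_gene[gene_id]}")
    Path(path).write_text("\n".join(lines) + "\n")
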