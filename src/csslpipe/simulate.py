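"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator emulates one class of input the candidate-gene pipeline
consumes, with the planted signal returned alongside the data so recovery can
be quantified:

* differential SNP sets with Poisson-placed variants, denser inside planted
  introgressed segments;
* expression matrices with planted correlated gene modules (latent profile
  plus calibrated independent noise);
* genotype x treatment phenotype time series with multiplicative stress
  effects and lognormal replicate noise;
* small RGB plate images with an exact known green-pixel count;
* physiology summary tables with group means and replicate noise.

Generators are deterministic given their seed and write the standard formats
(VCF, GFF3, TSV, CSV, PNG) so the pipeline is exercised through its real
readers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .introgression import IntrogressionSegment, SnpRecord, SnpSet

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GenomeSimConfig:
    """Differential-SNP genome simulation.

    Rates are expected SNPs per bp.  ``true_segments`` are (chromosome,
    start, end) in 0-based half-open bp; they are the planted introgressions,
    where line-specific SNPs occur at ``segment_snp_rate`` instead of
    ``background_snp_rate``.  ``shared_snp_rate`` places identical SNPs in
    both lines (discarded by differential filtering downstream).
    """

    chrom_lengths: Mapping[str, int]
    background_snp_rate: float = 1e-4
    segment_snp_rate: float = 0.03
    true_segments: Sequence[tuple[str, int, int]] = ()
    shared_snp_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.background_snp_rate, self.segment_snp_rate, self.shared_snp_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.true_segments and self.segment_snp_rate <= self.background_snp_rate:
            raise ValueError("segment_snp_rate must exceed background_snp_rate")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.true_segments:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"segment on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"segment [{start}, {end}) outside {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping true segments on {chrom}")


def _sample_positions(rng: np.random.Generator, start: int, end: int,
                      rate: float, used: set[int]) -> list[int]:
    """Poisson count, unique 0-based positions by rejection against ``used``."""
    n = int(rng.poisson(rate * (end - start)))
    out: list[int] = []
    while len(out) < n:
        for p in rng.integers(start, end, size=n - len(out)):
            p = int(p)
            if p not in used:
                used.add(p)
                out.append(p)
    return out


def _random_snp(rng: np.random.Generator, chrom: str, pos0: int,
                genotype: str = "hom") -> SnpRecord:
    ref, alt = rng.choice(4, size=2, replace=False)
    return SnpRecord(chrom, pos0 + 1, str(_BASES[ref]), str(_BASES[alt]), genotype)


def gen_differential_snps(
    cfg: GenomeSimConfig,
) -> tuple[SnpSet, SnpSet, list[IntrogressionSegment]]:
    """Simulate call sets for a substitution line (A) and its recurrent
    parent (B) against a common reference.

    Shared SNPs appear identically in both sets.  Line-A-only SNPs are
    Poisson-placed at the background rate outside the planted segments and at
    the segment rate inside them.  Returns the two SnpSets plus the truth
    segments (coordinates from the config; ``total_snps`` is the realized
    line-A-only count inside each segment).
    """
    rng = np.random.default_rng(cfg.seed)
    a_records: list[SnpRecord] = []
    b_records: list[SnpRecord] = []
    truth: list[IntrogressionSegment] = []
    segs_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in cfg.true_segments:
        segs_by_chrom.setdefault(chrom, []).append((start, end))
    for chrom in sorted(cfg.chrom_lengths):
        length = cfg.chrom_lengths[chrom]
        used: set[int] = set()
        for pos0 in _sample_positions(rng, 0, length, cfg.shared_snp_rate, used):
            snp = _random_snp(rng, chrom, pos0)
            a_records.append(snp)
            b_records.append(snp)
        segs = sorted(segs_by_chrom.get(chrom, []))
        cursor = 0
        for seg_start, seg_end in segs:
            for pos0 in _sample_positions(rng, cursor, seg_start,
                                          cfg.background_snp_rate, used):
                a_records.append(_random_snp(rng, chrom, pos0))
            n_inside = 0
            for pos0 in _sample_positions(rng, seg_start, seg_end,
                                          cfg.segment_snp_rate, used):
                a_records.append(_random_snp(rng, chrom, pos0))
                n_inside += 1
            truth.append(IntrogressionSegment(chrom, seg_start, seg_end,
                                              total_snps=n_inside))
            cursor = seg_end
        for pos0 in _sample_positions(rng, cursor, length,
                                      cfg.background_snp_rate, used):
            a_records.append(_random_snp(rng, chrom, pos0))
    line_a = SnpSet(a_records, line_name="lineA")
    line_b = SnpSet(b_records, line_name="lineB")
    truth.sort(key=lambda s: (s.chromosome, s.start))
    return line_a, line_b, truth


def write_vcf(
    snps: SnpSet,
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    sample_name: str | None = None,
) -> None:
    """Write a SnpSet as an uncompressed VCF v4.2 with contig headers."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in sorted(chrom_lengths):
        header.contigs.add(chrom, length=chrom_lengths[chrom])
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_sample(sample_name or snps.line_name or "sample")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in snps:
            v = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                stop=rec.position,
                alleles=(rec.ref_allele, rec.alt_allele),
            )
            v.samples[0]["GT"] = (1, 1) if rec.genotype == "hom" else (0, 1)
            out.write(v)


def gen_gene_models(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    seed: int = 0,
    gene_length: int = 3000,
    id_prefix: str = "GENE",
) -> list:
    """Place non-overlapping fixed-length gene models uniformly over the
    genome (proportionally to chromosome length)."""
    from .introgression import GeneModel

    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n_genes, weights / weights.sum())
    genes = []
    i = 0
    for chrom, k in zip(chroms, counts):
        length = chrom_lengths[chrom]
        usable = length - gene_length
        if usable <= 0 or k == 0:
            continue
        slots = max(k, 1)
        starts = np.sort(rng.choice(usable // gene_length, size=min(k, usable // gene_length),
                                    replace=False)) * gene_length
        for s in starts:
            i += 1
            genes.append(GeneModel(f"{id_prefix}{i:05d}", chrom, int(s) + 1,
                                   int(s) + gene_length,
                                   "+" if rng.random() < 0.5 else "-"))
    return genes


def write_gff3(genes: Sequence, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chromosome}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimConfig:
    """Expression matrix with planted co-expressed modules.

    Each module is (member gene ids, target pairwise Pearson correlation).
    Members are generated as a shared latent profile plus independent
    Gaussian noise whose variance is calibrated analytically so the expected
    within-module pair correlation equals the target: for x_i = z + s*e_i
    with z, e_i ~ N(0,1), corr(x_i, x_j) = 1/(1+s^2), so s = sqrt(1/r - 1).
    ``noise_sd`` scales that calibrated noise (1 = on target, 0 = noiseless).
    Background genes are independent N(0,1) profiles.
    """

    n_genes: int = 200
    n_samples: int = 50
    modules: Sequence[tuple[Sequence[str], float]] = ()
    noise_sd: float = 1.0
    baseline: float = 8.0
    custom_gene_ids: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need n_samples >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.custom_gene_ids is not None:
            ids = list(self.custom_gene_ids)
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate gene ids")
            self.n_genes = len(ids)
        for members, target in self.modules:
            if not (0 < target <= 1):
                raise ValueError(f"correlation target {target} outside (0, 1]")

    def gene_ids(self) -> list[str]:
        if self.custom_gene_ids is not None:
            return list(self.custom_gene_ids)
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def gen_expression(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Generate a gene x sample expression matrix plus truth membership.

    Returns ``(matrix, truth)`` where truth maps ``"module_1"``... to member
    gene lists.  Raises if a module references an unknown gene id.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = cfg.gene_ids()
    known = set(gene_ids)
    values = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    index = {g: i for i, g in enumerate(gene_ids)}
    truth: dict[str, list[str]] = {}
    for m, (members, target) in enumerate(cfg.modules, start=1):
        members = list(members)
        unknown = [g for g in members if g not in known]
        if unknown:
            raise ValueError(f"module references unknown gene ids: {unknown}")
        latent = rng.standard_normal(cfg.n_samples)
        noise_scale = cfg.noise_sd * math.sqrt(1.0 / target - 1.0)
        for g in members:
            values[index[g]] = latent + noise_scale * rng.standard_normal(cfg.n_samples)
        truth[f"module_{m}"] = members
    samples = [f"S{j + 1:03d}" for j in range(cfg.n_samples)]
    matrix = pd.DataFrame(values + cfg.baseline, index=gene_ids, columns=samples)
    matrix.index.name = "gene_id"
    return matrix, truth


def expression_to_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# phenotypes


@dataclass
class PhenoSimConfig:
    """Plate-phenotyping time series with multiplicative stress effects.

    Log green area grows linearly: log A(t) = log(baseline) +
    growth_rate[genotype] * multiplier[genotype, treatment] * t, with
    lognormal multiplicative replicate noise of coefficient of variation
    ``replicate_cv``.  ``stress_multiplier`` maps (genotype, treatment) to a
    value in (0, 1]; the control multiplier is 1 by construction.  The
    default design mirrors a wild type plus seven mutant lines under
    control / mild / severe osmotic stress.
    """

    genotypes: Sequence[str] = ("WT", "mut1", "mut2", "mut3", "mut4", "mut5", "mut6", "mut7")
    wild_type: str = "WT"
    treatments: Sequence[str] = ("control", "mild", "severe")
    timepoints: Sequence[float] = (0, 1, 2, 3, 4, 5, 6, 7)
    baseline_area: float = 500.0
    growth_rate: Mapping[str, float] | float = 0.45
    stress_multiplier: Mapping[tuple[str, str], float] | None = None
    replicate_cv: float = 0.15
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.wild_type not in self.genotypes:
            raise ValueError("wild_type must be among genotypes")
        if self.baseline_area <= 0:
            raise ValueError("baseline_area must be positive")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")

    def rate_of(self, genotype: str) -> float:
        if isinstance(self.growth_rate, Mapping):
            return self.growth_rate[genotype]
        return float(self.growth_rate)

    def multiplier_of(self, genotype: str, treatment: str) -> float:
        if treatment == "control":
            return 1.0
        if self.stress_multiplier is None:
            return {"mild": 0.8, "severe": 0.6}.get(treatment, 1.0)
        m = self.stress_multiplier.get((genotype, treatment), 1.0)
        if not (0 < m <= 1):
            raise ValueError(f"multiplier for {genotype}/{treatment} outside (0, 1]")
        return m


def gen_phenotype_series(
    cfg: PhenoSimConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Simulate green-pixel series for every genotype x treatment x replicate.

    Returns a tidy DataFrame (genotype, treatment, replicate, timepoint,
    green_pixels) and the truth multipliers keyed genotype -> treatment.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log(1.0 + cfg.replicate_cv**2)) if cfg.replicate_cv > 0 else 0.0
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for genotype in cfg.genotypes:
        truth[genotype] = {}
        for treatment in cfg.treatments:
            mult = cfg.multiplier_of(genotype, treatment)
            truth[genotype][treatment] = mult
            rate = cfg.rate_of(genotype) * mult
            for rep in range(1, cfg.n_replicates + 1):
                for t in cfg.timepoints:
                    mean_log = math.log(cfg.baseline_area) + rate * float(t)
                    noise = sigma * rng.standard_normal() if sigma > 0 else 0.0
                    rows.append(
                        (genotype, treatment, rep, float(t),
                         math.exp(mean_log - 0.5 * sigma**2 + noise))
                    )
    df = pd.DataFrame(
        rows, columns=["genotype", "treatment", "replicate", "timepoint", "green_pixels"]
    )
    return df, truth


def phenotype_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def expected_stability_index(
    cfg: PhenoSimConfig, genotype: str, treatment: str, day: float
) -> float:
    """Noise-free stress/control area ratio implied by the growth model:
    exp(growth_rate * (multiplier - 1) * day)."""
    rate = cfg.rate_of(genotype)
    mult = cfg.multiplier_of(genotype, treatment)
    return math.exp(rate * (mult - 1.0) * day)


# ---------------------------------------------------------------------------
# plate images


def gen_rgb_plate(
    width: int,
    height: int,
    n_green_pixels: int,
    seed: int = 0,
    criterion=None,
) -> tuple[np.ndarray, int]:
    """An RGB image in which exactly ``n_green_pixels`` pixels satisfy the
    green criterion used by :func:`csslpipe.phenomics.count_green_pixels`.

    Plant pixels are saturated greens with slight channel jitter; background
    is neutral gray (zero saturation), which no green band accepts.
    """
    from .phenomics import GreenCriterion

    criterion = criterion or GreenCriterion()
    if n_green_pixels > width * height:
        raise ValueError("n_green_pixels exceeds image size")
    rng = np.random.default_rng(seed)
    gray = rng.integers(90, 150, size=(height, width, 1), dtype=np.uint8)
    img = np.repeat(gray, 3, axis=2)
    idx = rng.choice(width * height, size=n_green_pixels, replace=False)
    ys, xs = np.unravel_index(idx, (height, width))
    g = rng.integers(170, 230, size=n_green_pixels)
    r = rng.integers(10, 60, size=n_green_pixels)
    b = rng.integers(10, 60, size=n_green_pixels)
    img[ys, xs, 0] = r
    img[ys, xs, 1] = g
    img[ys, xs, 2] = b
    return img, n_green_pixels


def write_png(img: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(img, mode="RGB").save(str(path))


# ---------------------------------------------------------------------------
# physiology tables


def gen_physiology_replicates(
    summary: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Expand a summary table (line, condition, day, trait, mean, se, n) into
    tidy replicates with Gaussian noise matching each cell's SE * sqrt(n)."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in summary.iterrows():
        n = int(r["n"])
        sd = float(r["se"]) * math.sqrt(n)
        for rep in range(1, n + 1):
            rows.append(
                (r["line"], r["condition"], r["day"], r["trait"], rep,
                 float(r["mean"]) + sd * rng.standard_normal())
            )
    return pd.DataFrame(
        rows, columns=["line", "condition", "day", "trait", "replicate", "value"]
    )


def write_truth_json(truth, path: str | Path) -> None:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=default) + "\n")
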