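# csslpipe

Candidate-gene identification for chromosome segment substitution lines
(CSSLs), built around the analysis of a drought-tolerant rice line carrying a
donor segment from a tolerant parent (DH103) in the genetic background of the
elite but drought-susceptible cultivar KDML105.

A CSSL differs from its recurrent parent only in the introgressed donor
segment, so the genes behind its phenotype must lie where the two genomes
differ. `csslpipe` implements that reasoning as a reproducible pipeline:

1. **Introgression scan** — read variant calls of the substitution line and
   the recurrent parent against a common reference, discard shared SNPs, and
   count the remaining differential SNPs in 5,000 bp windows; windows holding
   more than 100 SNPs are flagged and merged into candidate introgression
   segments. SNPs are assigned to gene bodies to give the SNP-bearing gene
   set.
2. **Co-expression network** — Pearson correlations between SNP-bearing seed
   genes and all genes of an expression matrix; pairs with r ≥ 0.95 become
   edges, and the highest-degree seed genes ("major nodes") are the hub
   candidates.
3. **Prioritization** — hubs are intersected with marker-flanked
   drought-tolerance QTL intervals and joined to a rice→Arabidopsis homolog
   table; candidates are ranked (QTL membership, then hub degree, then id).
4. **Phenomics** — green pixel areas per plant over time under control /
   75 mM / 150 mM mannitol; Welch t-tests of each mutant against the wild
   type per timepoint (`*` p < 0.05, `**` p < 0.01), and the **stability
   index** — mean green area under stress divided by mean area under control
   for the same genotype, by default after six days of stress — with a
   delta-method standard error and Student-t confidence interval.
5. **Physiology statistics** — one-way ANOVA, Duncan's multiple range test
   with compact-letter display (the superscript letters of physiology
   tables), and the percent-change arithmetic behind headline statements
   such as "a nearly 70% reduction in photosynthesis rate". The critical
   range for a span of p ordered means is
   R_p = q(1 − (1 − α)^(p−1); p, df) · √(MSE/n_h), with q the studentized
   range quantile at Duncan's protection level.

A synthetic-data module generates every input the pipeline needs — genomes
with planted introgressions, expression matrices with planted correlated
modules, phenotype time series with known stress multipliers, plate images
with exact green-pixel counts — with the ground truth returned alongside, so
every stage is tested end to end without external downloads.

## Worked example

```python
from csslpipe import physiostats as ps, simulate as sim, introgression as intro

t = ps.load_physiology_table()          # packaged summary (mean, SE, n = 4)
pn = "net_photosynthesis"
for line in ("KDML105", "DH103", "CSSL104"):
    pc = ps.percent_change(ps.table_value(t, line, "normal", 6, pn),
                           ps.table_value(t, line, "stress", 6, pn))
    print(f"{line:8s} day-6 photosynthesis reduction: {pc.raw:5.1f}%")

print(ps.dmrt_letters_for_cell(t, "transpiration", "stress", 9).table)

lengths = {"chr01": 2_000_000}
cfg = sim.GenomeSimConfig(lengths, 1e-4, 0.03,
                          true_segments=[("chr01", 800_000, 1_300_000)], seed=7)
line_a, line_b, truth = sim.gen_differential_snps(cfg)
diff = intro.differential_snps(line_a, line_b)
segs = intro.merge_flagged(intro.window_scan(diff, lengths))
print(segs[0])
```

prints

```
KDML105  day-6 photosynthesis reduction:  69.1%
DH103    day-6 photosynthesis reduction:  46.1%
CSSL104  day-6 photosynthesis reduction:  44.2%
     group  mean  n letters
0    DH103  3.33  4       a
1  CSSL104  2.16  4       b
2  KDML105  1.87  4       b
IntrogressionSegment(chromosome='chr01', start=800000, end=1300000,
                     total_snps=14905, n_windows=100)
```

The susceptible parent loses about 69% of its photosynthesis rate after six
days of stress while the tolerant parent and the substitution line lose only
~46% and ~44%; Duncan letters separate the tolerant parent (a) from the
other two lines (b) for transpiration at day 9 under stress; and the window
scan recovers a planted 0.5 Mb introgression exactly.

## Command line

```bash
csslpipe simulate --out demo --seed 1        # synthetic input bundle + truth
csslpipe scan --line demo/line.vcf --parent demo/parent.vcf \
              --genes demo/genes.gff3 --out demo/out
csslpipe network --expr demo/expression.tsv --cutoff 0.95 \
                 --hub-rule degree_min --hub-param 5 --out demo/out
csslpipe pheno --input demo/phenotype.csv --wt WT --day 6 --out demo/out
csslpipe physio --out demo/out               # packaged physiology table
csslpipe run --config cfg.yaml               # full pipeline from one config
```

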