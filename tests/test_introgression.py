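"""Unit tests for the differential-SNP scan."""

import numpy as np
import pytest

from csslpipe.introgression import (
    GeneModel,
    GenomicWindow,
    ScanConfig,
    SnpRecord,
    SnpSet,
    differential_snps,
    merge_flagged,
    plot_chromosome_density,
    read_vcf,
    snps_to_genes,
    window_scan,
)

from conftest import (
    brute_force_gene_hits,
    brute_force_window_counts,
    snpset,
    write_vcf_text,
)


class TestReadVcf:
    def test_empty_body(self, tmp_path):
        path = write_vcf_text(tmp_path / "empty.vcf", [])
        assert len(read_vcf(path)) == 0

    def test_three_records_sorted(self, tmp_path):
        body = [
            "chr01\t500\t.\tA\tG\t.\tPASS\t.\tGT\t1/1",
            "chr01\t100\t.\tC\tT\t.\tPASS\t.\tGT\t0/1",
            "chr02\t50\t.\tG\tA\t.\tPASS\t.\tGT\t1/1",
        ]
        snps = read_vcf(write_vcf_text(tmp_path / "a.vcf", body))
        assert len(snps) == 3
        assert [r.position for r in snps.by_chromosome("chr01")] == [100, 500]
        assert snps.by_chromosome("chr01")[0].genotype == "het"

    def test_multiallelic_split(self, tmp_path):
        body = ["chr01\t200\t.\tA\tC,T\t.\tPASS\t.\tGT\t1/2"]
        snps = read_vcf(write_vcf_text(tmp_path / "m.vcf", body))
        recs = snps.by_chromosome("chr01")
        assert len(recs) == 2
        assert {r.alt_allele for r in recs} == {"C", "T"}
        assert all(r.genotype == "het" for r in recs)

    def test_indels_skipped(self, tmp_path):
        body = ["chr01\t10\t.\tAT\tA\t.\tPASS\t.\tGT\t1/1",
                "chr01\t20\t.\tA\tG\t.\tPASS\t.\tGT\t1/1"]
        snps = read_vcf(write_vcf_text(tmp_path / "i.vcf", body))
        assert [r.position for r in snps] == [20]


class TestSnpSetInvariants:
    def test_record_validation(self):
        with pytest.raises(ValueError):
            SnpRecord("chr01", 0, "A", "G")
        with pytest.raises(ValueError):
            SnpRecord("chr01", 5, "A", "A")

    def test_duplicate_key_conflict(self):
        recs = [SnpRecord("chr01", 5, "A", "G", "hom"),
                SnpRecord("chr01", 5, "A", "G", "het")]
        with pytest.raises(ValueError, match="conflicting"):
            SnpSet(recs)


class TestDifferentialSnps:
    def test_identical_sets_empty(self):
        a = snpset([10, 20, 30])
        assert len(differential_snps(a, snpset([10, 20, 30]))) == 0

    def test_symmetric_difference(self):
        diff = differential_snps(snpset([10, 20]), snpset([20, 30]))
        assert sorted(r.position for r in diff) == [10, 30]

    def test_genotype_aware_keeps_hom_vs_het(self):
        line = snpset([100], genotype="hom")
        parent = snpset([100], genotype="het")
        diff = differential_snps(line, parent)
        assert [r.position for r in diff] == [100]  # retained as one locus
        assert len(differential_snps(line, parent, genotype_aware=False)) == 0

    def test_inconsistent_reference_raises(self):
        a = SnpSet([SnpRecord("chr01", 10, "A", "G")])
        b = SnpSet([SnpRecord("chr01", 10, "C", "G")])
        with pytest.raises(ValueError, match="reference"):
            differential_snps(a, b)

    def test_symmetry(self, rng):
        pos_a = sorted(rng.choice(10000, 50, replace=False) + 1)
        pos_b = sorted(rng.choice(10000, 50, replace=False) + 1)
        d1 = differential_snps(snpset(pos_a), snpset(pos_b))
        d2 = differential_snps(snpset(pos_b), snpset(pos_a))
        assert sorted(r.position for r in d1) == sorted(r.position for r in d2)


class TestWindowScan:
    def test_no_snps_all_zero(self):
        windows = window_scan(SnpSet([]), {"chr01": 20000}, ScanConfig())
        assert len(windows) == 4
        assert all(w.snp_count == 0 and not w.flagged for w in windows)

    def test_flag_threshold_strictly_greater(self):
        cfg = ScanConfig(5000, 5000, 100)
        w101 = window_scan(snpset(range(1, 102)), {"chr01": 5000}, cfg)
        w100 = window_scan(snpset(range(1, 101)), {"chr01": 5000}, cfg)
        assert w101[0].flagged and w101[0].snp_count == 101
        assert not w100[0].flagged and w100[0].snp_count == 100

    def test_counts_conserve_when_tiled(self, rng):
        positions = sorted(rng.choice(50000, 500, replace=False) + 1)
        windows = window_scan(snpset(positions), {"chr01": 50000}, ScanConfig())
        assert sum(w.snp_count for w in windows) == 500

    @pytest.mark.parametrize("step,window", [(1000, 5000), (2500, 5000), (5000, 5000)])
    def test_matches_brute_force(self, rng, step, window):
        for _ in range(20):
            n = int(rng.integers(0, 300))
            positions = sorted(rng.choice(30000, n, replace=False) + 1)
            got = window_scan(snpset(positions), {"chr01": 30000},
                              ScanConfig(window, step, 10))
            expected = brute_force_window_counts(positions, 30000, window, step)
            assert [(w.start, w.end, w.snp_count) for w in got] == expected

    def test_snp_beyond_length_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            window_scan(snpset([6000]), {"chr01": 5000}, ScanConfig())


class TestMergeFlagged:
    def windows(self, flags, width=5000, chrom="chr01"):
        return [
            GenomicWindow(chrom, i * width, (i + 1) * width, 200 if f else 0, f)
            for i, f in enumerate(flags)
        ]

    def test_no_flags_empty(self):
        assert merge_flagged(self.windows([False, False])) == []

    def test_adjacent_windows_merge(self):
        segs = merge_flagged(self.windows([True, True]))
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].n_windows) == (0, 10000, 2)

    def test_run_count_matches_run_length_oracle(self, rng):
        for _ in range(20):
            flags = list(rng.random(30) < 0.4)
            segs = merge_flagged(self.windows(flags))
            runs = sum(
                1 for i, f in enumerate(flags) if f and (i == 0 or not flags[i - 1])
            )
            assert len(segs) == runs


class TestSnpsToGenes:
    def test_no_genes(self):
        per_gene, totals = snps_to_genes(snpset([10, 20]), [])
        assert per_gene == {} and totals == {"n_snps": 0, "n_genes_hit": 0}

    def test_boundary_inclusion(self):
        genes = [GeneModel("g1", "chr01", 100, 200)]
        per_gene, totals = snps_to_genes(snpset([100, 200, 201]), genes)
        assert per_gene == {"g1": 2}
        assert totals == {"n_snps": 2, "n_genes_hit": 1}

    def test_nested_genes_share_snp(self):
        genes = [GeneModel("outer", "chr01", 50, 500),
                 GeneModel("inner", "chr01", 100, 200)]
        per_gene, totals = snps_to_genes(snpset([150]), genes)
        assert per_gene == {"outer": 1, "inner": 1}
        assert totals["n_snps"] == 1  # counted once despite two gene credits

    def test_matches_brute_force(self, rng):
        positions = sorted(rng.choice(100000, 400, replace=False) + 1)
        genes = []
        for i in range(50):
            start = int(rng.integers(1, 95000))
            genes.append(GeneModel(f"g{i}", "chr01", start, start + int(rng.integers(100, 8000))))
        per_gene, totals = snps_to_genes(snpset(positions), genes)
        exp_genes, exp_hits = brute_force_gene_hits({"chr01": positions}, genes)
        assert per_gene == exp_genes
        assert totals["n_snps"] == exp_hits


class TestPlot:
    def test_smoke_and_coordinates(self, tmp_path, rng):
        positions = list(range(10001, 10200)) + [40000]
        windows = window_scan(snpset(positions), {"chr01": 50000, "chr02": 50000},
                              ScanConfig(5000, 5000, 100))
        out = tmp_path / "density.png"
        drawn = plot_chromosome_density(windows, out, {"chr01": 50000, "chr02": 50000})
        assert out.exists() and out.stat().st_size > 0
        flagged = [(w.start, w.end) for w in windows if w.flagged]
        assert drawn["chr01"] == flagged
        assert drawn["chr02"] == []
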