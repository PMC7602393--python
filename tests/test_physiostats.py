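"""Unit tests for ANOVA, Duncan's multiple range test and percent arithmetic."""

import numpy as np
import pytest
from scipy import stats

from csslpipe.physiostats import (
    anova_oneway,
    dmrt,
    dmrt_from_summary,
    dmrt_letters_for_cell,
    duncan_critical_range,
    load_physiology_table,
    percent_change,
    percent_difference,
    replicates_from_summary,
    table_extrema,
)

from conftest import oracle_duncan_partition, partition_from_letters


class TestAnova:
    def test_identical_groups(self):
        res = anova_oneway([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_hand_decomposition(self):
        res = anova_oneway([[1.0, 2, 3], [4.0, 5, 6]])
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.f_statistic == pytest.approx(13.5)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc, 1.0, size=4) for loc in (0.0, 0.5, 1.5)]
        res = anova_oneway(groups)
        f, p = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(f, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestDmrt:
    def test_identical_groups_share_a(self):
        g = dmrt([[5.0, 5.1, 4.9], [5.0, 5.1, 4.9], [5.0, 5.1, 4.9]],
                 labels=["x", "y", "z"])
        assert set(g.letters.values()) == {"a"}

    def test_well_separated_all_distinct(self, rng):
        groups = [rng.normal(m, 0.1, 4) for m in (0.0, 10.0, 20.0)]
        g = dmrt(groups, labels=["lo", "mid", "hi"])
        assert g.letters["hi"] == "a"
        assert g.letters["mid"] == "b"
        assert g.letters["lo"] == "c"

    def test_letters_follow_sorted_means(self, rng):
        groups = [rng.normal(m, 1.0, 5) for m in (3.0, 0.0, 6.0, 1.0)]
        g = dmrt(groups)
        assert g.table["mean"].is_monotonic_decreasing
        assert g.table["letters"].iloc[0].startswith("a")

    def test_letter_consistency_invariant(self, rng):
        # groups sharing a letter must have gap <= their span's range
        for _ in range(10):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 4), 1.0, int(rng.integers(3, 7)))
                      for _ in range(k)]
            g = dmrt(groups)
            means = g.table["mean"].to_numpy()
            letters = g.table["letters"].tolist()
            for i in range(k):
                for j in range(i + 1, k):
                    if set(letters[i]) & set(letters[j]):
                        span = j - i + 1
                        r_p = duncan_critical_range(
                            g.alpha, span, g.df_within, g.n_harmonic, g.mse)
                        # containment can only widen acceptance; the direct
                        # range bound applies to the largest enclosing span
                        r_max = duncan_critical_range(
                            g.alpha, k, g.df_within, g.n_harmonic, g.mse)
                        assert means[i] - means[j] <= max(r_p, r_max)

    def test_matches_clique_oracle(self, rng):
        for _ in range(15):
            k = int(rng.integers(3, 6))
            groups = [list(rng.normal(rng.uniform(0, 5), 1.0, 4)) for _ in range(k)]
            labels = [f"g{i}" for i in range(k)]
            got = partition_from_letters(dmrt(groups, labels=labels), labels)
            assert got == oracle_duncan_partition(groups)

    def test_summary_agrees_with_replicates(self):
        means, ses, ns = [10.0, 12.5, 8.0], [0.4, 0.5, 0.6], [4, 4, 4]
        reps = [replicates_from_summary(m, s, n) for m, s, n in zip(means, ses, ns)]
        labels = ["a1", "a2", "a3"]
        from_reps = dmrt(reps, labels=labels)
        from_summary = dmrt_from_summary(means, ses, ns, labels=labels)
        assert from_reps.letters == from_summary.letters
        assert from_reps.mse == pytest.approx(from_summary.mse, rel=1e-12)

    def test_published_transpiration_cell_separates_lines(self):
        """Day-9 stress transpiration: the drought-tolerant donor line must
        receive a letter distinct from the recurrent parent."""
        table = load_physiology_table()
        g = dmrt_letters_for_cell(table, "transpiration", "stress", 9)
        assert not g.share_letter("DH103", "KDML105")
        assert g.letters["DH103"] == "a"
        # replicate-level route agrees
        cells = table[(table.trait == "transpiration") & (table.condition == "stress")
                      & (table.day == 9)]
        reps = [replicates_from_summary(r["mean"], r["se"], int(r["n"]))
                for _, r in cells.iterrows()]
        g2 = dmrt(reps, labels=cells["line"].tolist())
        assert g2.letters == g.letters

    def test_duncan_never_wider_than_tukey(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 6))
            n = int(rng.integers(3, 8))
            df = k * (n - 1)
            mse = float(rng.uniform(0.2, 4.0))
            tukey = stats.studentized_range.ppf(0.95, k, df) * np.sqrt(mse / n)
            for span in range(2, k + 1):
                assert duncan_critical_range(0.05, span, df, n, mse) <= tukey + 1e-12


class TestReplicateReconstruction:
    @pytest.mark.parametrize("n", [2, 3, 4, 7])
    def test_exact_mean_and_se(self, n):
        reps = replicates_from_summary(3.7, 0.42, n)
        assert reps.mean() == pytest.approx(3.7, abs=1e-12)
        assert reps.std(ddof=1) / np.sqrt(n) == pytest.approx(0.42, abs=1e-12)


class TestPercentArithmetic:
    def test_photosynthesis_reductions(self):
        assert percent_change(17.85, 5.51).raw == pytest.approx(69.13, abs=0.01)
        assert percent_change(18.92, 10.20).rounded == 46
        assert percent_change(18.47, 10.31).rounded == 44

    def test_conductance_differences(self):
        assert percent_difference(0.19, 0.08).rounded == 58
        assert percent_difference(0.19, 0.11).rounded == 42

    def test_trivial_and_errors(self):
        assert percent_change(3.3, 3.3).raw == 0.0
        assert percent_difference(7.0, 7.0).raw == 0.0
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)

    def test_rescaling_invariance(self):
        a = percent_change(18.92, 10.20).raw
        b = percent_change(1892.0, 1020.0).raw
        assert a == pytest.approx(b, abs=1e-12)

    def test_sign_convention_antisymmetry(self):
        down = percent_difference(0.19, 0.08).raw
        up = percent_difference(0.08, 0.19).raw
        assert down > 0 > up

    def test_round_half_away_from_zero(self):
        assert percent_change(200.0, 99.0).rounded == 51  # 50.5 rounds away
        assert percent_change(99.0, 200.0).rounded == -102


class TestTableExtrema:
    def test_day9_stress_lwp_minimum(self):
        table = load_physiology_table()
        lines, value = table_extrema(table, "leaf_water_potential", "stress", 9, "min")
        assert lines == ["CSSL104"] and value == pytest.approx(-7.75)

    def test_tie_returns_both(self):
        import pandas as pd

        table = pd.DataFrame(
            {"line": ["A", "B"], "condition": ["normal"] * 2, "day": [6, 6],
             "trait": ["x", "x"], "mean": [2.0, 2.0], "se": [0.1, 0.1], "n": [4, 4]})
        lines, value = table_extrema(table, "x", "normal", 6, "max")
        assert lines == ["A", "B"] and value == 2.0

    def test_missing_cell_named(self):
        table = load_physiology_table()
        cell_mask = ((table["line"] == "DH103") & (table["trait"] == "transpiration")
                     & (table["condition"] == "stress") & (table["day"] == 9))
        partial = table[~cell_mask]
        with pytest.raises(ValueError, match="DH103"):
            table_extrema(partial, "transpiration", "stress", 9)
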