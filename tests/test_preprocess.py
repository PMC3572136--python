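"""Normalization, ternary calls, TSS-window RPKM, correlations, peak overlap."""

import numpy as np
import pandas as pd
import pytest

from cretools.errors import (
    ContractViolation,
    InsufficientReplication,
    UndefinedFraction,
)
from cretools.preprocess import (
    PeakSet,
    TimecourseMatrix,
    background_level,
    correlation_matrix,
    detection_filter,
    differential_calls,
    normalize,
    peak_overlap_fraction,
    per_gene_correlation,
    quantile_normalize,
    rpkm_from_counts,
    tss_window_rpkm,
)

from helpers_oracles import overlap_fraction_bruteforce, window_count_bruteforce


def make_tm(values, timepoints, n_reps, features=None):
    values = np.asarray(values, dtype=float)
    cols = pd.MultiIndex.from_product(
        [timepoints, list("ABCDEFGH")[:n_reps]], names=["timepoint", "replicate"]
    )
    features = features or [f"g{i}" for i in range(values.shape[0])]
    return TimecourseMatrix(pd.DataFrame(values, index=features, columns=cols))


class TestQuantileNormalization:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_permuted_columns_get_identical_sorted_profiles(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        df = pd.DataFrame({"a": col, "b": rng.permutation(col), "c": rng.permutation(col)})
        out = quantile_normalize(df)
        for c in out.columns[1:]:
            assert np.allclose(np.sort(out["a"]), np.sort(out[c]))

    def test_hand_computed_rank_means(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 9.0, 5.0]})
        out = quantile_normalize(df)
        # rank-mean profile: [(2+1)/2, (4+5)/2, (6+9)/2] = [1.5, 4.5, 7.5]
        assert np.allclose(out["a"], [1.5, 4.5, 7.5])
        assert np.allclose(out["b"], [1.5, 7.5, 4.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_normalize_rejects_non_positive_without_offset(self):
        df = pd.DataFrame({"D0_A": [1.0, 0.0], "D0_B": [2.0, 3.0]})
        with pytest.raises(ValueError):
            normalize(df)
        tm = normalize(df, offset=1.0)
        assert tm.values.shape == (2, 2)


class TestDetectionFilter:
    def test_threshold_boundaries(self, toy_matrix):
        flags = pd.DataFrame(
            True, index=toy_matrix.features, columns=toy_matrix.values.columns
        )
        flags.iloc[0, :] = False
        flags.iloc[0, :2] = True  # detected in 2 samples -> dropped
        flags.iloc[1, :] = False
        flags.iloc[1, :3] = True  # detected in 3 -> retained
        filtered, removed = detection_filter(toy_matrix, flags, min_samples=3)
        assert list(removed) == ["g0"]
        assert "g1" in filtered.features

    def test_all_detected_is_identity(self, toy_matrix):
        flags = pd.DataFrame(
            True, index=toy_matrix.features, columns=toy_matrix.values.columns
        )
        filtered, removed = detection_filter(toy_matrix, flags)
        assert len(removed) == 0
        assert filtered.values.equals(toy_matrix.values)

    def test_misaligned_flags_rejected(self, toy_matrix):
        flags = pd.DataFrame(
            True, index=list(toy_matrix.features)[:-1],
            columns=toy_matrix.values.columns,
        )
        with pytest.raises(ContractViolation):
            detection_filter(toy_matrix, flags)


class TestDifferentialCalls:
    def base_matrix(self, lfc, sd=0.01, n_reps=3):
        rng = np.random.default_rng(1)
        base = np.full((1, n_reps), 8.0) + rng.normal(0, sd, (1, n_reps))
        shifted = base + lfc
        return make_tm(np.hstack([base, shifted]), ["D8", "D11"], n_reps)

    def test_headline_rule_applied(self):
        tm = self.base_matrix(1.2)
        table, obs = differential_calls(tm, ("D8", "D11"), preset="headline")
        assert obs.calls["g0"] == 1

    def test_fold_change_gate_blocks_significant_feature(self):
        tm = self.base_matrix(0.9)
        table, _ = differential_calls(tm, ("D8", "D11"), preset="headline")
        assert table.loc["g0", "adj_p"] < 0.01  # highly significant...
        assert table.loc["g0", "call"] == 0  # ...but below the 2-fold gate

    def test_toptable_uses_raw_p_and_lower_fold_gate(self):
        tm = self.base_matrix(0.8)
        table, obs = differential_calls(tm, ("D8", "D11"), preset="toptable")
        assert obs.calls["g0"] == 1

    def test_null_false_call_rate_at_raw_p(self):
        rng = np.random.default_rng(42)
        tm = make_tm(rng.normal(8, 0.5, size=(1000, 6)), ["D8", "D11"], 3)
        table, _ = differential_calls(tm, ("D8", "D11"), preset="toptable")
        # Welch t on 3v3: raw p < 0.01 should fire at roughly its nominal rate
        assert (table["p"] < 0.01).mean() <= 0.02

    def test_insufficient_replicates(self):
        tm = make_tm([[8.0, 9.0]], ["D8", "D11"], 1)
        with pytest.raises(InsufficientReplication):
            differential_calls(tm, ("D8", "D11"))

    def test_unknown_timepoint(self, toy_matrix):
        with pytest.raises(ContractViolation):
            differential_calls(toy_matrix, ("D8", "D99"))


class TestRpkm:
    def test_arithmetic_from_definition(self):
        # 50 reads fully inside a 5 kb window, 10 M mapped -> RPKM 1.0
        tss = pd.DataFrame({"chrom": ["chr1"], "start": [10000], "end": [10001],
                            "name": ["geneA"]})
        reads = pd.DataFrame({
            "chrom": ["chr1"] * 50,
            "start": np.linspace(8000, 12000, 50).astype(int),
        })
        reads["end"] = reads["start"] + 36
        rpkm = tss_window_rpkm(reads, tss, total_mapped=10_000_000)
        assert rpkm["geneA"] == pytest.approx(1.0)

    def test_no_reads_gives_zero(self):
        tss = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [5001],
                            "name": ["g"]})
        reads = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [36]})
        assert tss_window_rpkm(reads, tss, total_mapped=100)["g"] == 0.0

    def test_linearity_in_reads_and_total(self):
        tss = pd.DataFrame({"chrom": ["c"], "start": [5000], "end": [5001], "name": ["g"]})
        reads = pd.DataFrame({"chrom": ["c"] * 20, "start": [4000] * 20})
        reads["end"] = reads["start"] + 30
        r1 = tss_window_rpkm(reads, tss, total_mapped=1_000_000)["g"]
        r2 = tss_window_rpkm(pd.concat([reads, reads]), tss, total_mapped=1_000_000)["g"]
        r3 = tss_window_rpkm(reads, tss, total_mapped=2_000_000)["g"]
        assert r2 == pytest.approx(2 * r1)
        assert r3 == pytest.approx(r1 / 2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_read_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_reads = 200
        starts = rng.integers(0, 50_000, n_reads)
        reads = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 36})
        tss = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(3000, 47_000, 5),
            "name": [f"g{i}" for i in range(5)],
        })
        tss["end"] = tss["start"] + 1
        rpkm = tss_window_rpkm(reads, tss, window_bp=5000, total_mapped=n_reads)
        pairs = list(zip(reads["start"], reads["end"]))
        for _, row in tss.iterrows():
            lo, hi = max(0, row["start"] - 2500), row["start"] + 2500
            expected = window_count_bruteforce(pairs, lo, hi) / 5.0 / (n_reads / 1e6)
            assert rpkm[row["name"]] == pytest.approx(expected)

    def test_counts_table_conversion_and_background(self):
        counts = pd.DataFrame({"D0": [50, 10], "CTRL": [5, 5]}, index=["g1", "g2"])
        rpkm = rpkm_from_counts(counts, total_mapped={"D0": 10_000_000, "CTRL": 1_000_000})
        assert rpkm.loc["g1", "D0"] == pytest.approx(1.0)
        assert background_level(rpkm["CTRL"]) == pytest.approx(1.0)
        with pytest.raises(UndefinedFraction):
            background_level([])


class TestCorrelations:
    def test_self_levels_has_unit_diagonal(self, toy_matrix):
        m = correlation_matrix(toy_matrix, toy_matrix, mode="levels")
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)

    def test_negated_layer_gives_minus_one(self, toy_matrix):
        neg = TimecourseMatrix(-toy_matrix.values, layer="h3k4me3")
        m = correlation_matrix(toy_matrix, neg, mode="levels")
        assert np.allclose(np.diag(m.values), -1.0)

    def test_changes_mode_hand_case(self):
        x = make_tm([[0, 1, 3], [2, 0, 1], [5, 4, 6], [1, 3, 2]], ["T0", "T1", "T2"], 1)
        m = correlation_matrix(x, x, mode="changes")
        assert list(m.columns) == ["T0-T1", "T1-T2"]
        # hand Pearson between interval-change vectors
        d01 = np.array([1, -2, -1, 2])
        d12 = np.array([2, 1, 2, -1])
        expected = np.corrcoef(d01, d12)[0, 1]
        assert m.loc["T0-T1", "T1-T2"] == pytest.approx(expected)
        assert m.loc["T0-T1", "T0-T1"] == pytest.approx(1.0)

    def test_too_few_shared_features_rejected(self):
        x = make_tm([[1, 2, 3]], ["T0", "T1", "T2"], 1, features=["a"])
        y = make_tm([[1, 2, 3]], ["T0", "T1", "T2"], 1, features=["b"])
        with pytest.raises(ContractViolation):
            correlation_matrix(x, y)

    def test_per_gene_identical_profiles_give_one(self, toy_matrix):
        r = per_gene_correlation(toy_matrix, toy_matrix)
        assert np.allclose(r.values, 1.0)

    def test_per_gene_constant_track_is_nan(self):
        x = make_tm([[1, 2, 3], [1, 2, 3]], ["T0", "T1", "T2"], 1)
        y = make_tm([[5, 5, 5], [0, 2, 4]], ["T0", "T1", "T2"], 1)
        r = per_gene_correlation(x, y)
        assert np.isnan(r["g0"])
        assert r["g1"] == pytest.approx(1.0)


class TestPeakOverlap:
    def test_small_example(self):
        a = PeakSet(pd.DataFrame({"chrom": ["c", "c"], "start": [0, 200], "end": [100, 300]}))
        b = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [50], "end": [60]}))
        assert peak_overlap_fraction(a, b) == 0.5

    def test_full_containment_gives_one(self):
        a = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [10], "end": [20]}))
        b = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]}))
        assert peak_overlap_fraction(a, b) == 1.0

    def test_asymmetry(self):
        a = PeakSet(pd.DataFrame({"chrom": ["c", "c"], "start": [0, 50], "end": [10, 60]}))
        b = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]}))
        assert peak_overlap_fraction(a, b) == 0.5
        assert peak_overlap_fraction(b, a) == 1.0

    def test_empty_query_rejected(self):
        b = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1]}))
        empty = PeakSet(pd.DataFrame({"chrom": [], "start": [], "end": []}))
        with pytest.raises(UndefinedFraction):
            peak_overlap_fraction(empty, b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            PeakSet(pd.DataFrame({"chrom": ["c"], "start": [5], "end": [5]}))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_scan(self, seed):
        rng = np.random.default_rng(seed)

        def random_set(n):
            chroms = rng.choice(["chr1", "chr2"], size=n)
            starts = rng.integers(0, 10_000, n)
            lens = rng.integers(1, 500, n)
            return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lens})

        a, b = PeakSet(random_set(40)), PeakSet(random_set(30))
        expected = overlap_fraction_bruteforce(
            list(a.intervals.itertuples(index=False, name=None)),
            list(b.intervals.itertuples(index=False, name=None)),
        )
        assert peak_overlap_fraction(a, b) == pytest.approx(expected)
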