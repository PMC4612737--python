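"""Differential testing: Fisher exactness, permutation FDR, detection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcompare.dmr import (
    cdmr_detection,
    cdmr_probe_coverage,
    filter_constant_loci,
    fisher_p,
    fisher_tests,
    min_detection_count,
    permutation_fdr,
    permutation_null,
)
from methylcompare.io import IntervalSet, ProbeManifest, ValidationError


def calls_frame(vals):
    vals = np.asarray(vals, dtype=float)
    return pd.DataFrame(
        vals,
        index=[f"l{i}" for i in range(vals.shape[0])],
        columns=[f"s{j}" for j in range(vals.shape[1])],
    )


class TestFilterConstantLoci:
    def test_constant_and_mixed(self):
        calls = calls_frame([[1, 1, 1], [0, 1, np.nan], [0, 0, 0], [np.nan, 1, 0]])
        assert list(filter_constant_loci(calls)) == ["l1", "l3"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        vals = rng.choice([0.0, 1.0, np.nan], size=(300, 10), p=[0.45, 0.45, 0.1])
        calls = calls_frame(vals)
        got = set(filter_constant_loci(calls))
        brute = {
            f"l{i}"
            for i in range(300)
            if 0.0 in set(vals[i][~np.isnan(vals[i])])
            and 1.0 in set(vals[i][~np.isnan(vals[i])])
        }
        assert got == brute


class TestFisher:
    def test_extreme_table_exact_value(self):
        # (5,0; 0,63): only the observed and fully-swapped tables are as
        # extreme; P = 1 / C(68, 5)
        from math import comb
        assert fisher_p(5, 0, 0, 63) == pytest.approx(1 / comb(68, 5), rel=1e-9)

    def test_identical_distribution_p_one(self):
        # same call distribution in both groups: no association, P = 1
        calls = calls_frame([[1, 0, 1, 0]])
        p = fisher_tests(calls, [0, 0, 1, 1])
        assert p.iloc[0] == pytest.approx(1.0)

    def test_group_label_swap_symmetry(self):
        calls = calls_frame(np.random.default_rng(1).integers(0, 2, (50, 12)).astype(float))
        g = np.array([0] * 5 + [1] * 7)
        pd.testing.assert_series_equal(fisher_tests(calls, g), fisher_tests(calls, 1 - g))

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_p(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_group_entirely_missing_gives_missing_p(self):
        calls = calls_frame([[np.nan, np.nan, 1, 0]])
        p = fisher_tests(calls, [0, 0, 1, 1])
        assert np.isnan(p.iloc[0])


class TestPermutationNull:
    def test_preserves_per_locus_call_frequency(self):
        # permuting labels leaves each locus's methylation frequency intact,
        # so the permuted table's row margins equal the original's
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 2, (100, 20)).astype(float)
        calls = calls_frame(vals)
        g = np.array([0] * 5 + [1] * 15)
        # frequency preservation is structural: the null P is computed from
        # the same calls with shuffled labels, never from altered calls
        null = permutation_null(calls, g, seed=4)
        assert len(null) == 100 and null.notna().all()

    def test_same_seed_identical(self):
        rng = np.random.default_rng(5)
        calls = calls_frame(rng.integers(0, 2, (50, 10)).astype(float))
        g = np.array([0] * 3 + [1] * 7)
        pd.testing.assert_series_equal(
            permutation_null(calls, g, seed=6), permutation_null(calls, g, seed=6)
        )

    def test_null_and_observed_indistinguishable_under_global_null(self):
        rng = np.random.default_rng(7)
        obs_all, null_all = [], []
        for rep in range(5):
            calls = calls_frame((rng.random((400, 24)) < 0.4).astype(float))
            g = np.array([0] * 8 + [1] * 16)
            keep = filter_constant_loci(calls)
            obs_all.append(fisher_tests(calls.loc[keep], g).dropna().to_numpy())
            null_all.append(permutation_null(calls.loc[keep], g, seed=rep).dropna().to_numpy())
        _, p = stats.ks_2samp(np.concatenate(obs_all), np.concatenate(null_all))
        assert p > 0.01


class TestPermutationFDR:
    def test_null_all_ones_everything_significant(self):
        observed = pd.Series([0.01, 0.5, 0.2], index=["a", "b", "c"])
        null = pd.Series([1.0, 1.0, 1.0])
        out = permutation_fdr(observed, null, q=0.05)
        assert out.n_significant == 3
        assert (out.table["fdr"] == 0).all()

    def test_observed_equals_null_top_fdr_is_one(self):
        rng = np.random.default_rng(8)
        p = pd.Series(rng.random(50))
        out = permutation_fdr(p, p.copy(), q=0.05)
        assert out.table["fdr"].iloc[-1] == pytest.approx(1.0)

    def test_worked_five_locus_example(self):
        observed = pd.Series([0.001, 0.01, 0.2, 0.5, 0.9],
                             index=list("abcde"))
        null = pd.Series([0.05, 0.3, 0.6, 0.8, 1.0])
        out = permutation_fdr(observed, null, q=0.05)
        assert list(out.table["fdr"]) == [0 / 1, 0 / 2, 1 / 3, 2 / 4, 4 / 5]
        assert out.n_significant == 2

    def test_q_of_one_flags_all(self):
        rng = np.random.default_rng(9)
        out = permutation_fdr(pd.Series(rng.random(30)), pd.Series(rng.random(30)), q=1.0)
        assert out.n_significant == 30

    def test_null_below_observed_flags_none(self):
        observed = pd.Series([0.5, 0.6, 0.7])
        null = pd.Series([0.01, 0.02, 0.03])
        out = permutation_fdr(observed, null, q=0.5)
        assert out.n_significant == 0

    def test_ties_at_cut_all_flagged(self):
        observed = pd.Series([0.01, 0.01, 0.01, 0.9])
        null = pd.Series([0.5, 0.6, 0.7, 0.8])
        out = permutation_fdr(observed, null, q=0.05)
        assert out.n_significant == 3


class TestMinDetectionCount:
    def test_study_sized_example(self):
        assert min_detection_count(70, 0.10, 0.05) == 12

    def test_single_sample(self):
        assert min_detection_count(1, 0.5, 0.6) == 1

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(1, 100))
            p0 = float(rng.uniform(0.05, 0.9))
            alpha = float(rng.uniform(0.01, 0.5))
            try:
                got = min_detection_count(n, p0, alpha)
            except ValidationError:
                got = None
            brute = next(
                (k for k in range(n + 1) if stats.binom.sf(k - 1, n, p0) < alpha), None
            )
            assert got == brute

    def test_unreachable_significance_is_error(self):
        with pytest.raises(ValidationError):
            min_detection_count(1, 0.99, 0.001)


class TestCdmr:
    def _cdmrs(self):
        return IntervalSet.from_records(
            [("chr1", 100, 200, ""), ("chr1", 300, 400, ""), ("chr2", 0, 50, "")]
        )

    def test_any_vs_half_modes(self):
        cpgs = pd.DataFrame(
            {"seq": ["chr1"] * 3, "pos": [110, 120, 130], "count": [12, 0, 0]}
        )
        detected, frac, empty = cdmr_detection(self._cdmrs(), cpgs, k=12, mode="any")
        assert detected == 1 and empty == 2
        detected, _, _ = cdmr_detection(self._cdmrs(), cpgs, k=12, mode="half")
        assert detected == 0  # 1 of 3 significant < ceil(3/2)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        cdmrs = IntervalSet.from_records(
            [("chr1", int(s), int(s) + int(l), "")
             for s, l in zip(np.sort(rng.integers(0, 9_000, 30)) * 3,
                             rng.integers(50, 500, 30))]
        )
        cpgs = pd.DataFrame(
            {"seq": "chr1", "pos": rng.integers(0, 30_000, 400),
             "count": rng.integers(0, 20, 400)}
        )
        for mode in ("any", "half"):
            got_det, _, got_empty = cdmr_detection(cdmrs, cpgs, k=12, mode=mode)
            det = empty = 0
            for _, row in cdmrs.table.iterrows():
                inside = cpgs[(cpgs["pos"] >= row["start"]) & (cpgs["pos"] < row["end"])]
                if len(inside) == 0:
                    empty += 1
                    continue
                n_sig = int((inside["count"] >= 12).sum())
                need = 1 if mode == "any" else -(-len(inside) // 2)
                det += n_sig >= need
            assert (got_det, got_empty) == (det, empty)

    def test_probe_coverage_boundary_and_brute_force(self):
        probes = ProbeManifest(
            table=pd.DataFrame(
                {"probe_id": ["p1", "p2"], "seq": ["chr1", "chr1"],
                 "pos": [100, 250], "assay_type": 1, "strand": "+"}
            )
        )
        # probe at a cDMR's start base counts (half-open containment)
        frac = cdmr_probe_coverage(self._cdmrs(), probes)
        assert frac == pytest.approx(1 / 3)
        with pytest.raises(ValidationError):
            cdmr_probe_coverage(IntervalSet(), probes)
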