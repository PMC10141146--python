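"""FPKM, size factors, NB Wald test, BH adjustment, DE calling."""
from __future__ import annotations

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from lncmolt.expression_de import (
    COMPARISONS,
    STAGES,
    DEResult,
    ExpressionMatrix,
    bh_adjust,
    compute_fpkm,
    de_summary,
    nb_test,
    run_de,
    size_factors,
)


def oracle_bh(p: list[float]) -> list[float]:
    """Naive O(m^2) step-up BH."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def oracle_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per sample over all-positive rows, plain Python."""
    rows = [r for r in counts.tolist() if all(v > 0 for v in r)]
    out = []
    for j in range(counts.shape[1]):
        logs = [
            math.log(r[j]) - statistics.fmean(math.log(v) for v in r) for r in rows
        ]
        out.append(math.exp(statistics.median(logs)))
    return np.array(out)


class TestFpkm:
    def test_formula_hand_value(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["a", "b"])
        lengths = pd.Series({"a": 500, "b": 1000})
        fpkm = compute_fpkm(counts, lengths)
        # 10 * 1e9 / (500 * 100) = 200_000
        assert fpkm.loc["a", "s1"] == pytest.approx(200_000.0)
        assert fpkm.loc["b", "s1"] == pytest.approx(90e9 / (1000 * 100))

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (20, 2)), columns=["x", "y"])
        lengths = pd.Series(rng.integers(200, 2000, 20), index=counts.index)
        doubled = counts.copy()
        doubled["y"] = counts["y"] * 2  # doubling depth leaves FPKM unchanged
        a = compute_fpkm(counts, lengths)
        b = compute_fpkm(doubled, lengths)
        pd.testing.assert_series_equal(a["y"], b["y"])

    def test_zero_total_column_warns(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero total"):
            fpkm = compute_fpkm(counts, pd.Series({"a": 100, "b": 100}))
        assert (fpkm["s1"] == 0).all()

    def test_bad_length_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, pd.Series({"a": 0}))


class TestSizeFactors:
    def test_hand_value(self):
        counts = pd.DataFrame({"s1": [2, 10], "s2": [4, 20]})
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / math.sqrt(2))
        assert f["s2"] == pytest.approx(math.sqrt(2))

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 30)) * 2 + 1  # odd row count: no interpolation
            counts = pd.DataFrame(
                rng.integers(1, 500, (n, int(rng.integers(2, 6)))).astype(float)
            )
            got = size_factors(counts).to_numpy()
            want = oracle_size_factors(counts.to_numpy())
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_all_zero_rows_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError, match="positive counts"):
            size_factors(counts)


class TestBhAdjust:
    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            np.testing.assert_allclose(bh_adjust(p), oracle_bh(list(p)), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 200)
        got = bh_adjust(p)
        want = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        assert bh_adjust([]).size == 0

    def test_monotone_in_p(self):
        p = [0.001, 0.01, 0.02, 0.8]
        adj = bh_adjust(p)
        assert list(adj) == sorted(adj)


def _nb_counts(rng, mu_a, mu_b, n=200, disp=0.05, reps=3):
    a = rng.poisson(rng.gamma(1 / disp, disp * np.full((n, reps), mu_a)))
    b = rng.poisson(rng.gamma(1 / disp, disp * np.full((n, reps), mu_b)))
    cols = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
    return pd.DataFrame(np.hstack([a, b]), columns=cols), cols[:reps], cols[reps:]


class TestNbTest:
    def test_requires_two_replicates(self):
        counts = pd.DataFrame({"a1": [5], "a2": [6], "b1": [7]})
        with pytest.raises(ValueError, match="two replicates"):
            nb_test(counts, ["a1", "a2"], ["b1"], pd.Series(1.0, index=counts.columns))

    def test_direction_sign(self):
        rng = np.random.default_rng(0)
        counts, sa, sb = _nb_counts(rng, 100, 1600, n=50)
        res = nb_test(counts, sa, sb, pd.Series(1.0, index=counts.columns))
        lfc = np.array([r.log2fc for r in res])
        assert (lfc > 0).mean() > 0.95  # positive log2FC = higher in B

    def test_all_zero_rows_neutral(self):
        counts = pd.DataFrame(
            np.vstack([[0] * 6, [50, 60, 55, 400, 420, 380]]),
            columns=list("abcdef"),
            index=["zero", "real"],
        )
        res = nb_test(counts, ["a", "b", "c"], ["d", "e", "f"],
                      pd.Series(1.0, index=counts.columns))
        by_id = {r.transcript_id: r for r in res}
        assert by_id["zero"].p_value == 1.0 and by_id["zero"].log2fc == 0.0
        assert by_id["real"].p_value < 0.05

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(12)
        counts, sa, sb = _nb_counts(rng, 300, 300, n=3000)
        res = nb_test(counts, sa, sb, pd.Series(1.0, index=counts.columns))
        p = np.array([r.p_value for r in res])
        assert 0.02 < (p < 0.05).mean() < 0.08
        assert 0.4 < (p < 0.5).mean() < 0.6

    def test_size_factor_correction(self):
        # same expression, one library sequenced 2x deeper: no DE after scaling
        rng = np.random.default_rng(4)
        base = rng.poisson(500.0, (300, 6)).astype(float)
        base[:, 3:] *= 2.0
        counts = pd.DataFrame(base, columns=list("abcdef"))
        res = nb_test(counts, ["a", "b", "c"], ["d", "e", "f"], size_factors(counts))
        lfc = np.array([r.log2fc for r in res])
        assert np.abs(np.median(lfc)) < 0.05


class TestDECall:
    def test_fdr_strictly_below_cutoff(self):
        assert not DEResult("t", "c", 3.0, 0.01, fdr=0.05).is_de()
        assert DEResult("t", "c", 3.0, 0.01, fdr=0.049999).is_de()

    def test_lfc_inclusive_at_cutoff(self):
        assert DEResult("t", "c", 2.0, 0.001, fdr=0.001).is_de()
        assert DEResult("t", "c", -2.0, 0.001, fdr=0.001).is_de()
        assert not DEResult("t", "c", 1.999, 0.001, fdr=0.001).is_de()

    def test_direction(self):
        assert DEResult("t", "c", 2.5, 0.001, fdr=0.001).direction() == "up"
        assert DEResult("t", "c", -2.5, 0.001, fdr=0.001).direction() == "down"
        assert DEResult("t", "c", 0.5, 0.001, fdr=0.001).direction() is None


class TestRunDe:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(21)
        samples = [f"{st}{i}" for st in STAGES for i in range(1, 4)]
        stages = {s: s[:2] for s in samples}
        n = 60
        base = rng.poisson(300.0, (n, 9)).astype(float)
        base[:5, 3:6] *= 16  # 5 transcripts up in DE stage
        counts = pd.DataFrame(base, columns=samples,
                              index=[f"t{i}" for i in range(n)])
        lengths = pd.Series(1000, index=counts.index)
        return ExpressionMatrix(counts, stages, lengths)

    def test_all_three_comparisons_present(self, matrix):
        table = run_de(matrix)
        assert set(table["comparison"]) == {f"{a}vs{b}" for a, b in COMPARISONS}
        assert len(table) == 3 * len(matrix.counts)

    def test_planted_de_found(self, matrix):
        table = run_de(matrix)
        up = table[(table["comparison"] == "PEvsDE") & table["is_de"]]
        assert set(up["transcript_id"]) == {f"t{i}" for i in range(5)}
        assert (up["direction"] == "up").all()
        summary = de_summary(table)
        assert summary["PEvsDE"] == {"up": 5, "down": 0, "total": 5}
        # DEvsAE mirrors PEvsDE with the sign flipped
        down = table[(table["comparison"] == "DEvsAE") & table["is_de"]]
        assert (down["direction"] == "down").all()

    def test_design_mismatch_rejected(self, matrix):
        with pytest.raises(ValueError, match="sample ids"):
            ExpressionMatrix(matrix.counts, {"x": "PE"}, matrix.lengths)

    def test_stage_mean_ordering(self, matrix):
        sm = matrix.stage_mean_fpkm()
        assert list(sm.columns) == list(STAGES)
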