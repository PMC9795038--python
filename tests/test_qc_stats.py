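"""QC filters, ΔΔCt identities, and the statistical battery vs. oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from alleleq.qc_stats import (
    QCError,
    QCThresholds,
    QPCRMeasurement,
    compare_many,
    compare_two,
    ddct_knockdown,
    filter_cells,
    kruskal_dunn,
)
from alleleq.qc_stats import _smm_sf


# ---------------------------------------------------------------------------
# independent oracles (hand formulas, no shared code with the implementation)
# ---------------------------------------------------------------------------

def welch_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def kruskal_h_oracle(groups):
    """Tie-corrected H from first principles (mid-ranks by sorting)."""
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(len(flat))
    i = 0
    srt = flat[order]
    while i < len(flat):
        j = i
        while j < len(flat) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(flat)
    h = 0.0
    start = 0
    for g in groups:
        sub = ranks[start : start + len(g)]
        h += len(g) * (sub.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(flat, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def anova_f_oracle(groups):
    groups = [np.asarray(g, float) for g in groups]
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = sum(len(g) for g in groups) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, sps.f.sf(f, dfb, dfw)


def fixed_vectors(n_sets=20, seed=42):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        sizes = rng.integers(4, 9, 3)
        out.append([rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), s) for s in sizes])
    return out


# ---------------------------------------------------------------------------
# cell / gene filters
# ---------------------------------------------------------------------------

def toy_table():
    # gene filter at >=2 cells drops g_rare (detected in D only).  Then, at
    # min_genes_per_cell=4 and mito<=7%:
    #   cell A: 6 qualifying genes, ~2% mito  -> kept
    #   cell B: 3 qualifying genes, 1% mito   -> dropped (too few genes)
    #   cell C: 6 qualifying genes, 8% mito   -> dropped (mito fraction)
    #   cell D: 6 qualifying genes, ~3% mito  -> kept
    cols = ["g1", "g2", "g3", "g4", "g5", "g_rare", "mt-1"]
    data = {
        "A": [10, 10, 10, 19, 1, 0, 1],
        "B": [50, 49, 0, 0, 0, 0, 1],
        "C": [20, 20, 20, 20, 12, 0, 8],
        "D": [5, 5, 5, 5, 5, 3, 1],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


class TestFilterCells:
    thresholds = QCThresholds(min_genes_per_cell=4, max_mito_fraction=0.07, min_cells_per_gene=2)

    def test_toy_example(self):
        out, report = filter_cells(toy_table(), self.thresholds)
        assert set(out.index) == {"A", "D"}
        assert "g_rare" not in out.columns
        reasons = {d["cell"]: d["reason"] for d in report["dropped_cells"]}
        assert "genes" in reasons["B"] and "mito" in reasons["C"]

    def test_idempotent(self):
        out1, _ = filter_cells(toy_table(), self.thresholds)
        out2, _ = filter_cells(out1, self.thresholds)
        pd.testing.assert_frame_equal(out1, out2)

    def test_all_passing_is_identity(self):
        df = pd.DataFrame(1, index=["a", "b", "c"], columns=["g1", "g2", "g3"])
        out, _ = filter_cells(df, QCThresholds(2, 0.5, 2))
        pd.testing.assert_frame_equal(out, df)

    def test_gene_filter_precedes_cell_filter(self):
        # cell X expresses 3 genes, but one is private to X: after the gene
        # filter only 2 qualifying genes remain and X must drop.  Applying
        # the cell filter first would keep X.
        df = pd.DataFrame(
            {"g1": [5, 5], "g2": [5, 5], "private": [5, 0]},
            index=["X", "Y"],
        )
        out, _ = filter_cells(df, QCThresholds(3, 1.0, 2))
        assert list(out.index) == []

    def test_rare_gene_absent_from_output(self):
        out, _ = filter_cells(toy_table(), QCThresholds(1, 1.0, 3))
        assert "g_rare" not in out.columns

    def test_empty_table_error(self):
        with pytest.raises(QCError):
            filter_cells(pd.DataFrame(), self.thresholds)

    def test_threshold_validation(self):
        with pytest.raises(QCError):
            QCThresholds(max_mito_fraction=1.5)
        with pytest.raises(QCError):
            QCThresholds(min_genes_per_cell=0)


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------

class TestDdct:
    def meas(self, target, ref, name="s"):
        return QPCRMeasurement(name, target, ref)

    def test_identical_samples_no_knockdown(self):
        m = self.meas((20, 20, 20), (15, 15, 15))
        res = ddct_knockdown(m, m)
        assert res["knockdown_pct"] == pytest.approx(0.0)
        assert res["relative_expression"] == pytest.approx(1.0)

    def test_two_cycle_shift_is_75_percent(self):
        test = self.meas((22, 22, 22), (15, 15, 15))
        control = self.meas((20, 20, 20), (15, 15, 15))
        assert ddct_knockdown(test, control)["knockdown_pct"] == pytest.approx(75.0)

    def test_80_percent_knockdown_ddct(self):
        # solve 2^-x = 0.2 -> x = log2(5)
        shift = math.log2(5)
        test = self.meas((20 + shift,) * 3, (15,) * 3)
        control = self.meas((20,) * 3, (15,) * 3)
        assert ddct_knockdown(test, control)["knockdown_pct"] == pytest.approx(80.0)

    def test_monotone_in_ddct(self):
        control = self.meas((20,) * 3, (15,) * 3)
        kds = [
            ddct_knockdown(self.meas((20 + s,) * 3, (15,) * 3), control)["knockdown_pct"]
            for s in np.linspace(0, 5, 11)
        ]
        assert all(a < b for a, b in zip(kds, kds[1:]))

    def test_relative_expression_identity(self):
        test = self.meas((21.7, 22.1, 21.9), (15.2, 15.0, 14.9))
        control = self.meas((19.8, 20.1, 20.0), (15.1, 15.0, 15.2))
        res = ddct_knockdown(test, control)
        assert res["relative_expression"] == pytest.approx(1 - res["knockdown_pct"] / 100)

    def test_validation(self):
        with pytest.raises(QCError):
            QPCRMeasurement("s", (), (15,))
        with pytest.raises(QCError):
            QPCRMeasurement("s", (20, -1), (15,))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

class TestCompareTwo:
    def test_identical_groups(self):
        res = compare_two([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_constant_equal_groups_p_one(self):
        res = compare_two([5, 5, 5], [5, 5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_strong_separation(self):
        res = compare_two([0, 0, 1, 1], [10, 10, 11, 11])
        assert res.p_value < 0.001

    def test_matches_oracle_on_fixed_vectors(self):
        for groups in fixed_vectors():
            a, b = groups[0], groups[1]
            t, p = welch_t_oracle(a, b)
            res = compare_two(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)


class TestCompareMany:
    def test_identical_constant_groups(self):
        res = compare_many([[5, 5], [5, 5], [5, 5]])
        assert res.p_value == 1.0 and "degenerate" in res.route

    def test_equal_variance_routes_to_anova_tukey(self):
        groups = [[1.0, 2, 3, 4], [3.0, 4, 5, 6], [6.0, 7, 8, 9]]
        res = compare_many(groups)
        assert res.method == "anova" and "tukey" in res.route
        f, p = anova_f_oracle(groups)
        assert res.statistic == pytest.approx(f, abs=1e-8)
        assert res.p_value == pytest.approx(p, abs=1e-8)
        assert set(res.pairwise["adjustment"]) == {"tukey_hsd"}

    def test_heteroscedastic_routes_to_welch_t3(self):
        rng = np.random.default_rng(0)
        groups = [
            rng.normal(0, 1, 10),
            rng.normal(0.5, 1, 10),
            rng.normal(1, 10, 10),  # 100x variance
        ]
        res = compare_many(groups)
        assert res.method == "welch_anova" and "dunnett_t3" in res.route
        assert sps.bartlett(*groups).pvalue < 0.05

    def test_welch_anova_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for groups in fixed_vectors(5, seed=7):
            df = pd.DataFrame(
                {
                    "g": np.repeat([f"g{i}" for i in range(3)], [len(g) for g in groups]),
                    "v": np.concatenate(groups),
                }
            )
            expected = pg.welch_anova(dv="v", between="g", data=df)
            res = compare_many(groups, bartlett_alpha=1.1)  # force welch route
            assert res.statistic == pytest.approx(float(expected["F"][0]), abs=1e-8)
            assert res.p_value == pytest.approx(float(expected["p_unc"][0]), abs=1e-8)

    def test_constant_group_routes_to_welch(self):
        with pytest.warns(UserWarning):
            res = compare_many([[1.0, 1, 1], [1.0, 2, 3], [4.0, 5, 6]])
        assert res.method == "welch_anova"

    def test_smm_reduces_to_two_sided_t_for_single_contrast(self):
        for t, df in [(1.5, 7.0), (2.3, 12.4), (0.4, 3.3)]:
            assert _smm_sf(t, 1, df) == pytest.approx(2 * sps.t.sf(t, df), abs=1e-8)

    def test_t3_p_values_exceed_unadjusted(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, s, 8) for m, s in [(0, 1), (1, 3), (2, 0.5)]]
        res = compare_many(groups, bartlett_alpha=1.1)
        for _, row in res.pairwise.iterrows():
            raw = 2 * sps.t.sf(abs(row["statistic"]), row["df"])
            assert row["p_adj"] >= raw - 1e-12


class TestKruskalDunn:
    def test_h_on_three_rank_groups(self):
        res = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_identical_values(self):
        res = kruskal_dunn([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_two_group_case_matches_oracle(self):
        for groups in fixed_vectors(10, seed=9):
            a, b = list(groups[0]), list(groups[1])
            h = kruskal_h_oracle([a, b])
            res = kruskal_dunn([a, b])
            assert res.statistic == pytest.approx(h, abs=1e-8)
            assert res.p_value == pytest.approx(sps.chi2.sf(h, 1), abs=1e-8)

    def test_tie_corrected_h_matches_oracle(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4], [4, 4, 5, 5]]
        res = kruskal_dunn(groups)
        assert res.statistic == pytest.approx(kruskal_h_oracle(groups), abs=1e-10)

    def test_dunn_z_and_bh_frozen_values(self):
        # ranks 1..9 in three groups: mean ranks 2, 5, 8; SE = sqrt(5)
        res = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        pw = res.pairwise.set_index(["group_a", "group_b"])
        z01 = pw.loc[("g0", "g1"), "statistic"]
        z02 = pw.loc[("g0", "g2"), "statistic"]
        assert z01 == pytest.approx(-3 / math.sqrt(5), abs=1e-10)
        assert z02 == pytest.approx(-6 / math.sqrt(5), abs=1e-10)
        p01 = 2 * sps.norm.sf(3 / math.sqrt(5))
        p02 = 2 * sps.norm.sf(6 / math.sqrt(5))
        assert pw.loc[("g0", "g2"), "p_adj"] == pytest.approx(3 * p02, abs=1e-10)
        assert pw.loc[("g0", "g1"), "p_adj"] == pytest.approx(p01, abs=1e-10)

    def test_bh_preserves_p_value_ordering(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1, 7) for m in (0, 0.5, 1, 2)]
        pw = kruskal_dunn(groups).pairwise.sort_values("p_raw")
        assert pw["p_adj"].is_monotonic_increasing
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-12).all()
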