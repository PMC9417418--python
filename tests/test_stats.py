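"""ROI aggregation, Spearman/FDR/Wilcoxon/t/rm-ANOVA against brute force."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepod.stats import (
    condition_change,
    correlate_features,
    fdr_bh,
    rm_anova,
    roi_average,
    spearman,
    t_test_paired,
    t_test_vs_one,
    wilcoxon_signed_rank,
)

LAYOUT = {"O1": "occipital", "O2": "occipital", "Fp1": "prefrontal",
          "Cz": "sensorimotor", "C3": "sensorimotor", "E99": "none"}


class TestRoiAverage:
    def frame(self, values):
        rows = []
        for subj in ("s1",):
            for ch, v in values.items():
                rows.append({"subject": subj, "condition": "MDnight",
                             "channel": ch, "feat": v})
        return pd.DataFrame(rows)

    def test_identical_members_pass_through(self):
        out = roi_average(self.frame({"O1": 4.0, "O2": 4.0, "Cz": 1.0}), LAYOUT)
        occ = out[out.roi == "occipital"]
        assert occ.feat.iloc[0] == pytest.approx(4.0)
        assert occ.n_channels.iloc[0] == 2

    def test_two_channel_mean(self):
        out = roi_average(self.frame({"O1": 10.0, "O2": 20.0}), LAYOUT)
        assert out[out.roi == "occipital"].feat.iloc[0] == pytest.approx(15.0)

    def test_permutation_invariance_and_exclusions(self, rng):
        vals = {ch: float(rng.normal()) for ch in LAYOUT}
        df = self.frame(vals)
        out1 = roi_average(df, LAYOUT, bad_channels=["O2"])
        out2 = roi_average(df.iloc[::-1].reset_index(drop=True), LAYOUT,
                           bad_channels=["O2"])
        m1 = out1.set_index("roi").feat.sort_index()
        m2 = out2.set_index("roi").feat.sort_index()
        pd.testing.assert_series_equal(m1, m2)
        assert m1["occipital"] == pytest.approx(vals["O1"])  # O2 excluded
        assert "none" not in set(out1.roi)


class TestConditionChange:
    def frame(self):
        rows = []
        for subj, md, cn in [("s1", 12.0, 10.0), ("s2", 3.0, 3.0)]:
            rows.append({"subject": subj, "condition": "MDnight", "roi": "occ",
                         "feat": md})
            rows.append({"subject": subj, "condition": "Cnight", "roi": "occ",
                         "feat": cn})
        return pd.DataFrame(rows)

    def test_signed_difference(self):
        out = condition_change(self.frame()).set_index("subject")
        assert out.loc["s1", "feat"] == pytest.approx(2.0)
        assert out.loc["s2", "feat"] == pytest.approx(0.0)

    def test_label_swap_negates(self):
        df = self.frame()
        a = condition_change(df).set_index("subject").feat
        b = condition_change(df, deprived="Cnight", control="MDnight")
        b = b.set_index("subject").feat
        pd.testing.assert_series_equal(a, -b)

    def test_missing_night_dropped(self):
        df = self.frame().iloc[:-1]  # drop s2's control night
        with pytest.warns(UserWarning, match="s2"):
            out = condition_change(df)
        assert list(out.subject) == ["s1"]


def rank_then_pearson(x, y):
    """Independent Spearman oracle: midranks then product-moment formula."""
    def midrank(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            for k in range(i, j + 1):
                r[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = midrank(list(x)), midrank(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 41])
        assert res.statistic == pytest.approx(1.0)

    def test_ties_match_midrank_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y).statistic == pytest.approx(
                rank_then_pearson(x, y)
            )

    def test_exact_p_matches_enumeration(self):
        x = [1.0, 2, 3, 4, 5, 6]
        y = [2.0, 1, 4, 3, 6, 5]
        res = spearman(x, y)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        obs = rank_then_pearson(x, y)
        count = sum(
            abs(rank_then_pearson(rx, p)) >= abs(obs) - 1e-12
            for p in itertools.permutations(ry)
        )
        assert res.p == pytest.approx(count / math.factorial(6))

    @given(st.lists(st.integers(-300, 300), min_size=12, max_size=12,
                    unique=True))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        r1 = spearman(x, y).statistic
        r2 = spearman(np.exp(np.asarray(x, dtype=float) / 100.0), y).statistic
        assert r1 == pytest.approx(r2)

    def test_constant_input_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.statistic)
        assert "constant" in res.note

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_step_up(self):
        adj, _ = fdr_bh([0.009, 0.012, 0.03, 0.4])
        assert np.allclose(adj, [0.024, 0.024, 0.04, 0.4])

    def test_all_equal_ps(self):
        adj, _ = fdr_bh([0.2, 0.2, 0.2])
        assert np.allclose(adj, 0.2)

    def test_adjusted_monotone_in_raw(self, rng):
        p = rng.uniform(size=25)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_bh([])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def brute_force_wilcoxon_w(x, y):
    """Signed-rank statistic by direct enumeration of signed midranks."""
    d = [a - b for a, b in zip(x, y) if a != b]
    absd = sorted((abs(v), i) for i, v in enumerate(d))
    ranks = [0.0] * len(d)
    i = 0
    while i < len(absd):
        j = i
        while j + 1 < len(absd) and absd[j + 1][0] == absd[i][0]:
            j += 1
        for k in range(i, j + 1):
            ranks[absd[k][1]] = (i + j) / 2 + 1
        i = j + 1
    w_pos = sum(r for r, v in zip(ranks, d) if v > 0)
    w_neg = sum(r for r, v in zip(ranks, d) if v < 0)
    return min(w_pos, w_neg)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert res.p == 1.0
        assert "zero" in res.note

    def test_w_matches_enumeration(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            y = x + rng.normal(scale=0.8, size=8)
            res = wilcoxon_signed_rank(x, y)
            assert res.statistic == pytest.approx(brute_force_wilcoxon_w(x, y))

    def test_large_shift_significant(self, rng):
        x = rng.normal(size=10)
        res = wilcoxon_signed_rank(x, x + 5.0)
        assert res.p < 0.05


class TestTTests:
    def test_all_ones_zero_t(self):
        with pytest.raises(ValueError, match="variance"):
            t_test_vs_one([1.0, 1.0, 1.0, 1.0])

    def test_closed_form_four_values(self):
        v = [0.8, 0.9, 1.0, 0.7]
        res = t_test_vs_one(v)
        m = np.mean(v)
        sd = np.std(v, ddof=1)
        assert res.statistic == pytest.approx((m - 1) / (sd / 2.0))
        assert res.effect == pytest.approx(abs(m - 1) / sd)
        assert res.df == (3,)

    def test_paired_equals_one_sample_on_differences(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = t_test_paired(x, y)
        b = t_test_vs_one(x - y + 1.0, mu=1.0)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)


def brute_force_oneway_rm(table):
    """Sum-of-squares decomposition for a subjects x levels matrix."""
    n, k = table.shape
    grand = table.mean()
    ss_total = ((table - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_time = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_time
    df1, df2 = k - 1, (n - 1) * (k - 1)
    f = (ss_time / df1) / (ss_err / df2)
    return f, (df1, df2), ss_time / (ss_time + ss_err), ss_total


class TestRmAnova:
    def long(self, mat):
        rows = []
        for i, row in enumerate(mat):
            for j, v in enumerate(row):
                rows.append({"subject": f"s{i}", "time": f"t{j}", "y": v})
        return pd.DataFrame(rows)

    def test_identical_levels_zero_f(self):
        mat = np.tile([[1.0], [2.0], [3.0]], (1, 5))
        res = rm_anova(self.long(mat), "y", "time")[0]
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_matches_ss_decomposition(self, rng):
        mat = rng.normal(size=(3, 5)) + np.linspace(0, 1, 5)
        res = rm_anova(self.long(mat), "y", "time")[0]
        f, dof, np2, _ = brute_force_oneway_rm(mat)
        assert res.statistic == pytest.approx(f)
        assert res.df == dof
        assert res.effect == pytest.approx(np2)

    def test_total_ss_conserved(self, rng):
        """Decomposed components add to the total on random tables."""
        for _ in range(5):
            mat = rng.normal(size=(6, 4))
            n, k = mat.shape
            grand = mat.mean()
            ss_total = ((mat - grand) ** 2).sum()
            ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
            ss_time = n * ((mat.mean(axis=0) - grand) ** 2).sum()
            ss_err = ss_total - ss_subj - ss_time
            assert ss_subj + ss_time + ss_err == pytest.approx(ss_total)
            assert ss_err >= -1e-9

    def test_two_factor_interaction_reported(self, rng):
        rows = []
        for s in range(6):
            for a in ("pre", "post"):
                for c in ("MDnight", "MDmorn"):
                    rows.append({"subject": f"s{s}", "TIME": a, "COND": c,
                                 "y": rng.normal()})
        res = rm_anova(pd.DataFrame(rows), "y", ["TIME", "COND"])
        names = [r.name for r in res]
        assert any("TIME * COND" in n for n in names)

    def test_incomplete_subject_dropped(self, rng):
        df = self.long(rng.normal(size=(4, 3)))
        df = df.iloc[:-1]  # s3 misses t2
        with pytest.warns(UserWarning, match="s3"):
            res = rm_anova(df, "y", "time")[0]
        assert res.n == 3


class TestCorrelateFeatures:
    def test_family_fdr_and_rejection(self, rng):
        n = 15
        di = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        changes = pd.DataFrame({
            "subject": di.index,
            "coupled": -di.values + rng.normal(scale=0.1, size=n),
            "null_a": rng.normal(size=n),
            "null_b": rng.normal(size=n),
        })
        out = correlate_features(changes, di, q=0.05, family="before")
        out = out.set_index("feature")
        assert out.loc["coupled", "rho"] < -0.8
        assert out.loc["coupled", "significant"]
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()
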