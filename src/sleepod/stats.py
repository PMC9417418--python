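"""ROI aggregation and the statistical battery.

Channel-level sleep features are averaged into regions of interest
(occipital, prefrontal, sensorimotor control), between-night change scores
are formed (deprivation night minus control night), and the features are
related to the deprivation index with Spearman correlations under
Benjamini-Hochberg FDR control.  Night comparisons use the Wilcoxon
signed-rank test; deprivation-index timepoints are tested against 1 with
one-sample t-tests (Cohen's d), and their time course with repeated-measures
ANOVA (partial eta squared).

Spearman's rho uses midranks for ties and an exact permutation p-value for
n <= 9 (the regime of small cohorts), a t-approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

ROIS = ("occipital", "prefrontal", "sensorimotor")


@dataclass
class StatResult:
    name: str
    statistic: float
    n: int
    p: float
    df: tuple[float, ...] = ()
    p_fdr: float | None = None
    effect: float | None = None
    effect_name: str | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# ROI aggregation and change scores
# ---------------------------------------------------------------------------


def roi_average(
    channel_table: pd.DataFrame,
    layout: Mapping[str, str],
    channel_col: str = "channel",
    bad_channels: Sequence[str] = (),
) -> pd.DataFrame:
    """Unweighted mean of the member channels of each ROI, per feature.

    ``channel_table`` has one row per channel (plus any grouping columns such
    as subject/condition) and numeric feature columns.  ``layout`` maps
    channel label -> ROI name; channels mapped to ``"none"``, absent from the
    layout, or listed in ``bad_channels`` are excluded.  The member count is
    reported as ``n_channels``.
    """
    df = channel_table.copy()
    df["roi"] = df[channel_col].map(lambda c: layout.get(c, "none"))
    df = df[(df["roi"] != "none") & ~df[channel_col].isin(set(bad_channels))]
    named = [r for r in set(layout.values()) if r != "none"]
    empty = sorted(set(named) - set(df["roi"].unique()))
    if empty:
        warnings.warn(f"ROI(s) {empty} have no usable channels")
    group_cols = [
        c
        for c in df.columns
        if c not in (channel_col, "roi") and not pd.api.types.is_numeric_dtype(df[c])
    ]
    grouped = df.groupby(group_cols + ["roi"], as_index=False)
    out = grouped.mean(numeric_only=True)
    out["n_channels"] = grouped.size()["size"].values
    return out


def condition_change(
    roi_table: pd.DataFrame,
    condition_col: str = "condition",
    deprived: str = "MDnight",
    control: str = "Cnight",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Per-subject signed difference (deprivation night minus control night).

    Subjects missing either night are dropped with a warning.
    """
    keys = [c for c in roi_table.columns
            if c in (subject_col, "roi")]
    feat_cols = [
        c
        for c in roi_table.columns
        if c not in keys + [condition_col, "n_channels"]
        and pd.api.types.is_numeric_dtype(roi_table[c])
    ]
    md = roi_table[roi_table[condition_col] == deprived].set_index(keys)
    cn = roi_table[roi_table[condition_col] == control].set_index(keys)
    common = md.index.intersection(cn.index)
    dropped = sorted(
        set(md.index.symmetric_difference(cn.index).get_level_values(0))
    )
    if dropped:
        warnings.warn(f"subjects missing one night dropped: {dropped}")
    delta = md.loc[common, feat_cols] - cn.loc[common, feat_cols]
    return delta.reset_index()


# ---------------------------------------------------------------------------
# Spearman with exact small-n p
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt((a @ a) * (b @ b))
    return float(a @ b / den) if den > 0 else float("nan")


def spearman(
    x: Sequence[float], y: Sequence[float], name: str = "spearman",
    exact_n_max: int = 9,
) -> StatResult:
    """Spearman rank correlation with midranks for ties.

    Pairs with missing values are removed (pairwise deletion).  The two-sided
    p-value enumerates all rank permutations for n <= ``exact_n_max`` and uses
    the t-approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError(f"Spearman needs >= 4 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(name, float("nan"), n, float("nan"),
                          note="constant input: rho undefined")
    rx = spstats.rankdata(x)
    ry = spstats.rankdata(y)
    rho = _pearson(rx, ry)
    if n <= exact_n_max:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * spstats.t.sf(abs(t), n - 2)
    return StatResult(name, rho, n, p, effect=rho, effect_name="rho")


# ---------------------------------------------------------------------------
# FDR, Wilcoxon, t-tests
# ---------------------------------------------------------------------------


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], name: str = "wilcoxon"
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (Wilcoxon convention); if every difference is
    zero the result is degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = np.count_nonzero(d)
    if nz == 0:
        return StatResult(name, 0.0, len(x), 1.0, note="all differences zero")
    if nz < 5:
        warnings.warn(f"only {nz} non-zero differences; Wilcoxon p unstable")
    res = spstats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return StatResult(name, float(res.statistic), nz, float(res.pvalue))


def t_test_vs_one(
    values: Sequence[float], mu: float = 1.0, name: str = "t_vs_1"
) -> StatResult:
    """Two-tailed one-sample t-test against mu (default 1 = no change)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 3:
        raise ValueError("one-sample t-test needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t undefined")
    res = spstats.ttest_1samp(v, mu)
    d = abs(v.mean() - mu) / sd
    return StatResult(name, float(res.statistic), n, float(res.pvalue),
                      df=(n - 1,), effect=d, effect_name="cohen_d")


def t_test_paired(
    x: Sequence[float], y: Sequence[float], name: str = "t_paired"
) -> StatResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("paired t-test needs n >= 3 complete pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: t undefined")
    res = spstats.ttest_rel(x, y)
    return StatResult(name, float(res.statistic), n, float(res.pvalue),
                      df=(n - 1,), effect=abs(d.mean()) / sd,
                      effect_name="cohen_d")


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | Sequence[str],
    subject: str = "subject",
) -> list[StatResult]:
    """Within-subject ANOVA (one factor, or two factors with interaction).

    Subjects with any missing cell are dropped listwise with a warning.
    Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    within_l = [within] if isinstance(within, str) else list(within)
    df = data[[subject, dv] + within_l].copy()
    cells = df.groupby(subject)[dv].count()
    expected = int(np.prod([df[w].nunique() for w in within_l]))
    complete = cells[cells == expected].index
    dropped = sorted(set(cells.index) - set(complete))
    if dropped:
        warnings.warn(f"subjects with missing cells dropped: {dropped}")
    df = df[df[subject].isin(complete)]
    if df[subject].nunique() < 2:
        raise ValueError("repeated-measures ANOVA needs >= 2 complete subjects")
    aov = pg.rm_anova(
        data=df, dv=dv,
        within=within_l if len(within_l) > 1 else within_l[0],
        subject=subject, detailed=True, effsize="np2", correction=False,
    )
    err_df = None
    if "DF" in aov.columns:
        err = aov[aov["Source"].str.lower() == "error"]
        if len(err):
            err_df = float(err["DF"].iloc[0])
    results = []
    for _, row in aov.iterrows():
        if str(row["Source"]).lower() == "error":
            continue
        if "ddof1" in aov.columns:
            dof = (float(row["ddof1"]), float(row["ddof2"]))
        else:
            dof = (float(row["DF"]), err_df)
        degenerate = "F" not in aov.columns or not np.isfinite(row.get("F", np.nan))
        results.append(
            StatResult(
                name=f"rm_anova[{row['Source']}]",
                statistic=0.0 if degenerate else float(row["F"]),
                n=int(df[subject].nunique()),
                p=1.0 if degenerate else float(row["p_unc"]),
                df=dof,
                effect=0.0 if degenerate else float(row["np2"]),
                effect_name="partial_eta2",
                note="zero effect and error variance" if degenerate else "",
            )
        )
    return results


# ---------------------------------------------------------------------------
# feature-vs-DI correlation families
# ---------------------------------------------------------------------------


def correlate_features(
    changes: pd.DataFrame,
    di: Mapping[str, float] | pd.Series,
    features: Sequence[str] | None = None,
    q: float = 0.05,
    subject_col: str = "subject",
    family: str = "",
) -> pd.DataFrame:
    """Spearman of each feature change against the DI, BH-FDR over the family.

    ``changes`` holds one row per subject with feature-change columns; ``di``
    maps subject -> deprivation index.  Returns a tidy table with rho, p,
    adjusted p, and the rejection flag at level ``q``.
    """
    di = pd.Series(di)
    if features is None:
        features = [
            c
            for c in changes.columns
            if c != subject_col and pd.api.types.is_numeric_dtype(changes[c])
        ]
    idx = changes[subject_col] if subject_col in changes else changes.index
    rows = []
    for feat in features:
        x = di.reindex(idx).to_numpy()
        y = changes[feat].to_numpy()
        res = spearman(x, y, name=feat)
        rows.append(
            {"feature": feat, "family": family, "n": res.n,
             "rho": res.statistic, "p": res.p}
        )
    out = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(out["p"].fillna(1.0), q=q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out
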