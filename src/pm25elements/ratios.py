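"""Seasonal binary diagnostic ratios with ANOVA / t significance tests.

The campaign year is partitioned into three season bins by sample start
month: March-June (pre-monsoon burning season), July-October (wet season)
and November-February (cool/dry season).  Per-sample element ratios are
summarised per season and compared with a one-way F test (three seasons)
or a pooled two-sample t test (two seasons), against critical values at
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConcentrationTable, ValidationError

SEASONS = {
    "March-June": (3, 4, 5, 6),
    "July-October": (7, 8, 9, 10),
    "November-February": (11, 12, 1, 2),
}

#: the ratio pairs the campaign reports
RATIO_PAIRS = (("Ca", "Al"), ("Ca", "Si"), ("Zn", "Al"), ("Pb", "Al"),
               ("Fe", "Al"), ("Na", "Mg"), ("Ni", "V"), ("V", "Fe"),
               ("As", "V"), ("Se", "V"))


def assign_season(date) -> str:
    """Season bin of a sample's start date (total over all 12 months)."""
    month = pd.Timestamp(date).month
    for name, months in SEASONS.items():
        if month in months:
            return name
    raise ValidationError(f"month {month} outside 1..12")  # pragma: no cover


def binary_ratios(table: ConcentrationTable, num: str, den: str) -> pd.DataFrame:
    """Per-sample num/den concentration ratios, season-annotated.

    Samples whose denominator is zero or missing are skipped; if none
    survive, that is an error.
    """
    for sym in (num, den):
        if sym not in table.panel.symbols:
            raise ValidationError(f"element {sym!r} not in panel")
    d = table.values[den].to_numpy(float)
    nvals = table.values[num].to_numpy(float)
    keep = np.isfinite(d) & (d > 0) & np.isfinite(nvals)
    if not keep.any():
        raise ValidationError(f"no usable denominators for {num}/{den}")
    out = pd.DataFrame({
        "site": table.values.loc[keep, "site"],
        "date": table.values.loc[keep, "date"],
        "ratio": nvals[keep] / d[keep],
    })
    out["season"] = out["date"].map(assign_season)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class TestResult:
    test: str            # "anova" or "t"
    statistic: float
    critical: float
    significant: bool
    df: tuple


def anova_oneway(groups, alpha: float = 0.05) -> TestResult:
    """Classical one-way F with df (k-1, N-k) and the F critical value at
    1 - alpha; significant iff F > F_crit."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    f_crit = float(stats.f.ppf(1 - alpha, df1, df2))
    return TestResult("anova", float(f), f_crit, bool(f > f_crit), (df1, df2))


def ttest_two_sample(a, b, alpha: float = 0.05, tails: int = 1,
                     welch: bool = False) -> TestResult:
    """Two-sample t (pooled variance by default, Welch optional).

    The critical value defaults to the one-tailed 1 - alpha point at
    df = n_a + n_b - 2, matching the campaign's printed criticals; a
    two-tailed critical is available via ``tails=2``.  Significance is
    judged on |t|.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    if welch:
        t, _ = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    else:
        sp2 = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
               / (na + nb - 2))
        if sp2 == 0:
            t = 0.0
        else:
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    q = 1 - alpha if tails == 1 else 1 - alpha / 2
    crit = float(stats.t.ppf(q, df))
    return TestResult("t", float(t), crit, bool(abs(t) > crit), (df,))


def seasonal_ratio_table(table: ConcentrationTable,
                         pairs=RATIO_PAIRS, alpha: float = 0.05) -> pd.DataFrame:
    """Season mean +/- sd and n per site and ratio, with the F or t test.

    Sites with three populated seasons get one-way ANOVA; sites with two
    get the pooled t test; a single populated season yields no test.
    """
    rows = []
    for num, den in pairs:
        per_sample = binary_ratios(table, num, den)
        for site, sub in per_sample.groupby("site", sort=False):
            groups = {s: g["ratio"].to_numpy()
                      for s, g in sub.groupby("season", sort=False)}
            groups = {s: g for s, g in groups.items() if len(g) >= 2}
            res = None
            if len(groups) >= 3:
                res = anova_oneway(list(groups.values()), alpha=alpha)
            elif len(groups) == 2:
                res = ttest_two_sample(*groups.values(), alpha=alpha)
            for season in SEASONS:
                g = groups.get(season, np.array([]))
                rows.append({
                    "ratio": f"{num}/{den}", "site": site, "season": season,
                    "n": len(g),
                    "mean": g.mean() if len(g) else np.nan,
                    "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
                    "test": res.test if res else "",
                    "statistic": res.statistic if res else np.nan,
                    "critical": res.critical if res else np.nan,
                    "significant": res.significant if res else False,
                })
    return pd.DataFrame(rows).set_index(["ratio", "site", "season"])


def pearson_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over complete cases.

    Constant columns yield NaN rows/columns (flagged undefined) rather
    than an error, mirroring how correlation tables print blanks.
    """
    sub = frame.dropna()
    if len(sub) < 3:
        raise ValidationError("need >= 3 complete samples")
    x = sub.to_numpy(float)
    sds = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[sds == 0, :] = np.nan
    corr[:, sds == 0] = np.nan
    np.fill_diagonal(corr, np.where(sds == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=frame.columns, columns=frame.columns)
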