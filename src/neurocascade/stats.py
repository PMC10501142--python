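"""Post-hoc analyses: abnormal-region frequency, feature–clinical
correlations, demographic group statistics, and balanced down-sampling.

The demographic tests mirror the study's cohort table: a Pearson chi-square
on the sex counts and one-way ANOVAs on the continuous traits.  The ANOVA
has a summary-statistic path (from per-group n, mean, SD — the form printed
in papers) and a raw-data path that reduces to it algebraically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import FeatureTable

__all__ = [
    "GroupSummary",
    "region_frequency",
    "clinical_correlation",
    "chi_square_independence",
    "anova_oneway_summary",
    "anova_oneway_raw",
    "downsample_balance",
    "table1_report",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group n / mean / SD of one continuous trait."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def region_frequency(
    per_fold_features: list,
    threshold: int = 6,
    stage: str | None = None,
) -> list[tuple[tuple, int]]:
    """Count how often each (metric, region) was selected across folds.

    ``per_fold_features`` is either a list of per-fold feature-key lists, or
    the list of per-fold stage dicts a classification report carries (then
    ``stage`` picks one stage, or all stages are pooled per fold as a set).
    Only features appearing in at least ``threshold`` folds are returned,
    sorted by descending count then by key.
    """
    counts: Counter = Counter()
    for fold in per_fold_features:
        if isinstance(fold, dict):
            if stage is not None:
                keys = fold.get(stage, [])
            else:
                keys = [k for v in fold.values() for k in v]
        else:
            keys = fold
        counts.update({tuple(k) if isinstance(k, (list, tuple)) else k for k in keys})
    kept = [(k, c) for k, c in counts.items() if c >= threshold]
    return sorted(kept, key=lambda kc: (-kc[1], str(kc[0])))


def clinical_correlation(
    table: FeatureTable,
    scores: pd.DataFrame,
    feature_keys: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Pearson r between feature columns and clinical scores (pooled subjects).

    Rows are features, columns are clinical scores; zero-variance columns
    yield NaN.  Subjects are matched by id; incomplete pairs are dropped.
    """
    feats = table.values if feature_keys is None else table.values[feature_keys]
    common = feats.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired complete observations")
    F = feats.loc[common]
    S = scores.loc[common].select_dtypes(include=[np.number])
    out = pd.DataFrame(index=F.columns, columns=S.columns, dtype=float)
    for sc in S.columns:
        s = S[sc].to_numpy(dtype=float)
        for fc in F.columns:
            f = F[fc].to_numpy(dtype=float)
            ok = np.isfinite(f) & np.isfinite(s)
            if ok.sum() < 3 or f[ok].std() == 0 or s[ok].std() == 0:
                out.loc[fc, sc] = np.nan
            else:
                out.loc[fc, sc] = float(np.corrcoef(f[ok], s[ok])[0, 1])
    return out


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a groups × categories table.

    No continuity correction.  Returns (statistic, df, p).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the contingency table")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway_summary(
    groups: list[GroupSummary] | list[tuple[int, float, float]],
) -> tuple[float, int, int, float]:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    SS_between = sum n_i (xbar_i - xbar)^2, SS_within = sum (n_i - 1) s_i^2,
    F = MS_b / MS_w with df (k-1, N-k); p from the upper F tail.
    """
    gs = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    N = ns.sum()
    k = len(gs)
    grand = float((ns * means).sum() / N)
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, int(N - k)
    if ss_w == 0:
        if ss_b == 0:
            raise ValueError("all groups identical with zero variance; F undefined")
        return float("inf"), df1, df2, 0.0
    F = (ss_b / df1) / (ss_w / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def anova_oneway_raw(samples: list[np.ndarray]) -> tuple[float, int, int, float]:
    """One-way ANOVA from raw per-group samples (reduces to the summary path)."""
    gs = [
        GroupSummary(n=len(s), mean=float(np.mean(s)), sd=float(np.std(s, ddof=1)))
        for s in (np.asarray(s, dtype=float) for s in samples)
    ]
    return anova_oneway_summary(gs)


def downsample_balance(table: FeatureTable, n_target: int, seed: int = 0) -> FeatureTable:
    """Uniform random down-sampling to ``n_target`` subjects per class."""
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cls, cnt in sorted(table.class_counts().items()):
        ids = table.groups.index[table.groups == cls].to_numpy()
        if len(ids) < n_target:
            raise ValueError(f"class {cls!r} has {len(ids)} < n_target={n_target}")
        keep.extend(rng.choice(ids, size=n_target, replace=False))
    keep = sorted(keep)
    return table.subset_rows(keep)


def table1_report(demographics: pd.DataFrame) -> pd.DataFrame:
    """Cohort-table style group statistics with chi-square / ANOVA p-values.

    Expects columns 'group', 'sex' and numeric traits; returns one row per
    trait with per-group mean ± sd (or counts for sex) and the p-value.
    """
    groups = ["AD", "MCI", "HC"]
    rows = []
    sex_tab = pd.crosstab(demographics["group"], demographics["sex"]).reindex(groups)
    stat, df, p = chi_square_independence(sex_tab.to_numpy())
    rows.append(
        {
            "trait": "sex",
            **{
                g: "/".join(str(int(v)) for v in sex_tab.loc[g]) for g in groups
            },
            "test": "chi-square",
            "p": p,
        }
    )
    for trait in demographics.select_dtypes(include=[np.number]).columns:
        summaries, cells = [], {}
        degenerate = False
        for g in groups:
            v = demographics.loc[demographics["group"] == g, trait].to_numpy(dtype=float)
            sd = float(np.std(v, ddof=1))
            cells[g] = f"{np.mean(v):.2f} ± {sd:.2f}"
            if sd == 0:
                degenerate = True
            summaries.append(GroupSummary(len(v), float(np.mean(v)), sd))
        if degenerate and len({s.mean for s in summaries}) > 1:
            p = 0.0  # deterministic trait (e.g. CDR): groups differ exactly
        elif degenerate:
            p = float("nan")
        else:
            *_, p = anova_oneway_summary(summaries)
        rows.append({"trait": trait, **cells, "test": "one-way ANOVA", "p": p})
    return pd.DataFrame(rows).set_index("trait")
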