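"""Between-cluster comparison of covariates and activity summaries.

Continuous variables are compared across clusters with a one-way ANOVA F-test;
categorical variables with a Pearson chi-square on the cluster x level
contingency table. Pairwise follow-ups (Welch two-sample t-tests, or 2-group
chi-squares) are computed only when the overall test is significant, mirroring
the usual "omnibus first" reporting convention, and are unadjusted by default
(a Holm correction is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass
class ComparisonSpec:
    """One covariate to compare: its name and measurement type."""

    variable: str
    type: str  # "categorical" | "continuous"
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.type not in ("categorical", "continuous"):
            raise ValueError(f"unknown variable type {self.type!r}")


@dataclass
class ComparisonResult:
    variable: str
    type: str
    statistic: float            # F or chi-square; NaN when flagged
    df: tuple                   # (df1, df2) for F, (df,) for chi-square
    p_value: float              # NaN when the test is degenerate
    group_summaries: dict       # cluster -> {"n", "mean", "sd"} or {"n", "counts"}
    pairwise: list = field(default_factory=list)  # (group_a, group_b, p)
    flags: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < DEFAULT_ALPHA)


def _holm(pairs: list) -> list:
    from statsmodels.stats.multitest import multipletests

    if not pairs:
        return pairs
    _, adj, _, _ = multipletests([p for *_ab, p in pairs], method="holm")
    return [(a, b, float(p)) for (a, b, _), p in zip(pairs, adj)]


def _continuous(values: pd.Series, groups: dict, alpha, t_variant, adjust) -> ComparisonResult:
    samples = {c: values.loc[ids].dropna().to_numpy(float) for c, ids in groups.items()}
    k = len(samples)
    n_total = sum(len(v) for v in samples.values())
    flags: list[str] = []
    summaries = {
        c: {"n": len(v), "mean": float(np.mean(v)) if len(v) else np.nan,
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan}
        for c, v in samples.items()
    }
    if all(len(v) > 0 and np.ptp(v) == 0 for v in samples.values()):
        flags.append("zero within-group variance; F undefined")
        stat, p = np.nan, np.nan
    else:
        stat, p = stats.f_oneway(*samples.values())
        stat, p = float(stat), float(p)
    result = ComparisonResult(
        variable=values.name, type="continuous", statistic=stat,
        df=(k - 1, n_total - k), p_value=p, group_summaries=summaries, flags=flags,
    )
    if np.isfinite(p) and p < alpha:
        pairs = []
        for a, b in combinations(sorted(samples), 2):
            equal_var = t_variant == "pooled"
            _, pp = stats.ttest_ind(samples[a], samples[b], equal_var=equal_var)
            pairs.append((a, b, float(pp)))
        result.pairwise = _holm(pairs) if adjust == "holm" else pairs
    return result


def _categorical(values: pd.Series, groups: dict, alpha, yates, adjust) -> ComparisonResult:
    flags: list[str] = []
    table = pd.DataFrame(
        {c: values.loc[ids].dropna().value_counts() for c, ids in groups.items()}
    ).fillna(0).astype(int).T  # rows = clusters, columns = levels
    empty_levels = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_levels):
        flags.append(f"dropped all-zero levels: {list(empty_levels)}")
        warnings.warn(f"{values.name}: dropping all-zero levels {list(empty_levels)}")
        table = table.drop(columns=empty_levels)
    summaries = {
        c: {"n": int(table.loc[c].sum()), "counts": table.loc[c].to_dict()}
        for c in table.index
    }
    correction = yates and table.shape == (2, 2)
    if table.shape[1] < 2:
        flags.append("fewer than 2 observed levels; chi-square undefined")
        stat, p, dof = np.nan, np.nan, 0
    else:
        stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        stat, p = float(stat), float(p)
    result = ComparisonResult(
        variable=values.name, type="categorical", statistic=stat,
        df=(dof,), p_value=p, group_summaries=summaries, flags=flags,
    )
    if np.isfinite(p) and p < alpha:
        pairs = []
        for a, b in combinations(sorted(table.index), 2):
            sub = table.loc[[a, b]]
            sub = sub.loc[:, sub.sum(axis=0) > 0]
            if sub.shape[1] < 2:
                continue
            corr = yates and sub.shape == (2, 2)
            _, pp, _, _ = stats.chi2_contingency(sub.to_numpy(), correction=corr)
            pairs.append((a, b, float(pp)))
        result.pairwise = _holm(pairs) if adjust == "holm" else pairs
    return result


def compare_groups(
    cohort,
    labels,
    specs: list[ComparisonSpec],
    alpha: float = DEFAULT_ALPHA,
    t_variant: str = "welch",
    yates: bool = False,
    adjust: str | None = None,
) -> list[ComparisonResult]:
    """Overall then conditional pairwise tests for each covariate.

    ``labels`` maps participant_id -> cluster (dict or Series), or is an
    array aligned with the cohort's sorted participant ids. Requires at least
    two nonempty clusters.
    """
    ids = sorted(cohort.participant_ids)
    if isinstance(labels, (dict, pd.Series)):
        lab = pd.Series({i: labels[i] for i in ids})
    else:
        labels = np.asarray(labels)
        if len(labels) != len(ids):
            raise ValueError("labels do not align with sorted participant ids")
        lab = pd.Series(labels, index=ids)
    groups = {c: list(lab.index[lab == c]) for c in sorted(lab.unique())}
    if len(groups) < 2:
        raise ValueError("need at least two clusters to compare")
    cov = cohort.covariates
    results = []
    for spec in specs:
        if spec.variable not in cov.columns:
            raise KeyError(f"covariate {spec.variable!r} not in cohort table")
        values = cov[spec.variable]
        if spec.type == "continuous":
            results.append(_continuous(values, groups, alpha, t_variant, adjust))
        else:
            results.append(_categorical(values, groups, alpha, yates, adjust))
    return results


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0").replace("0.", ".")


def cluster_summary_table(
    cohort,
    labels,
    bouts: pd.DataFrame | None,
    specs: list[ComparisonSpec],
    results: list[ComparisonResult] | None = None,
    names: dict | None = None,
    **compare_kwargs,
) -> pd.DataFrame:
    """Per-cluster summary table: n, mean (SD) / n (%), overall and pairwise p.

    ``bouts`` (from :func:`acticlust.bouts.cohort_bout_summaries`) is folded
    in as extra continuous rows when provided.
    """
    ids = sorted(cohort.participant_ids)
    if isinstance(labels, (dict, pd.Series)):
        lab = pd.Series({i: labels[i] for i in ids})
    else:
        lab = pd.Series(np.asarray(labels), index=ids)

    work = cohort
    all_specs = list(specs)
    if bouts is not None and len(bouts):
        cov = cohort.covariates.join(bouts.set_index("participant_id"), how="left")
        from .io_cohort import CohortDataset

        work = CohortDataset(cohort.traces, cov)
        for col in ("weekly_mvpa_1min", "weekly_mvpa_5min", "weekly_mvpa_10min",
                    "mean_daily_steps"):
            if col in cov.columns and cov[col].notna().any():
                all_specs.append(ComparisonSpec(col, "continuous"))
    if results is None:
        results = compare_groups(work, labels, all_specs, **compare_kwargs)

    clusters = sorted(lab.unique())
    sizes = {c: int((lab == c).sum()) for c in clusters}

    def col_name(c):
        base = names.get(c, f"cluster {c}") if names else f"cluster {c}"
        return f"{base} (n={sizes[c]})"

    rows = []
    for res in results:
        if res.type == "continuous":
            cells = {
                col_name(c): (
                    f"{s['mean']:.1f} ({s['sd']:.1f})"
                    if np.isfinite(s.get("mean", np.nan)) else "—"
                )
                for c, s in res.group_summaries.items()
            }
            rows.append({"variable": res.variable, **cells,
                         "overall_p": _fmt_p(res.p_value),
                         "pairwise": _fmt_pairwise(res, names)})
        else:
            levels = sorted({lv for s in res.group_summaries.values() for lv in s["counts"]})
            for lv in levels:
                cells = {}
                for c, s in res.group_summaries.items():
                    n_c, cnt = s["n"], s["counts"].get(lv, 0)
                    pct = 100.0 * cnt / n_c if n_c else 0.0
                    cells[col_name(c)] = f"{cnt} ({pct:.1f})"
                rows.append({"variable": f"{res.variable}: {lv}", **cells,
                             "overall_p": _fmt_p(res.p_value) if lv == levels[0] else "",
                             "pairwise": _fmt_pairwise(res, names) if lv == levels[0] else ""})
    header = {"variable": "n", **{col_name(c): str(sizes[c]) for c in clusters},
              "overall_p": "", "pairwise": ""}
    return pd.DataFrame([header] + rows)


def _fmt_pairwise(res: ComparisonResult, names: dict | None) -> str:
    def nm(c):
        return names.get(c, str(c)) if names else str(c)

    sig = [(a, b, p) for a, b, p in res.pairwise if p < DEFAULT_ALPHA]
    return "; ".join(f"{nm(a)} vs {nm(b)}: {_fmt_p(p)}" for a, b, p in sig)
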