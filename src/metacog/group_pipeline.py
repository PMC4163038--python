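"""Subject- and group-level analysis of metacognitive efficiency.

Composes per-session meta-d' fits into the full analysis: log-efficiency with
exclusion of non-positive ratios, the domain-general index
DGI = |log Mp - log Mm| (Mp, Mm the perceptual and memory meta-d'/d'),
subject-resampled bootstrap percentile confidence intervals, parametric and
rank-based group comparisons, and a permutation test of the group x domain
interaction on log-efficiency.

The interaction is tested on the per-subject difference log Mp - log Mm: each
subject contributes exactly one value per domain, so a group effect on that
difference *is* the group x domain interaction at this design's granularity,
and permuting subjects across groups yields an exact reference distribution
without any random-effects assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sdt_core import efficiency_from_trials

__all__ = [
    "dgi",
    "bootstrap_percentile_ci",
    "apply_exclusions",
    "fit_cohort",
    "group_tests",
    "run_full_analysis",
    "GroupResult",
    "AnalysisResult",
]

DOMAINS = ("perception", "memory")


def dgi(mp: float, mm: float, log_base: float | None = None) -> float:
    """Domain-general index: |log Mp - log Mm| (natural log by default).

    Quantifies how *consistent* a subject's metacognitive efficiency is
    across the perceptual and memory domains: 0 means identical efficiency
    (whether both high or both low); larger values mean a domain-specific
    profile.  Symmetric in its arguments and invariant to the log base up to
    a constant factor; pass ``log_base`` (e.g. 10) to rescale.

    Raises
    ------
    ValueError
        If either efficiency is non-positive (the log is undefined; such
        subjects are excluded from DGI analyses upstream).
    """
    if not (mp > 0 and mm > 0):
        raise ValueError(
            f"dgi undefined for non-positive efficiency (Mp={mp}, Mm={mm}); "
            "such subjects are excluded from log-based analyses"
        )
    value = abs(math.log(mp) - math.log(mm))
    if log_base is not None:
        value /= math.log(log_base)
    return value


def bootstrap_percentile_ci(
    values,
    level: float = 0.95,
    n_resamples: int = 100_000,
    seed=None,
    *,
    chunk: int = 20_000,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean.

    Draws ``n_resamples`` resamples with replacement (resampling unit = the
    supplied values, i.e. subjects when called on per-subject summaries),
    recomputes the mean of each, and returns the ``(1-level)/2`` and
    ``(1+level)/2`` percentiles of the resampled distribution.  Reproducible
    from ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 values for a bootstrap interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = x.size
    means = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(m, n))
        means[done : done + m] = x[idx].mean(axis=1)
        done += m
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def fit_cohort(trials: pd.DataFrame, nbins: int = 4) -> pd.DataFrame:
    """Fit meta-d' for every subject x domain in a pooled trial table.

    Returns one row per subject x domain with the type-1 and type-2 fit
    summaries; rows are sorted by (group, subject_id, domain) so downstream
    outputs are deterministic.
    """
    rows = []
    for (subject, group, domain), sub in trials.groupby(
        ["subject_id", "group", "domain"], sort=True
    ):
        fit = efficiency_from_trials(sub, nbins)
        rows.append(
            {
                "subject_id": subject,
                "group": group,
                "domain": domain,
                "n_trials": len(sub),
                "percent_correct": 100.0 * sub["accuracy"].mean(),
                "mean_confidence": sub["confidence_raw"].mean(),
                "d_prime": fit.d_prime,
                "criterion_c": fit.criterion_c,
                "meta_d": fit.meta_d,
                "efficiency": fit.efficiency,
                "log_efficiency": np.nan if fit.log_efficiency is None else fit.log_efficiency,
                "excluded": fit.excluded,
                "flags": ";".join(fit.flags),
                "loglik": fit.log_likelihood,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["group", "subject_id", "domain"], ignore_index=True)


def apply_exclusions(
    fits: pd.DataFrame, log_base: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-subject summaries, excluding non-positive efficiencies from logs.

    A subject with non-positive (or undefined) efficiency in a domain keeps
    the raw value in ``Mp``/``Mm`` but has the corresponding log column set
    to missing and is dropped from DGI; every exclusion is recorded with its
    reason.  ``log_base`` rescales the log columns and DGI (natural log by
    default).  The rule is a pure function of the fits, so re-applying it
    changes nothing.

    Returns
    -------
    (summaries, exclusion_log)
    """
    scale = 1.0 if log_base is None else 1.0 / math.log(log_base)
    records = {}
    exclusions = []
    for row in fits.itertuples(index=False):
        rec = records.setdefault(
            row.subject_id,
            {
                "subject_id": row.subject_id,
                "group": row.group,
                "Mp": np.nan,
                "Mm": np.nan,
                "log_Mp": np.nan,
                "log_Mm": np.nan,
                "dgi": np.nan,
                "excluded_domains": [],
            },
        )
        eff = row.efficiency
        key = "Mp" if row.domain == "perception" else "Mm"
        rec[key] = eff
        if np.isfinite(eff) and eff > 0:
            rec["log_" + key] = math.log(eff) * scale
        else:
            rec["excluded_domains"].append(row.domain)
            reason = (
                "undefined efficiency"
                if not np.isfinite(eff)
                else f"non-positive efficiency (meta-d'/d' = {eff:.3f})"
            )
            exclusions.append(
                {"subject_id": row.subject_id, "domain": row.domain, "reason": reason}
            )
    for rec in records.values():
        if np.isfinite(rec["log_Mp"]) and np.isfinite(rec["log_Mm"]):
            rec["dgi"] = dgi(rec["Mp"], rec["Mm"], log_base)
        rec["excluded_domains"] = ";".join(sorted(rec["excluded_domains"]))
    summaries = pd.DataFrame(list(records.values())).sort_values(
        ["group", "subject_id"], ignore_index=True
    )
    log = pd.DataFrame(exclusions, columns=["subject_id", "domain", "reason"])
    return summaries, log


@dataclass
class GroupResult:
    """Group-level statistics, intervals and tests.

    ``group_stats`` has one row per group x measure (mean, SD, n, bootstrap
    CI); ``tests`` one row per comparison (statistic NaN with an explanatory
    note when a test is not computable); ``interaction`` holds the permuted
    group x domain contrast on log-efficiency.
    """

    group_stats: pd.DataFrame
    tests: pd.DataFrame
    interaction: dict
    settings: dict = field(default_factory=dict)


def _not_computable(name: str, note: str) -> dict:
    return {"test": name, "statistic": np.nan, "p_value": np.nan, "note": note}


def _interaction_statistic(values: np.ndarray, labels: np.ndarray, groups) -> float:
    """Contrast on per-subject domain differences: mean difference for two
    groups, one-way F for more."""
    if len(groups) == 2:
        a = values[labels == groups[0]]
        b = values[labels == groups[1]]
        return float(a.mean() - b.mean())
    grand = values.mean()
    ss_between = sum(
        (values[labels == g].size) * (values[labels == g].mean() - grand) ** 2 for g in groups
    )
    ss_within = sum(
        ((values[labels == g] - values[labels == g].mean()) ** 2).sum() for g in groups
    )
    df1 = len(groups) - 1
    df2 = values.size - len(groups)
    if ss_within <= 0 or df2 <= 0:
        return np.nan
    return float((ss_between / df1) / (ss_within / df2))


def group_tests(
    summaries: pd.DataFrame,
    *,
    seed=None,
    n_permutations: int = 10_000,
    bootstrap_n: int = 100_000,
    ci_level: float = 0.95,
) -> GroupResult:
    """Compare efficiency and DGI across groups.

    Produces per-group descriptives with subject-resampled bootstrap
    percentile CIs, omnibus one-way ANOVA and Kruskal-Wallis tests, pairwise
    pooled-variance t and Wilcoxon rank-sum tests, and the permutation test
    of the group x domain interaction on log-efficiency.  Groups too small
    for a test yield a not-computable marker rather than an error.
    """
    rng = np.random.default_rng(seed)
    groups = list(pd.unique(summaries["group"]))
    measures = ["Mp", "Mm", "log_Mp", "log_Mm", "dgi"]

    stat_rows = []
    for g in groups:
        sub = summaries[summaries["group"] == g]
        for m in measures:
            vals = sub[m].dropna().to_numpy()
            row = {
                "group": g,
                "measure": m,
                "n": vals.size,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "ci_level": ci_level,
                "n_resamples": bootstrap_n,
            }
            if vals.size >= 2:
                lo, hi = bootstrap_percentile_ci(
                    vals, ci_level, bootstrap_n, rng.integers(0, 2**31 - 1)
                )
                row["ci_lower"], row["ci_upper"] = lo, hi
            stat_rows.append(row)
    group_stats = pd.DataFrame(stat_rows)

    test_rows = []
    for m in ("Mp", "Mm", "dgi"):
        samples = [summaries.loc[summaries["group"] == g, m].dropna().to_numpy() for g in groups]
        usable = [(g, s) for g, s in zip(groups, samples) if s.size >= 2]
        if len(usable) >= 2:
            arrays = [s for _, s in usable]
            f_stat, f_p = stats.f_oneway(*arrays)
            test_rows.append(
                {"test": f"anova_{m}", "statistic": float(f_stat), "p_value": float(f_p), "note": ""}
            )
            if all(s.size >= 2 for s in arrays):
                try:
                    h_stat, h_p = stats.kruskal(*arrays)
                    test_rows.append(
                        {
                            "test": f"kruskal_{m}",
                            "statistic": float(h_stat),
                            "p_value": float(h_p),
                            "note": "",
                        }
                    )
                except ValueError as exc:  # all values identical
                    test_rows.append(_not_computable(f"kruskal_{m}", str(exc)))
        else:
            test_rows.append(
                _not_computable(f"anova_{m}", "need >=2 groups with >=2 subjects each")
            )
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = summaries.loc[summaries["group"] == groups[i], m].dropna().to_numpy()
                b = summaries.loc[summaries["group"] == groups[j], m].dropna().to_numpy()
                pair = f"{m}:{groups[i]}_vs_{groups[j]}"
                if a.size >= 2 and b.size >= 2:
                    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
                    test_rows.append(
                        {
                            "test": f"ttest_{pair}",
                            "statistic": float(t_stat),
                            "p_value": float(t_p),
                            "note": "",
                        }
                    )
                    u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    test_rows.append(
                        {
                            "test": f"ranksum_{pair}",
                            "statistic": float(u_stat),
                            "p_value": float(u_p),
                            "note": "",
                        }
                    )
                else:
                    test_rows.append(
                        _not_computable(f"ttest_{pair}", "need >=2 subjects per group")
                    )
    tests = pd.DataFrame(test_rows)

    # Group x domain interaction: permute subjects' group labels over the
    # per-subject log-efficiency domain difference.
    both = summaries.dropna(subset=["log_Mp", "log_Mm"])
    diff = (both["log_Mp"] - both["log_Mm"]).to_numpy()
    labels = both["group"].to_numpy()
    inter_groups = [g for g in groups if (labels == g).sum() >= 2]
    interaction: dict = {
        "statistic": np.nan,
        "p_value": np.nan,
        "n_permutations": n_permutations,
        "groups": inter_groups,
        "note": "",
    }
    if len(inter_groups) >= 2:
        mask = np.isin(labels, inter_groups)
        diff_u, labels_u = diff[mask], labels[mask]
        observed = _interaction_statistic(diff_u, labels_u, inter_groups)
        perm_stats = np.empty(n_permutations)
        for p in range(n_permutations):
            perm_stats[p] = _interaction_statistic(
                diff_u, rng.permutation(labels_u), inter_groups
            )
        if len(inter_groups) == 2:
            extreme = np.abs(perm_stats) >= abs(observed) - 1e-12
        else:
            extreme = perm_stats >= observed - 1e-12
        interaction["statistic"] = observed
        interaction["p_value"] = float((1 + extreme.sum()) / (1 + n_permutations))
    else:
        interaction["note"] = "need >=2 groups with >=2 unexcluded subjects"

    return GroupResult(
        group_stats=group_stats,
        tests=tests,
        interaction=interaction,
        settings={
            "n_permutations": n_permutations,
            "bootstrap_n": bootstrap_n,
            "ci_level": ci_level,
            "seed": seed,
        },
    )


@dataclass
class AnalysisResult:
    """End-to-end pipeline output."""

    fits: pd.DataFrame
    summaries: pd.DataFrame
    exclusions: pd.DataFrame
    descriptives: pd.DataFrame
    group_result: GroupResult
    report: str


def _descriptives(trials: pd.DataFrame, fits: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Task-performance and efficiency descriptives per group, in the layout
    of the standard results table for this design (memory measures split by
    study time, perception difficulty as the mean staircased dot difference)."""
    groups = list(pd.unique(fits["group"]))
    subj_group = trials.groupby("subject_id")["group"].first()
    rows = []

    def add(domain, measure, per_subject: pd.Series):
        by_group = per_subject.groupby(per_subject.index.map(subj_group)).agg(
            ["mean", "std", "count"]
        )
        for g in groups:
            if g in by_group.index:
                m, s, n = by_group.loc[g]
            else:
                m, s, n = np.nan, np.nan, 0
            rows.append(
                {"domain": domain, "measure": measure, "group": g, "mean": m, "sd": s, "n": int(n)}
            )

    mem = trials[trials["domain"] == "memory"]
    for t in sorted(pd.unique(mem["condition_tag"])):
        sub = mem[mem["condition_tag"] == t]
        add("memory", f"% correct, {t} min study", 100.0 * sub.groupby("subject_id")["accuracy"].mean())
        add("memory", f"confidence, {t} min study", sub.groupby("subject_id")["confidence_raw"].mean())
    per = trials[trials["domain"] == "perception"]
    if len(per):
        add("perception", "% correct", 100.0 * per.groupby("subject_id")["accuracy"].mean())
        add(
            "perception",
            "delta-d (dots)",
            per["condition_tag"].astype(float).groupby(per["subject_id"]).mean(),
        )
        add("perception", "confidence", per.groupby("subject_id")["confidence_raw"].mean())
    summ = summaries.set_index("subject_id")
    add("memory", "meta-d'/d'", summ["Mm"].dropna())
    add("perception", "meta-d'/d'", summ["Mp"].dropna())
    add("both", "domain-general index", summ["dgi"].dropna())
    return pd.DataFrame(rows)


def run_full_analysis(trials: pd.DataFrame, config=None, out_dir=None) -> AnalysisResult:
    """Run the complete analysis on a pooled trial table.

    Per-subject-per-domain meta-d' fits, exclusion of non-positive ratios
    from log-based measures, DGI, group descriptives with bootstrap CIs,
    group tests and the interaction permutation test, plus a plain-text
    report.  Deterministic given the configured seed.  If ``out_dir`` is
    given, all tables, the report and the effective configuration are
    written there (see :mod:`metacog.io_interface`).
    """
    from . import io_interface

    if config is None:
        config = io_interface.RunConfig()
    io_interface.validate_trials(trials)

    fits = fit_cohort(trials, config.nbins)
    summaries, exclusions = apply_exclusions(fits, config.log_base)
    group_result = group_tests(
        summaries,
        seed=config.seed,
        n_permutations=config.n_permutations,
        bootstrap_n=config.bootstrap_n,
        ci_level=config.ci_level,
    )
    descriptives = _descriptives(trials, fits, summaries)
    report = io_interface.format_report(descriptives, group_result, exclusions)
    result = AnalysisResult(
        fits=fits,
        summaries=summaries,
        exclusions=exclusions,
        descriptives=descriptives,
        group_result=group_result,
        report=report,
    )
    if out_dir is not None:
        io_interface.write_analysis(result, config, out_dir)
    return result
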