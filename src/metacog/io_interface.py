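"""Readers, writers, validation, configuration and report formatting.

All tabular files are comma-delimited UTF-8 text with one header row and LF
line endings; numbers in data files round-trip at full precision, and are
human-rounded only in the report.  Every run's effective configuration is
serialized alongside its outputs so results are reproducible from the files
alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sdt_core import S1, S2

__all__ = [
    "RunConfig",
    "TrialValidationError",
    "TRIAL_COLUMNS",
    "read_trials",
    "validate_trials",
    "write_trials",
    "write_report",
    "write_analysis",
    "format_report",
]

#: Required columns of a trial table, in canonical order.
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "domain",
    "block",
    "trial_index",
    "stimulus_side",
    "response_side",
    "accuracy",
    "confidence_raw",
    "condition_tag",
]


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema; lists offending rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid trial table:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass
class RunConfig:
    """Effective configuration of one analysis run.

    ``seed`` feeds every stochastic step (bootstrap resampling and the
    permutation test); two runs with equal configuration produce
    byte-identical outputs.
    """

    nbins: int = 4
    bootstrap_n: int = 100_000
    ci_level: float = 0.95
    n_permutations: int = 10_000
    seed: int = 0
    #: base for log-efficiency and DGI; None = natural log
    log_base: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )


def validate_trials(trials: pd.DataFrame) -> None:
    """Schema-check a trial table; raise listing every offending row.

    Row numbers refer to data rows (1-based, excluding the header).
    """
    problems: list[str] = []
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    unknown = [c for c in trials.columns if c not in TRIAL_COLUMNS]
    if missing:
        problems.append(f"missing columns: {missing}")
    if unknown:
        problems.append(f"unknown columns: {unknown}")
    if problems:
        raise TrialValidationError(problems)

    def report_rows(mask, message):
        rows = np.flatnonzero(np.asarray(mask)) + 1
        if rows.size:
            shown = ", ".join(map(str, rows[:10])) + (", ..." if rows.size > 10 else "")
            problems.append(f"{message} on row{'s' if rows.size > 1 else ''} {shown}")

    conf = pd.to_numeric(trials["confidence_raw"], errors="coerce")
    report_rows(conf.isna() | (conf < 1) | (conf > 6), "confidence_raw outside [1, 6]")
    acc = pd.to_numeric(trials["accuracy"], errors="coerce")
    report_rows(~acc.isin([0, 1]), "non-binary accuracy")
    for col in ("stimulus_side", "response_side"):
        report_rows(~trials[col].isin([S1, S2]), f"{col} not in {{{S1!r}, {S2!r}}}")
    consistent = (trials["stimulus_side"] == trials["response_side"]).astype(int)
    ok = acc.isin([0, 1])
    report_rows(ok & (acc != consistent), "accuracy inconsistent with stimulus/response sides")
    dup = trials.duplicated(subset=["subject_id", "domain", "trial_index"], keep=False)
    report_rows(dup & trials.duplicated(subset=["subject_id", "domain", "trial_index"]),
                "duplicate (subject_id, domain, trial_index)")
    if problems:
        raise TrialValidationError(problems)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table from a delimited text file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    trials = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    validate_trials(trials)
    return trials[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-delimited UTF-8 text."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def _fmt(x, digits=2) -> str:
    return "--" if x is None or not np.isfinite(x) else f"{x:.{digits}f}"


def format_report(descriptives: pd.DataFrame, group_result, exclusions: pd.DataFrame) -> str:
    """Render the group analysis as a plain-text/markdown report.

    Mirrors the standard results-table layout for this design: per-domain
    performance, confidence, meta-d'/d' and the domain-general index as
    "mean (SD)" per group, followed by bootstrap CIs, test statistics and the
    exclusion log.  Not-computable entries are reported as explicit gaps.
    """
    lines = ["# Metacognitive efficiency report", ""]
    groups = list(pd.unique(descriptives["group"]))

    lines.append("## Group descriptives (mean (SD))")
    lines.append("")
    header = "| Task / measure | " + " | ".join(str(g) for g in groups) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(groups) + 1))
    for domain in ("memory", "perception", "both"):
        block = descriptives[descriptives["domain"] == domain]
        if block.empty:
            continue
        lines.append(f"| **{domain.capitalize()}** |" + " |" * len(groups))
        for measure in block["measure"].unique():
            cells = []
            for g in groups:
                row = block[(block["measure"] == measure) & (block["group"] == g)]
                if row.empty or row["n"].iloc[0] == 0:
                    cells.append("--")
                else:
                    cells.append(f"{_fmt(row['mean'].iloc[0])} ({_fmt(row['sd'].iloc[0])})")
            lines.append(f"| {measure} | " + " | ".join(cells) + " |")
    lines.append("")

    gs = group_result.group_stats
    level = int(round(100 * gs["ci_level"].iloc[0])) if len(gs) else 95
    lines.append(f"## Bootstrap {level}% CIs (percentile, subject-resampled)")
    lines.append("")
    lines.append("| Group | Measure | n | mean | CI |")
    lines.append("|---|---|---|---|---|")
    for row in gs.itertuples(index=False):
        ci = (
            f"[{_fmt(row.ci_lower)}, {_fmt(row.ci_upper)}]"
            if np.isfinite(row.ci_lower)
            else "not computable (n < 2)"
        )
        lines.append(f"| {row.group} | {row.measure} | {row.n} | {_fmt(row.mean)} | {ci} |")
    lines.append("")

    lines.append("## Group tests (two-tailed, unadjusted)")
    lines.append("")
    lines.append("| Test | statistic | p |")
    lines.append("|---|---|---|")
    for row in group_result.tests.itertuples(index=False):
        if np.isfinite(row.statistic):
            lines.append(f"| {row.test} | {_fmt(row.statistic, 3)} | {_fmt(row.p_value, 4)} |")
        else:
            lines.append(f"| {row.test} | not computable | {row.note} |")
    inter = group_result.interaction
    lines.append("")
    if np.isfinite(inter.get("statistic", np.nan)):
        lines.append(
            f"Group x domain interaction (log-efficiency contrast, "
            f"{inter['n_permutations']} permutations over groups {inter['groups']}): "
            f"statistic = {_fmt(inter['statistic'], 3)}, p = {_fmt(inter['p_value'], 4)}."
        )
    else:
        lines.append(f"Group x domain interaction: not computable ({inter.get('note', '')}).")
    lines.append("")

    lines.append("## Exclusions")
    lines.append("")
    if len(exclusions):
        for row in exclusions.itertuples(index=False):
            lines.append(f"- {row.subject_id} ({row.domain}): {row.reason}")
    else:
        lines.append("- none")
    lines.append("")
    lines.append(
        "Notes: log-efficiency and DGI exclude non-positive meta-d'/d'. "
        "No multiple-comparison adjustment is applied. No covariate "
        "adjustment (IQ, gender, lesion volume) is performed by this "
        "pipeline."
    )
    lines.append("")
    return "\n".join(lines)


def write_report(report: str, path) -> None:
    """Write a formatted report to ``path``."""
    Path(path).write_text(report, encoding="utf-8")


def write_analysis(result, config: RunConfig, out_dir) -> None:
    """Write every pipeline output (tables, report, config, run log) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(out / "subject_fits.csv", index=False, lineterminator="\n")
    result.summaries.to_csv(out / "subject_summaries.csv", index=False, lineterminator="\n")
    result.exclusions.to_csv(out / "exclusions.csv", index=False, lineterminator="\n")
    result.descriptives.to_csv(out / "descriptives.csv", index=False, lineterminator="\n")
    result.group_result.group_stats.to_csv(out / "group_stats.csv", index=False, lineterminator="\n")
    result.group_result.tests.to_csv(out / "group_tests.csv", index=False, lineterminator="\n")
    write_report(result.report, out / "report.md")
    config.to_yaml(out / "run_config.yaml")
    _write_run_log(result, config, out / "run_log.json")


def _write_run_log(result, config: RunConfig, path) -> None:
    import scipy

    from . import __version__

    inter = dict(result.group_result.interaction)
    inter["groups"] = list(inter.get("groups", []))
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "config": dataclasses.asdict(config),
        "n_subjects": int(result.summaries.shape[0]),
        "n_excluded_rows": int(result.exclusions.shape[0]),
        "interaction": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in inter.items()
        },
    }
    Path(path).write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
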