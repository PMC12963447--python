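"""Human-readable summaries with traceable arithmetic.

Every percentage printed here is count / total * 100 rounded to the stated
number of decimals, so any figure in a rendered report can be traced back to
a cell of an output table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["percentage", "count_table", "render_report"]


def percentage(count: float, total: float, decimals: int = 2) -> float:
    """count / total expressed in percent, rounded half-away-from-zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = count / total * 100.0
    # round half away from zero, matching how printed tables are rounded
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def count_table(rows: list[tuple[str, float]], total: float, decimals: int = 2) -> pd.DataFrame:
    """Label/count rows with percentages over ``total``."""
    out = pd.DataFrame(rows, columns=["label", "count"])
    out["pct"] = [percentage(c, total, decimals) for c in out["count"]]
    return out


def _fmt_count_block(title: str, mapping: dict, total: int, indent: str = "  ") -> list[str]:
    lines = [f"{title}:"]
    for label, count in mapping.items():
        lines.append(f"{indent}{label}: {count} ({percentage(count, total, 2)}%)")
    return lines


def render_report(out_dir) -> str:
    """Assemble a plain-text study report from pipeline output files.

    Expects (subsets tolerated only for files never produced in the run):
    summary.json (descriptive summary), outcomes.csv, metrics.csv,
    pairs_top.csv, triads_top.csv, multistate.csv under ``out_dir``.
    """
    import json

    out = Path(out_dir)
    lines: list[str] = ["Multimorbidity progression report", "=" * 34]

    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"missing report input: {summary_path}")
    summary = json.loads(summary_path.read_text())
    n = summary["n_patients"]
    lines.append(f"Cohort size: {n}")
    for label in ("baseline", "end_of_study"):
        block = summary[label]
        lines.append(f"\n[{label}]")
        lines += _fmt_count_block("Age bands", block["age_bands"], n)
        lines += _fmt_count_block("Risk strata", block["strata"], n)
        lines.append(
            f"Index mean (SD) [IQR]: {block['index_mean']:.2f} ({block['index_sd']:.2f}) "
            f"[{block['index_iqr'][0]:.1f}, {block['index_iqr'][1]:.1f}]"
        )
        lines += _fmt_count_block("Chronic conditions", block["chronic_count_bins"], n)

    outcomes_path = out / "outcomes.csv"
    if outcomes_path.exists():
        outcomes = pd.read_csv(outcomes_path)
        eligible = outcomes.loc[outcomes["eligible"]]
        n_event = int(eligible["event"].sum())
        lines.append("\n[transitions]")
        lines.append(
            f"Eligible (baseline below P80, alive at end): {len(eligible)}"
        )
        if len(eligible):
            lines.append(
                f"Transitioned to high/very-high: {n_event} "
                f"({percentage(n_event, len(eligible), 1)}%)"
            )

    multistate_path = out / "multistate.csv"
    if multistate_path.exists():
        ms = pd.read_csv(multistate_path)
        lines.append("\n[multi-state occupancy]")
        lines.append(ms.to_string(index=False))

    metrics_path = out / "metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path)
        lines.append("\n[model discrimination (held-out)]")
        lines.append(metrics.to_string(index=False))

    for name, title in (("pairs_top.csv", "top pairs"), ("triads_top.csv", "top triads")):
        path = out / name
        if path.exists():
            lines.append(f"\n[{title}]")
            lines.append(pd.read_csv(path).to_string(index=False))

    return "\n".join(lines) + "\n"
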