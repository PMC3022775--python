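"""Condition-level aggregation, Welch tests and the screen report.

Scores are aggregated per condition as mean ± SEM over analyzable larvae
(orientation QC passed, at least one neuromast square detected).  Each
treatment is compared against the designated control with an unpaired
two-sided t-test with Welch's correction (no equal-variance pooling);
significance is reported at P < 0.05 with the conventional star mapping

    *** P < 0.001,  ** 0.001 ≤ P < 0.01,  * 0.01 ≤ P < 0.05,  else ns

where boundary P-values resolve toward the weaker claim.  Minimum group
sizes follow assay practice: 30 larvae per condition in intensity mode,
15 in count mode; smaller groups are flagged rather than dropped.  No
multiple-testing correction is applied by default (a Bonferroni option
exists for multi-treatment screens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .leukocyte_quantification import LarvaMeasurement

MIN_N_INTENSITY = 30
MIN_N_COUNT = 15

STAR_CUTPOINTS = (0.001, 0.01, 0.05)


@dataclass
class ConditionSummary:
    condition_label: str
    n_assigned: int
    n_analyzed: int
    n_excluded_orientation: int
    n_excluded_no_roi: int
    mean: float | None
    sem: float | None
    min_n_ok: bool

    def as_row(self) -> dict:
        return {
            "condition": self.condition_label,
            "n_assigned": self.n_assigned,
            "n_analyzed": self.n_analyzed,
            "n_excluded_orientation": self.n_excluded_orientation,
            "n_excluded_no_roi": self.n_excluded_no_roi,
            "mean": self.mean,
            "sem": self.sem,
            "min_n_ok": self.min_n_ok,
        }


@dataclass
class ComparisonResult:
    condition_a: str
    condition_b: str
    t_statistic: float
    degrees_freedom: float
    p_value: float
    stars: str

    def as_row(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "t_statistic": self.t_statistic,
            "degrees_freedom": self.degrees_freedom,
            "p_value": self.p_value,
            "stars": self.stars,
        }


def _scores(m: LarvaMeasurement, mode: str) -> float | None:
    if mode == "count":
        return None if m.band_count is None else float(m.band_count)
    return m.inflammation_score


def summarize_condition(
    measurements: Sequence[LarvaMeasurement],
    min_n: int | None = None,
    mode: str = "intensity",
) -> ConditionSummary:
    """Aggregate one condition's larvae into n / mean / SEM with QC counts.

    Exclusion order follows the pipeline: unfavourably oriented larvae are
    excluded first, then (intensity mode) larvae without a detected square.
    SEM = sd/sqrt(n) with the n−1 variance, defined for n ≥ 2.
    """
    labels = {m.condition_label for m in measurements}
    if len(labels) > 1:
        raise ValueError(f"measurements span multiple conditions: {sorted(labels)}")
    if min_n is None:
        min_n = MIN_N_COUNT if mode == "count" else MIN_N_INTENSITY
    label = labels.pop() if labels else ""

    n_assigned = len(measurements)
    oriented = [m for m in measurements if m.orientation_ok]
    n_excl_orient = n_assigned - len(oriented)
    if mode == "count":
        usable = [m for m in oriented if m.band_count is not None]
    else:
        usable = [m for m in oriented if m.data_producing and m.inflammation_score is not None]
    n_excl_no_roi = len(oriented) - len(usable)

    values = np.array([_scores(m, mode) for m in usable], dtype=np.float64)
    mean = float(values.mean()) if values.size else None
    sem = (
        float(values.std(ddof=1) / math.sqrt(values.size)) if values.size >= 2 else None
    )
    return ConditionSummary(
        condition_label=label,
        n_assigned=n_assigned,
        n_analyzed=len(usable),
        n_excluded_orientation=n_excl_orient,
        n_excluded_no_roi=n_excl_no_roi,
        mean=mean,
        sem=sem,
        min_n_ok=len(usable) >= min_n,
    )


def welch_t_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-sided unpaired t-test with Welch's correction.

    t = (m_a − m_b) / sqrt(s²_a/n_a + s²_b/n_b), degrees of freedom by
    Welch–Satterthwaite; variances are never pooled.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.size}, {b.size})")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    import warnings

    with warnings.catch_warnings():
        # two identical constant groups trip scipy's precision-loss warning;
        # that degenerate case is mapped to t=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if math.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return ComparisonResult(
        condition_a=label_a,
        condition_b=label_b,
        t_statistic=t,
        degrees_freedom=df,
        p_value=p,
        stars=significance_stars(p),
    )


def significance_stars(p_value: float) -> str:
    """Map a P-value to the conventional star label.

    Boundaries (exactly 0.001, 0.01, 0.05) map to the weaker category.
    """
    if not 0.0 <= p_value <= 1.0 or math.isnan(p_value):
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    if p_value < STAR_CUTPOINTS[0]:
        return "***"
    if p_value < STAR_CUTPOINTS[1]:
        return "**"
    if p_value < STAR_CUTPOINTS[2]:
        return "*"
    return "ns"


def compare_to_control(
    measurements_by_condition: dict[str, Sequence[LarvaMeasurement]],
    control: str,
    mode: str = "intensity",
    bonferroni: bool = False,
) -> list[ComparisonResult]:
    """Welch test of every treatment against the designated control."""
    if control not in measurements_by_condition:
        raise ValueError(
            f"control condition {control!r} not among {sorted(measurements_by_condition)}"
        )

    def usable_scores(ms: Sequence[LarvaMeasurement]) -> list[float]:
        out = []
        for m in ms:
            if not m.orientation_ok:
                continue
            v = _scores(m, mode)
            if v is not None:
                out.append(v)
        return out

    ctrl_scores = usable_scores(measurements_by_condition[control])
    results = []
    treatments = [c for c in measurements_by_condition if c != control]
    for cond in treatments:
        res = welch_t_test(
            usable_scores(measurements_by_condition[cond]),
            ctrl_scores,
            label_a=cond,
            label_b=control,
        )
        if bonferroni:
            p = min(1.0, res.p_value * len(treatments))
            res.p_value = p
            res.stars = significance_stars(p)
        results.append(res)
    return results


def screen_report(
    measurements: Sequence[LarvaMeasurement],
    control: str,
    out_dir: str | Path,
    mode: str = "intensity",
    min_n: int | None = None,
    bonferroni: bool = False,
) -> dict[str, Path]:
    """Write the screen report: summary CSV, comparison CSV, bar chart.

    The bar chart shows mean ± SEM per condition with significance stars
    over each treatment (vs. control).
    """
    if not control:
        raise ValueError("a control condition must be designated")
    by_cond: dict[str, list[LarvaMeasurement]] = {}
    for m in measurements:
        by_cond.setdefault(m.condition_label, []).append(m)
    if control not in by_cond:
        raise ValueError(f"control condition {control!r} has no measurements")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries = {
        cond: summarize_condition(ms, min_n=min_n, mode=mode)
        for cond, ms in by_cond.items()
    }
    order = [control] + sorted(c for c in by_cond if c != control)
    summary_df = pd.DataFrame([summaries[c].as_row() for c in order])
    comparisons = compare_to_control(by_cond, control, mode=mode, bonferroni=bonferroni)
    comp_df = pd.DataFrame([c.as_row() for c in comparisons])

    summary_path = out_dir / "summary.csv"
    comp_path = out_dir / "comparisons.csv"
    summary_df.to_csv(summary_path, index=False)
    comp_df.to_csv(comp_path, index=False)

    fig_path = out_dir / "report.png"
    _bar_chart(summaries, comparisons, order, mode, fig_path)
    return {"summary": summary_path, "comparisons": comp_path, "figure": fig_path}


def _bar_chart(summaries, comparisons, order, mode, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stars = {c.condition_a: c.stars for c in comparisons}
    means = [summaries[c].mean or 0.0 for c in order]
    sems = [summaries[c].sem or 0.0 for c in order]
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(order), 4.0))
    x = np.arange(len(order))
    ax.bar(x, means, yerr=sems, capsize=4, color="#7f9fc4", edgecolor="black")
    for i, cond in enumerate(order):
        if cond in stars:
            y = means[i] + sems[i]
            ax.text(i, y, stars[cond], ha="center", va="bottom", fontsize=12)
    ax.set_xticks(x)
    ax.set_xticklabels(order, rotation=30, ha="right")
    ylabel = "leukocytes in band" if mode == "count" else "mean relative red intensity"
    ax.set_ylabel(f"{ylabel} (mean ± SEM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
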