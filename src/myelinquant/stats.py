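"""Condition-level statistics: Welch's t-test with Benjamini–Hochberg FDR.

The sampling unit is the image: each condition contributes one percentage
value per analysed field, and conditions are compared pairwise by Welch's
unequal-variance t-test (two-sided).  The family of comparisons — all
pairs, or every condition against a designated control — is corrected
jointly by the Benjamini–Hochberg step-up procedure, the standard false
discovery rate adjustment.

Missing metric values (fields with an empty neurite mask) are excluded
from means and tests and reported in the per-condition summary.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import ImageMeasurement

MetricName = Literal["pct_myelination", "pct_neurite_density"]


@dataclasses.dataclass
class ExperimentDesign:
    conditions: list[str]
    comparison_mode: Literal["all_pairs", "vs_control"] = "all_pairs"
    control_label: str | None = None
    metric: MetricName = "pct_myelination"

    def validate(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("an experiment needs at least 2 conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.comparison_mode == "vs_control":
            if self.control_label is None or self.control_label not in self.conditions:
                raise ValueError(
                    "vs_control mode requires control_label to be one of the conditions"
                )
        elif self.comparison_mode != "all_pairs":
            raise ValueError(f"unknown comparison_mode {self.comparison_mode!r}")

    def comparison_pairs(self) -> list[tuple[str, str]]:
        self.validate()
        if self.comparison_mode == "all_pairs":
            return list(itertools.combinations(self.conditions, 2))
        ctrl = self.control_label
        return [(ctrl, c) for c in self.conditions if c != ctrl]


@dataclasses.dataclass(frozen=True)
class StatResult:
    """One pairwise condition comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    df: float
    p_raw: float
    q_fdr: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Welch–Satterthwaite degrees of
    freedom.  Two samples with zero variance and equal means give
    ``t = 0, p = 1``; a zero-variance sample against a different mean gives
    a finite t with ``df = n_other - 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"Welch's t needs n >= 2 per sample, got {x.size} and {y.size}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples have zero variance but different means")
    if vx == 0.0 or vy == 0.0:
        # Satterthwaite limit: all weight on the non-degenerate sample
        se2 = vx / x.size + vy / y.size
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        df = float((y.size if vx == 0.0 else x.size) - 1)
        p = 2.0 * sps.t.sf(abs(t), df)
        return float(t), df, float(p)
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def _metric_values(
    measurements: Iterable[ImageMeasurement], condition: str, metric: MetricName
) -> np.ndarray:
    vals = [
        getattr(m, metric)
        for m in measurements
        if m.condition == condition and not math.isnan(getattr(m, metric))
    ]
    return np.asarray(vals, dtype=float)


def compare_conditions(
    measurements: Sequence[ImageMeasurement], design: ExperimentDesign
) -> list[StatResult]:
    """All configured pairwise Welch tests with a joint FDR family.

    The FDR family is exactly the emitted comparisons: C(k, 2) in
    ``all_pairs`` mode, k - 1 in ``vs_control`` mode.
    """
    design.validate()
    samples = {c: _metric_values(measurements, c, design.metric) for c in design.conditions}
    for c, v in samples.items():
        if v.size < 2:
            raise ValueError(
                f"condition {c!r} has only {v.size} non-missing {design.metric} "
                "measurements; at least 2 are required"
            )
    pairs = design.comparison_pairs()
    raw = []
    for a, b in pairs:
        t, df, p = welch_t(samples[a], samples[b])
        raw.append((a, b, t, df, p))
    q = fdr_adjust([r[4] for r in raw])
    return [
        StatResult(
            group_a=a,
            group_b=b,
            n_a=int(samples[a].size),
            n_b=int(samples[b].size),
            mean_a=float(samples[a].mean()),
            mean_b=float(samples[b].mean()),
            t_statistic=t,
            df=df,
            p_raw=p,
            q_fdr=qi,
        )
        for (a, b, t, df, p), qi in zip(raw, q)
    ]


def summarize_conditions(
    measurements: Sequence[ImageMeasurement], design: ExperimentDesign
) -> pd.DataFrame:
    """Per-condition table: n, mean, sd, sem and missing count for the metric."""
    rows = []
    for c in design.conditions:
        vals = _metric_values(measurements, c, design.metric)
        n_total = sum(1 for m in measurements if m.condition == c)
        n = int(vals.size)
        rows.append(
            {
                "condition": c,
                "n": n,
                "mean": float(vals.mean()) if n else float("nan"),
                "sd": float(vals.std(ddof=1)) if n >= 2 else float("nan"),
                "sem": float(vals.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan"),
                "missing": n_total - n,
            }
        )
    return pd.DataFrame(rows, columns=["condition", "n", "mean", "sd", "sem", "missing"])


def results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """Stats results as a DataFrame (the stats CSV schema)."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=[
            "group_a",
            "group_b",
            "n_a",
            "n_b",
            "mean_a",
            "mean_b",
            "t_statistic",
            "df",
            "p_raw",
            "q_fdr",
        ],
    )


def plot_comparison(
    measurements: Sequence[ImageMeasurement],
    design: ExperimentDesign,
    results: Sequence[StatResult],
    path,
    jitter_seed: int = 0,
) -> None:
    """Box-plus-jitter plot of the metric per condition, annotated with q-values.

    The file format follows the extension (png/svg/pdf).  Jitter is drawn
    from a seeded generator so repeated calls produce identical figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(jitter_seed)
    conditions = design.conditions
    data = [_metric_values(measurements, c, design.metric) for c in conditions]
    fig, ax = plt.subplots(figsize=(1.8 + 1.2 * len(conditions), 4.5))
    ax.boxplot(data, positions=range(len(conditions)), widths=0.5, showfliers=False)
    for i, vals in enumerate(data):
        if vals.size:
            ax.scatter(
                i + rng.uniform(-0.12, 0.12, size=vals.size),
                vals,
                s=12,
                alpha=0.7,
                color="tab:blue",
                zorder=3,
            )
    ax.set_xticks(range(len(conditions)))
    ax.set_xticklabels(conditions, rotation=20, ha="right")
    ax.set_ylabel(design.metric.replace("pct_", "% ").replace("_", " "))
    top = max((v.max() for v in data if v.size), default=1.0)
    span = max(top, 1.0)
    idx = {c: i for i, c in enumerate(conditions)}
    for k, r in enumerate(results):
        y = top + span * 0.08 * (k + 1)
        xa, xb = idx[r.group_a], idx[r.group_b]
        ax.plot([xa, xa, xb, xb], [y, y + span * 0.015, y + span * 0.015, y], color="k", lw=0.8)
        ax.text((xa + xb) / 2, y + span * 0.02, f"q = {r.q_fdr:.3g}", ha="center", fontsize=8)
    ax.set_ylim(top=top + span * 0.08 * (len(results) + 1.5))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
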