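"""Cross-run statistical validation and comparison reports.

Stability across independently seeded runs is compared with a two-sided
variance-ratio F-test (larger sample variance in the numerator) and mean
performance with Welch's unequal-variance t-test. Exploration breadth is
summarized as the percent improvement of a method's mean descriptor
distances over a baseline's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scoring_eval import MetricsRecord, aggregate_metrics, recall_sd


def pct_improvement(d_method: float, d_baseline: float) -> float:
    """100 * (d_method - d_baseline) / d_baseline; baseline must be > 0."""
    if d_baseline <= 0:
        raise ValueError("baseline distance must be positive")
    return 100.0 * (d_method - d_baseline) / d_baseline


def f_test_var(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided variance-equality F-test.

    The larger sample variance goes in the numerator; the two-sided p-value
    is 2 * min(cdf, sf) of the F distribution with the matching degrees of
    freedom, capped at 1. Two zero-variance samples give (1.0, 1.0).
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0, 1.0
    if va >= vb:
        f, dfn, dfd = va / max(vb, 1e-300), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / max(va, 1e-300), b.size - 1, a.size - 1
    p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
    return float(f), float(min(p, 1.0))


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite dof, two-sided p."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    se2 = va + vb
    if se2 == 0:
        return 0.0, float(a.size + b.size - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    dof = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(min(p, 1.0))


def significance_marker(p: float) -> str:
    """ns / * / ** at 0.05 and 0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonReport:
    metrics: dict[str, dict[str, dict[str, float]]]  # method -> metric -> {mean, sd}
    recall_sds: dict[str, float]
    improvements: dict[str, dict[str, float]]  # "A_vs_B" -> metric -> pct
    tests: dict[str, dict[str, float | str]]  # "A_vs_B" -> test results

    def to_json(self) -> str:
        return json.dumps(
            {
                "metrics": self.metrics,
                "recall_sds": self.recall_sds,
                "improvements": self.improvements,
                "tests": self.tests,
            },
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(
            metrics=d["metrics"],
            recall_sds=d["recall_sds"],
            improvements=d["improvements"],
            tests=d["tests"],
        )

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(self.to_json())
        rows = []
        for method, ms in sorted(self.metrics.items()):
            for metric, agg in sorted(ms.items()):
                rows.append((method, metric, agg["mean"], agg["sd"]))
        pd.DataFrame(rows, columns=["method", "metric", "mean", "sd"]).to_csv(
            path.with_suffix(".tsv"), sep="\t", index=False
        )


def build_comparison(
    runs_by_method: dict[str, list[MetricsRecord]],
    descriptor_means: dict[str, dict[str, float]] | None = None,
    baseline: str | None = None,
) -> ComparisonReport:
    """Aggregate per-method runs, compute Recall SD, distance improvements
    relative to ``baseline`` (default: last method alphabetically that is not
    the only method), and F/Welch tests on recall for each method pair."""
    if any(len(v) < 2 for v in runs_by_method.values()):
        raise ValueError("each method needs at least 2 runs")
    methods = sorted(runs_by_method)
    metrics = {
        m: {
            metric: {"mean": float(df.loc[metric, "mean"]), "sd": float(df.loc[metric, "sd"])}
            for metric in df.index
        }
        for m, df in ((m, aggregate_metrics(runs_by_method[m])) for m in methods)
    }
    recall_sds = {
        m: recall_sd([r.recall for r in runs_by_method[m]]) for m in methods
    }

    improvements: dict[str, dict[str, float]] = {}
    if descriptor_means:
        if baseline is None:
            baseline = sorted(descriptor_means)[-1]
        for m, dists in sorted(descriptor_means.items()):
            if m == baseline:
                continue
            improvements[f"{m}_vs_{baseline}"] = {
                metric: pct_improvement(dists[metric], descriptor_means[baseline][metric])
                for metric in sorted(dists)
            }

    tests: dict[str, dict[str, float | str]] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            ra = [r.recall for r in runs_by_method[a]]
            rb = [r.recall for r in runs_by_method[b]]
            fstat, fp = f_test_var(ra, rb)
            tstat, dof, tp = welch_t(ra, rb)
            tests[f"{a}_vs_{b}"] = {
                "f_statistic": fstat,
                "f_p": fp,
                "f_marker": significance_marker(fp),
                "welch_t": tstat,
                "welch_dof": dof,
                "welch_p": tp,
                "welch_marker": significance_marker(tp),
            }
    return ComparisonReport(
        metrics=metrics, recall_sds=recall_sds, improvements=improvements, tests=tests
    )
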