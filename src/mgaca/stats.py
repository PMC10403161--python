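"""Model-comparison statistics over per-model evaluation scores.

For each metric, the nine models' training and validation scores form matched
pairs; a paired t-test (df = n - 1, two-sided p) quantifies the
training-validation gap across models, and 95% confidence intervals describe
each metric's score distribution per split. The published interval bounds are
reproduced by the population (n-denominator) standard-deviation convention
combined with the Student-t critical value — this reverse-engineered
convention is the default, and the usual sample-sd interval is available via
``dispersion='sample'``.

Scores are handled on the percent scale exactly as published.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

METRIC_COLUMNS = ("accuracy", "iou", "dcs", "precision", "recall", "f1")
METRIC_LABELS = {
    "accuracy": "Accuracy",
    "precision": "Precision",
    "recall": "Recall",
    "f1": "F1-Score",
    "iou": "Intersection over union",
    "dcs": "Dice coefficient score",
}
SPLITS = ("training", "validation")


@dataclass(frozen=True)
class TTestResult:
    metric: str
    t_stat: float
    p_value: float
    df: int


@dataclass(frozen=True)
class ConfidenceInterval:
    metric: str
    split: str
    lower: float
    upper: float
    level: float = 0.95

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


class ScoreTable:
    """Per-model training/validation scores for the six pixel metrics."""

    def __init__(self, frame: pd.DataFrame):
        required = {"method", "split", *METRIC_COLUMNS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"score table is missing columns: {sorted(missing)}")
        bad_split = set(frame["split"]) - set(SPLITS)
        if bad_split:
            raise ValueError(f"unknown split labels: {sorted(bad_split)}")
        for method, grp in frame.groupby("method"):
            if sorted(grp["split"]) != sorted(SPLITS):
                raise ValueError(
                    f"method {method!r} must have exactly one training and "
                    "one validation row")
        for col in METRIC_COLUMNS:
            if frame[col].isna().any():
                row = frame[frame[col].isna()].iloc[0]
                raise ValueError(f"missing score: ({row['method']}, {col}, "
                                 f"{row['split']})")
        self.frame = frame.reset_index(drop=True)

    @property
    def methods(self):
        return list(dict.fromkeys(self.frame["method"]))

    def column(self, metric: str, split: str) -> np.ndarray:
        sub = self.frame[self.frame["split"] == split]
        sub = sub.set_index("method").loc[self.methods]
        return sub[metric].to_numpy(dtype=float)

    def pairs(self, metric: str) -> np.ndarray:
        return np.column_stack([self.column(metric, s) for s in SPLITS])

    def score(self, method: str, split: str, metric: str) -> float:
        sub = self.frame[(self.frame["method"] == method)
                         & (self.frame["split"] == split)]
        return float(sub[metric].iloc[0])


def build_score_table(source) -> ScoreTable:
    """Validate a CSV (path or file-like) of per-model metric scores."""
    return ScoreTable(pd.read_csv(source))


def published_score_table() -> ScoreTable:
    """The packaged published comparison of MGACA with eight architectures."""
    ref = importlib.resources.files("mgaca.data") / "published_scores.csv"
    with ref.open("r") as fh:
        return build_score_table(fh)


def paired_t_test(pairs, metric: str = "") -> TTestResult:
    """Two-sided paired t-test on (training, validation) score pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (training, validation) pairs")
    n = pairs.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = pairs[:, 0] - pairs[:, 1]
    if not d.any():
        # identical splits everywhere: no gap, t = 0 by convention
        return TTestResult(metric=metric, t_stat=0.0, p_value=1.0, df=n - 1)
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: t statistic undefined")
    t_stat, p_value = sps.ttest_rel(pairs[:, 0], pairs[:, 1])
    return TTestResult(metric=metric, t_stat=float(t_stat),
                       p_value=float(p_value), df=n - 1)


def confidence_interval(values, level: float = 0.95, metric: str = "",
                        split: str = "", dispersion: str = "population"
                        ) -> ConfidenceInterval:
    """Symmetric t-based interval around the sample mean.

    ``dispersion='population'`` (default) uses the n-denominator standard
    deviation, the convention that reproduces the published bounds;
    ``'sample'`` uses the usual n-1 denominator.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("confidence interval needs at least 2 values")
    if dispersion not in ("population", "sample"):
        raise ValueError("dispersion must be 'population' or 'sample'")
    sd = values.std(ddof=0 if dispersion == "population" else 1)
    t_crit = sps.t.ppf(0.5 + level / 2.0, n - 1)
    half = t_crit * sd / np.sqrt(n)
    mean = values.mean()
    return ConfidenceInterval(metric=metric, split=split,
                              lower=float(mean - half),
                              upper=float(mean + half), level=level)


def stats_report(table: ScoreTable, out_dir=None, level: float = 0.95,
                 dispersion: str = "population", boxplots: bool = False):
    """One paired t-test per metric and one CI per metric and split.

    Optionally writes ``ttests.csv``, ``confidence_intervals.csv`` and
    boxplot PNGs under ``out_dir``.
    """
    tests = [paired_t_test(table.pairs(m), metric=m) for m in METRIC_COLUMNS]
    intervals = [confidence_interval(table.column(m, s), level=level,
                                     metric=m, split=s, dispersion=dispersion)
                 for m in METRIC_COLUMNS for s in SPLITS]
    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([{"metric": METRIC_LABELS[t.metric], "t_stat": round(t.t_stat, 2),
                       "p_value": round(t.p_value, 5), "df": t.df}
                      for t in tests]).to_csv(out_dir / "ttests.csv", index=False)
        pd.DataFrame([{"metric": METRIC_LABELS[ci.metric], "split": ci.split,
                       "lower": round(ci.lower, 2), "upper": round(ci.upper, 2),
                       "level": ci.level}
                      for ci in intervals]).to_csv(
                          out_dir / "confidence_intervals.csv", index=False)
        if boxplots:
            _boxplots(table, out_dir)
    return tests, intervals


def _boxplots(table: ScoreTable, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(14, 8))
    for ax, metric in zip(axes.ravel(), METRIC_COLUMNS):
        data = [table.column(metric, s) for s in SPLITS]
        ax.boxplot(data, tick_labels=list(SPLITS))
        ax.set_title(METRIC_LABELS[metric])
        ax.set_ylabel("score (%)")
    fig.tight_layout()
    fig.savefig(out_dir / "score_boxplots.png", dpi=120)
    plt.close(fig)
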