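"""Evaluation indexes, the repeated-run comparison harness, and report tables.

Metrics are computed from a K x K confusion matrix (rows = true class,
columns = predicted): accuracy, unweighted macro precision/recall/F1,
Cohen's kappa, and Hamming loss (= 1 - accuracy for single-label
classification).  Kappa is the chance-corrected agreement

    kappa = (Po - Pe) / (1 - Pe),   Po = trace/n,
    Pe = sum_i a_i * b_i / n^2,

with a_i the true-class row sums and b_i the predicted-class column sums.

The harness re-splits and re-initializes per run (the two sources of
run-to-run variation in a repeated holdout protocol) and summarizes the
accuracy column as Max / Min / Ave / Var.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import OdorDataset, stratified_split, zero_center_dataset


class UndefinedKappaError(ZeroDivisionError):
    """Both marginals concentrate on a single class, so Pe = 1."""


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) integers, rows true, columns predicted
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricPanel:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    hamming_loss: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "hamming_loss": self.hamming_loss,
        }


def confusion(
    y_true: Sequence, y_pred: Sequence, class_names: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Count table: entry (i, j) is #(true class i, predicted class j).

    Labels may be class names or integer indices; ``class_names`` defaults
    to the sorted union of observed labels.
    """
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    if class_names is None:
        class_names = sorted({str(v) for v in y_true} | {str(v) for v in y_pred})
    class_names = [str(c) for c in class_names]
    index = {c: i for i, c in enumerate(class_names)}

    def to_idx(v):
        if isinstance(v, (int, np.integer)) and str(v) not in index:
            if 0 <= v < len(class_names):
                return int(v)
            raise ValueError(f"label index {v} out of range")
        if str(v) not in index:
            raise ValueError(f"unknown label {v!r}")
        return index[str(v)]

    k = len(class_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[to_idx(t), to_idx(p)] += 1
    return ConfusionMatrix(counts=counts, class_names=class_names)


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (Po - Pe) / (1 - Pe) for any K."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    a = cm.counts.sum(axis=1)  # true-class totals
    b = cm.counts.sum(axis=0)  # predicted-class totals
    po = np.trace(cm.counts) / n
    pe = float(a @ b) / (n * n)
    if pe == 1.0:
        raise UndefinedKappaError("Pe = 1: single-class truth and prediction")
    return float((po - pe) / (1.0 - pe))


def metric_panel(cm: ConfusionMatrix) -> MetricPanel:
    """Accuracy, unweighted macro precision/recall/F1, kappa, Hamming loss.

    Per-class values with a zero denominator (class never predicted, or
    absent from the truth) contribute 0 to the macro average.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    diag = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_k = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        rec_k = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        denom = prec_k + rec_k
        f1_k = np.where(denom > 0, 2 * prec_k * rec_k / np.where(denom > 0, denom, 1), 0.0)
    acc = float(diag.sum() / n)
    return MetricPanel(
        accuracy=acc,
        precision=float(prec_k.mean()),
        recall=float(rec_k.mean()),
        f1=float(f1_k.mean()),
        kappa=kappa(cm),
        hamming_loss=1.0 - acc,
    )


@dataclass
class RunRecord:
    run: int
    seed: int
    panel: MetricPanel


@dataclass
class RunReport:
    """Per-run metric records plus a Max/Min/Ave/Var accuracy summary."""

    records: list[RunRecord]
    variance_mode: str = "population"

    def accuracies(self) -> np.ndarray:
        return np.array([r.panel.accuracy for r in self.records])

    def summary(self) -> dict:
        acc = self.accuracies()
        ddof = 0 if self.variance_mode == "population" else 1
        var = float(acc.var(ddof=ddof)) if len(acc) > ddof else 0.0
        return {
            "max": float(acc.max()),
            "min": float(acc.min()),
            "ave": float(acc.mean()),
            "var": var,
        }

    def panel_table(self) -> pd.DataFrame:
        """Per-run metric panel (one row per run, metric columns)."""
        rows = [
            {"No.": r.run + 1, "Accuracy": r.panel.accuracy,
             "Precision": r.panel.precision, "Recall": r.panel.recall,
             "F1 Score": r.panel.f1, "Kappa": r.panel.kappa}
            for r in self.records
        ]
        return pd.DataFrame(rows)


def run_experiment(
    model_factory: Callable[[int], object],
    dataset: OdorDataset,
    n_runs: int = 10,
    test_fraction: float = 0.25,
    base_seed: int = 0,
    normalize: bool = True,
) -> RunReport:
    """Repeated stratified holdout evaluation.

    Run r re-splits the dataset with seed ``base_seed + r`` and builds a
    fresh model via ``model_factory(base_seed + r)``; the factory must
    return an object with ``fit(train_dataset)`` and
    ``predict(test_dataset) -> labels``.  Zero-centering is per sample, so
    applying it before splitting leaks nothing across the split.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    data = zero_center_dataset(dataset) if normalize else dataset
    records = []
    for r in range(n_runs):
        seed = base_seed + r
        train, test = stratified_split(data, test_fraction, seed=seed)
        try:
            model = model_factory(seed)
            model.fit(train)
            y_pred = np.asarray(model.predict(test))
        except Exception as e:
            raise RuntimeError(f"run {r} (seed {seed}) failed: {e}") from e
        cm = confusion(
            test.labels(), y_pred, class_names=list(range(len(data.class_names)))
        )
        records.append(RunRecord(run=r, seed=seed, panel=metric_panel(cm)))
    return RunReport(records=records)


def comparison_table(reports: list[tuple[str, RunReport]]) -> pd.DataFrame:
    """One row per model: the per-run accuracies then Max/Min/Ave/Var."""
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    n_runs = max(len(rep.records) for _, rep in reports)
    for name, rep in reports:
        row: dict = {"Models": name}
        for i, r in enumerate(rep.records):
            row[f"{_ordinal(i + 1)}"] = r.panel.accuracy
        s = rep.summary()
        row.update({"Max.": s["max"], "Min.": s["min"],
                    "Ave.": s["ave"], "Var.": s["var"]})
        rows.append(row)
    cols = ["Models"] + [_ordinal(i + 1) for i in range(n_runs)] + [
        "Max.", "Min.", "Ave.", "Var."]
    return pd.DataFrame(rows).reindex(columns=cols)


def _ordinal(i: int) -> str:
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(i % 10 if i % 100 not in (11, 12, 13) else 0, "th")
    return f"{i}{suffix}"


def render_table(df: pd.DataFrame, path: str | Path | None = None,
                 fmt: str = "csv") -> str:
    """Delimited (``csv``) or aligned (``text``) rendering; optionally written."""
    if fmt == "csv":
        out = df.to_csv(index=False, float_format="%.6g")
    elif fmt == "text":
        out = df.to_string(index=False, float_format=lambda v: f"{v:.4f}")
    else:
        raise ValueError("fmt must be 'csv' or 'text'")
    if path is not None:
        Path(path).write_text(out if out.endswith("\n") else out + "\n")
    return out


def decoded_overlay(model, samples, out_path, grid: bool = False) -> list[Path]:
    """Original-vs-reconstruction overlay figures.

    One two-panel figure per sample (original left, decoder output right,
    one line per sensor, shared y-axis), or a single n x 2 grid when
    ``grid`` is true.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    out_path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def panel(ax_l, ax_r, sample):
        x = sample.values
        xh = model.reconstruct(x)
        t = np.arange(x.shape[1]) * sample.sample_interval_s
        for s in range(x.shape[0]):
            ax_l.plot(t, x[s], lw=0.8, label=sample.sensor_names[s])
            ax_r.plot(t, xh[s], lw=0.8)
        lo = min(x.min(), xh.min())
        hi = max(x.max(), xh.max())
        for ax in (ax_l, ax_r):
            ax.set_ylim(lo - 0.05, hi + 0.05)
            ax.set_xlabel("time (s)")
        ax_l.set_title(f"input ({sample.label})")
        ax_r.set_title("decoded")

    if grid:
        fig, axes = plt.subplots(len(samples), 2, figsize=(8, 2.2 * len(samples)),
                                 squeeze=False)
        for i, sample in enumerate(samples):
            panel(axes[i][0], axes[i][1], sample)
        fig.tight_layout()
        p = out_path / "decoded_grid.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        for i, sample in enumerate(samples):
            fig, (ax_l, ax_r) = plt.subplots(1, 2, figsize=(8, 2.4))
            panel(ax_l, ax_r, sample)
            fig.tight_layout()
            p = out_path / f"decoded_{i:02d}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
    return written
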