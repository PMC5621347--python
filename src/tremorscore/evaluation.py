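"""Ordinal evaluation metrics for UPDRS tremor-severity predictions.

Severity is an ordinal 0-4 scale, so a prediction that misses by one class
is far less harmful than one that misses by three.  Besides plain accuracy,
the metrics here are built on the absolute classification error
``e = |predicted - true|``: its empirical CDF, the normalized area under
that CDF (NAuC), RMSE variants, and per-class recall/precision with Wald
confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

N_CLASSES = 5

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "abs_error",
    "error_cdf",
    "nauc",
    "rmse",
    "confusion",
    "errors_from_confusion",
    "class_metrics",
    "evaluate",
    "evaluate_confusion",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 count table; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"expected a {N_CLASSES}x{N_CLASSES} table, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.counts)


def _as_labels(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.size and (a.min() < 0 or a.max() > N_CLASSES - 1):
        raise ValueError(f"{name} must lie in 0..{N_CLASSES - 1}")
    return a.astype(int)


def abs_error(u, u_hat) -> np.ndarray:
    """Per-sample absolute classification error e = |predicted - true|."""
    u = _as_labels(u, "true labels")
    u_hat = _as_labels(u_hat, "predicted labels")
    if u.shape != u_hat.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {u_hat.shape}")
    return np.abs(u_hat - u)


def error_cdf(e) -> np.ndarray:
    """Empirical CDF of the error at x = 0..4: cdf[x] = P(e <= x)."""
    e = np.asarray(e, dtype=int)
    if e.size == 0:
        raise ValueError("cannot compute a CDF from zero samples")
    return np.array([(e <= x).mean() for x in range(N_CLASSES)])


def nauc(cdf) -> float:
    """Normalized area under the error CDF.

    Trapezoidal area over x in [0, 4] divided by the total area 4, so a
    perfect classifier (cdf identically 1) scores 1.0.
    """
    cdf = np.asarray(cdf, dtype=float)
    if cdf.shape != (N_CLASSES,):
        raise ValueError("cdf must have 5 points (x = 0..4)")
    return float(np.trapezoid(cdf, dx=1.0) / (N_CLASSES - 1))


def rmse(e, variant: str = "rms") -> float:
    """Root-mean-square error of the ordinal errors.

    variant "rms" is sqrt(mean(e^2)); variant "rms_over_n" is sqrt(sum(e^2))/n.
    Both are reported by :class:`EvalReport` under explicit labels.
    """
    e = np.asarray(e, dtype=float)
    if e.size == 0:
        raise ValueError("cannot compute RMSE from zero samples")
    if variant == "rms":
        return float(np.sqrt(np.mean(e**2)))
    if variant == "rms_over_n":
        return float(np.sqrt(np.sum(e**2)) / e.size)
    raise ValueError(f"unknown RMSE variant {variant!r}")


def confusion(u, u_hat) -> ConfusionMatrix:
    """Tally true/predicted label pairs into a 5x5 count table."""
    u = _as_labels(u, "true labels")
    u_hat = _as_labels(u_hat, "predicted labels")
    if u.shape != u_hat.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {u_hat.shape}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (u, u_hat), 1)
    return ConfusionMatrix(counts)


def errors_from_confusion(cm: ConfusionMatrix) -> np.ndarray:
    """Expand a confusion matrix back into the multiset of per-sample errors."""
    true_idx, pred_idx = np.indices(cm.counts.shape)
    e = np.abs(pred_idx - true_idx).ravel()
    return np.repeat(e, cm.counts.ravel())


def class_metrics(
    cm: ConfusionMatrix,
    z: float = 1.96,
    ci_n: str = "total",
):
    """Per-class recall and precision with Wald confidence-interval half-widths.

    ``ci_n="total"`` uses the grand total of the table as the Wald n for every
    interval; ``ci_n="class"`` uses the per-class row/column sum instead.
    A class that was never predicted has undefined precision, reported as
    ``None`` (never as 0 or NaN).
    """
    if ci_n not in ("total", "class"):
        raise ValueError(f"ci_n must be 'total' or 'class', got {ci_n!r}")
    n_total = cm.total
    recalls: list[float | None] = []
    precisions: list[float | None] = []
    recall_ci: list[float | None] = []
    precision_ci: list[float | None] = []

    def halfwidth(p: float, n: int) -> float:
        return float(z * np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")

    for c in range(N_CLASSES):
        row = int(cm.row_sums[c])
        col = int(cm.col_sums[c])
        diag = int(cm.counts[c, c])
        if row > 0:
            r = diag / row
            recalls.append(r)
            recall_ci.append(halfwidth(r, n_total if ci_n == "total" else row))
        else:
            recalls.append(None)
            recall_ci.append(None)
        if col > 0:
            p = diag / col
            precisions.append(p)
            precision_ci.append(halfwidth(p, n_total if ci_n == "total" else col))
        else:
            precisions.append(None)
            precision_ci.append(None)
    return recalls, precisions, recall_ci, precision_ci


@dataclass
class EvalReport:
    """Full evaluation summary derived from one set of ordinal predictions."""

    confusion: ConfusionMatrix
    accuracy: float
    accuracy_ci: float
    cdf: np.ndarray
    nauc: float
    rmse_variants: dict[str, float]
    recalls: list[float | None]
    precisions: list[float | None]
    recall_ci: list[float | None]
    precision_ci: list[float | None]
    n: int = field(default=0)

    def to_dict(self) -> dict:
        def opt(x):
            return None if x is None else float(x)

        return {
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_pct": 100.0 * self.accuracy,
            "accuracy_ci_halfwidth": self.accuracy_ci,
            "cdf": [float(v) for v in self.cdf],
            "nauc": self.nauc,
            "rmse": dict(self.rmse_variants),
            "recall": [opt(v) for v in self.recalls],
            "precision": [opt(v) for v in self.precisions],
            "recall_ci_halfwidth": [opt(v) for v in self.recall_ci],
            "precision_ci_halfwidth": [opt(v) for v in self.precision_ci],
            "confusion": self.confusion.counts.tolist(),
        }

    def to_text(self) -> str:
        lines = [
            f"n recordings          : {self.n}",
            f"accuracy              : {100 * self.accuracy:.2f}%  (+/- {100 * self.accuracy_ci:.2f})",
            "P(e <= x), x = 0..4   : " + "  ".join(f"{v:.4f}" for v in self.cdf),
            f"NAuC                  : {self.nauc:.3f}",
            "RMSE                  : "
            + "  ".join(f"{k}={v:.4f}" for k, v in self.rmse_variants.items()),
        ]

        def fmt(v, ci):
            if v is None:
                return "undefined"
            return f"{v:.3f} (+/- {ci:.3f})"

        for c in range(N_CLASSES):
            lines.append(
                f"class {c}: recall {fmt(self.recalls[c], self.recall_ci[c])}"
                f", precision {fmt(self.precisions[c], self.precision_ci[c])}"
            )
        lines.append("confusion matrix (rows true, cols predicted):")
        for row in self.confusion.counts:
            lines.append("  " + " ".join(f"{v:4d}" for v in row))
        return "\n".join(lines)


def _report_from(cm: ConfusionMatrix, e: np.ndarray, z: float, ci_n: str) -> EvalReport:
    cdf = error_cdf(e)
    acc = float(cdf[0])
    n = cm.total
    recalls, precisions, r_ci, p_ci = class_metrics(cm, z=z, ci_n=ci_n)
    return EvalReport(
        confusion=cm,
        accuracy=acc,
        accuracy_ci=float(z * np.sqrt(acc * (1 - acc) / n)),
        cdf=cdf,
        nauc=nauc(cdf),
        rmse_variants={"rms": rmse(e, "rms"), "rms_over_n": rmse(e, "rms_over_n")},
        recalls=recalls,
        precisions=precisions,
        recall_ci=r_ci,
        precision_ci=p_ci,
        n=n,
    )


def evaluate(u, u_hat, z: float = 1.96, ci_n: str = "total") -> EvalReport:
    """Build the full report from true and predicted labels."""
    cm = confusion(u, u_hat)
    return _report_from(cm, abs_error(u, u_hat), z, ci_n)


def evaluate_confusion(cm: ConfusionMatrix, z: float = 1.96, ci_n: str = "total") -> EvalReport:
    """Build the full report directly from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return _report_from(cm, errors_from_confusion(cm), z, ci_n)
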