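"""Error metrics and reports for surrogate and Redfield predictions.

The headline metric is the mean relative absolute error of predicted
transfer times against the reference engine,

    dtau = 100 * mean_i |t_pred,i - t_ref,i| / t_ref,i   [%],

reported separately for the training, validation and test splits.  Signed
deviations (t_ref - t_approx)/t_ref are positive when the approximation
underestimates the transfer time; the quadrant fraction is the share of
records where the network deviation is strictly smaller in magnitude than
the Redfield one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "mean_relative_absolute_error",
    "signed_relative_deviation",
    "quadrant_fraction",
    "EvaluationReport",
    "make_report",
    "export_histogram",
]


def mean_relative_absolute_error(predicted, reference) -> float:
    """100 * mean(|t_pred - t_ref| / t_ref); references must be positive."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size < 1:
        raise ValueError("predicted and reference must have equal length >= 1")
    if np.any(reference <= 0.0):
        raise ValueError("reference transfer times must be positive")
    return float(100.0 * np.mean(np.abs(predicted - reference) / reference))


def signed_relative_deviation(t_ref, t_approx):
    """(t_ref - t_approx) / t_ref; positive when the approximation is fast."""
    t_ref = np.asarray(t_ref, dtype=float)
    if np.any(t_ref <= 0.0):
        raise ValueError("reference transfer times must be positive")
    return (t_ref - np.asarray(t_approx, dtype=float)) / t_ref


def quadrant_fraction(network_dev, redfield_dev) -> float:
    """Share of records where |network| < |redfield| (ties are not wins)."""
    network_dev = np.asarray(network_dev, dtype=float)
    redfield_dev = np.asarray(redfield_dev, dtype=float)
    if network_dev.shape != redfield_dev.shape or network_dev.size < 1:
        raise ValueError("deviation arrays must have equal length >= 1")
    return float(np.mean(np.abs(network_dev) < np.abs(redfield_dev)))


@dataclass
class EvaluationReport:
    """Per-split transfer-time errors for each predictor, plus deviations."""

    per_split: dict           # {predictor: {split: dtau_percent}}
    quadrant: float | None    # network-beats-redfield fraction, if both present
    deviations: dict          # {predictor: list of signed deviations}
    counts: dict              # {split: n_records}

    def to_json(self, path=None) -> str:
        payload = {"per_split": self.per_split, "quadrant": self.quadrant,
                   "deviations": {k: list(v) for k, v in self.deviations.items()},
                   "counts": self.counts}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        splits = list(self.counts)
        lines = ["predictor  " + "  ".join(f"dtau_{s}[%]" for s in splits)]
        for predictor, errs in self.per_split.items():
            cells = "  ".join(f"{errs.get(s, float('nan')):10.2f}" for s in splits)
            lines.append(f"{predictor:<9}  {cells}")
        if self.quadrant is not None:
            lines.append(f"network better than redfield: {100 * self.quadrant:.1f}%")
        return "\n".join(lines)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(per_split=d["per_split"], quadrant=d["quadrant"],
                   deviations=d["deviations"], counts=d["counts"])


def make_report(records: pd.DataFrame, reference_col: str = "transfer_time_ps",
                predictions: dict | None = None) -> EvaluationReport:
    """Build the per-split error table from aligned prediction columns.

    ``predictions`` maps predictor names (e.g. ``network``, ``redfield``)
    to arrays of predicted transfer times aligned with ``records`` rows.
    """
    predictions = predictions or {}
    ref = records[reference_col].to_numpy()
    for name, pred in predictions.items():
        if len(pred) != len(records):
            raise ValueError(f"prediction '{name}' not aligned with records")

    splits = [s for s in ("train", "valid", "test", "pool")
              if (records["split"] == s).any()]
    per_split = {}
    deviations = {}
    for name, pred in predictions.items():
        pred = np.asarray(pred, dtype=float)
        per_split[name] = {
            s: mean_relative_absolute_error(pred[records["split"] == s],
                                            ref[records["split"] == s])
            for s in splits}
        deviations[name] = signed_relative_deviation(ref, pred).tolist()

    quad = None
    if "network" in predictions and "redfield" in predictions:
        quad = quadrant_fraction(deviations["network"], deviations["redfield"])
    counts = {s: int((records["split"] == s).sum()) for s in splits}
    return EvaluationReport(per_split=per_split, quadrant=quad,
                            deviations=deviations, counts=counts)


def export_histogram(values, path, bins=50) -> None:
    """Write (bin_left, bin_right, count) CSV for plotting."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins)
    out = np.column_stack([edges[:-1], edges[1:], counts])
    np.savetxt(path, out, delimiter=",", header="bin_left,bin_right,count",
               comments="")
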