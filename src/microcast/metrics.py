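"""Forecast error metrics: MAE, RMSE and NRMSE, with overfit diagnostics.

NRMSE here divides the RMSE by the standard deviation of the *predicted*
values (not the observed values, and not the range). This makes errors
comparable across genera whose abundances differ by orders of magnitude, and
it is the documented contract of this package even though other NRMSE
conventions exist. When the predictions are constant the quantity is
undefined and a sentinel (NaN) is returned rather than infinity.

The overfit diagnostic compares test-set metrics with training-set metrics:
a test/train ratio above the threshold (default 3.0) on any of MAE/RMSE flags
the fit as overfitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for metrics that are undefined on the given inputs.
NOT_DEFINED = float("nan")


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("empty input")
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    return obs, pred


def mae(observed, predicted) -> float:
    """Mean absolute error, pooled over all supplied cells."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean(np.abs(obs - pred)))


def rmse(observed, predicted) -> float:
    """Root mean squared error, pooled over all supplied cells."""
    obs, pred = _paired(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def nrmse(observed, predicted, ddof: int = 1) -> float:
    """RMSE divided by the standard deviation of the predicted values.

    Scale-free: rescaling both vectors by a common affine map leaves it
    unchanged. Returns NaN (with a log entry) when std(predicted) == 0.
    """
    obs, pred = _paired(observed, predicted)
    if pred.size < 2:
        raise ValueError("nrmse needs at least 2 predictions")
    denom = float(np.std(pred, ddof=ddof))
    if denom == 0.0:
        logger.info("nrmse undefined: constant predictions")
        return NOT_DEFINED
    return rmse(obs, pred) / denom


@dataclass
class MetricsReport:
    """MAE/RMSE/NRMSE per split, per genus, with overfit ratios."""

    per_split: dict = field(default_factory=dict)   # split -> {metric: value}
    per_genus: dict = field(default_factory=dict)   # split -> {genus: {metric: value}}
    overfit_ratios: dict = field(default_factory=dict)
    overfit_flag: bool = False
    overfit_threshold: float = 3.0

    def to_dict(self) -> dict:
        return {
            "per_split": self.per_split,
            "per_genus": self.per_genus,
            "overfit_ratios": self.overfit_ratios,
            "overfit_flag": self.overfit_flag,
            "overfit_threshold": self.overfit_threshold,
        }

    def display(self, ndigits: int = 2) -> str:
        lines = []
        for split, vals in self.per_split.items():
            cells = ", ".join(
                f"{k}={round(v, ndigits) if not math.isnan(v) else 'n/d'}"
                for k, v in vals.items()
            )
            lines.append(f"{split}: {cells}")
        if self.overfit_ratios:
            lines.append(
                f"overfit: {self.overfit_flag} (ratios "
                + ", ".join(
                    f"{k}={v if isinstance(v, str) else round(v, 2)}"
                    for k, v in self.overfit_ratios.items()
                )
                + f", threshold {self.overfit_threshold})"
            )
        return "\n".join(lines)


def split_metrics(observed: np.ndarray, predicted: np.ndarray, genera=None) -> dict:
    """Pooled and optional per-genus MAE/RMSE/NRMSE for one split."""
    pooled = {
        "mae": mae(observed, predicted),
        "rmse": rmse(observed, predicted),
        "nrmse": nrmse(observed, predicted),
    }
    by_genus = {}
    if genera is not None:
        obs = np.asarray(observed, dtype=float)
        pred = np.asarray(predicted, dtype=float)
        for j, g in enumerate(genera):
            by_genus[g] = {
                "mae": mae(obs[:, j], pred[:, j]),
                "rmse": rmse(obs[:, j], pred[:, j]),
                "nrmse": nrmse(obs[:, j], pred[:, j]),
            }
    return {"pooled": pooled, "per_genus": by_genus}


def overfit_diagnostic(
    train: dict, test: dict, threshold: float = 3.0
) -> tuple[bool, dict]:
    """Flag overfitting when test/train MAE or RMSE exceeds ``threshold``.

    ``train`` and ``test`` map metric names to values. A zero train metric
    yields an "undefined" ratio; the flag is then decided on the remaining
    metrics.
    """
    ratios: dict = {}
    flag = False
    for metric in ("mae", "rmse"):
        if metric not in train or metric not in test:
            continue
        if train[metric] == 0:
            ratios[metric] = "undefined"
            continue
        r = test[metric] / train[metric]
        ratios[metric] = r
        if r > threshold:
            flag = True
    return flag, ratios


def build_report(
    observed_by_split: dict,
    predicted_by_split: dict,
    genera=None,
    overfit_threshold: float = 3.0,
) -> MetricsReport:
    """Assemble a full :class:`MetricsReport` over the available splits."""
    report = MetricsReport(overfit_threshold=overfit_threshold)
    for split, obs in observed_by_split.items():
        res = split_metrics(obs, predicted_by_split[split], genera)
        report.per_split[split] = res["pooled"]
        if res["per_genus"]:
            report.per_genus[split] = res["per_genus"]
    if "train" in report.per_split and "test" in report.per_split:
        report.overfit_flag, report.overfit_ratios = overfit_diagnostic(
            report.per_split["train"], report.per_split["test"], overfit_threshold
        )
    return report
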