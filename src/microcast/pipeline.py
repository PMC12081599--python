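"""End-to-end wiring: prepare data, train ensembles, build intervals, score.

This layer owns the bookkeeping the individual modules deliberately avoid:
carving the series into chronological partitions, fitting the scaler on the
training block only, appending scaled covariate columns, keeping the lag rows
of context needed to forecast the head of each partition, and converting
everything back to absolute abundances for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from microcast.ensemble import (
    EnsembleConfig,
    EnsembleForecast,
    OutlierReport,
    build_interval,
    detect_outliers,
    ensemble_forecast,
    train_ensemble,
)
from microcast.forecasters import FittedForecaster
from microcast.io import AbundanceSeries, SampleMetadata, filter_sick_days
from microcast.metrics import MetricsReport, build_report
from microcast.preprocess import (
    ScalerParams,
    SplitSpec,
    WindowConfig,
    WindowedDataset,
    chronological_split,
    fit_covariate_scaler,
    fit_scaler,
    make_windows,
    transform,
)


@dataclass
class PreparedData:
    """Partitions, scaler and windowed datasets for one series."""

    series: AbundanceSeries
    train: AbundanceSeries
    validation: AbundanceSeries
    test: AbundanceSeries
    scaler: ScalerParams
    covariate_scaler: ScalerParams | None
    windows: dict                      # split -> WindowedDataset
    window_cfg: WindowConfig
    split: SplitSpec
    meta: SampleMetadata | None = None

    def scaled_matrix(self, part: AbundanceSeries) -> np.ndarray:
        """Genus columns scaled to [0,1], covariate columns appended."""
        values = transform(part, self.scaler).counts
        if self.window_cfg.covariate_names:
            cov = self.meta.covariates_for(part.sample_ids)[
                self.window_cfg.covariate_names
            ].to_numpy(dtype=float)
            cov = transform(cov, self.covariate_scaler)
            values = np.hstack([values, cov])
        return values

    def history_with_context(self, part_name: str) -> np.ndarray:
        """Scaled matrix of a partition preceded by its lag rows of context."""
        order = ["train", "validation", "test"]
        parts = {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
        }
        idx = order.index(part_name)
        context_rows = []
        lag = self.window_cfg.lag
        for earlier in order[:idx]:
            if parts[earlier].n_samples:
                context_rows.append(self.scaled_matrix(parts[earlier]))
        target = self.scaled_matrix(parts[part_name])
        if context_rows:
            context = np.vstack(context_rows)[-lag:]
            return np.vstack([context, target])
        return target


def prepare(
    series: AbundanceSeries,
    meta: SampleMetadata | None = None,
    window: WindowConfig | None = None,
    split: SplitSpec | None = None,
    exclude_sick_days: bool = True,
) -> PreparedData:
    """Filter, split, scale and window a series for model fitting."""
    window = window or WindowConfig()
    split = split or SplitSpec()
    if meta is not None and exclude_sick_days:
        series = filter_sick_days(series, meta)
    train, val, test = chronological_split(series, split, window=None)
    scaler = fit_scaler(series, split)
    cov_scaler = None
    if window.covariate_names:
        if meta is None:
            raise ValueError("covariates configured but no metadata supplied")
        cov_scaler = fit_covariate_scaler(meta, train.sample_ids)
        cov_scaler = ScalerParams(
            minimum=cov_scaler.minimum[window.covariate_names],
            maximum=cov_scaler.maximum[window.covariate_names],
            fitted_on=cov_scaler.fitted_on,
        )
    windows = {}
    for name, part in (("train", train), ("validation", val), ("test", test)):
        if part.n_samples <= window.lag + window.horizon - 1:
            continue
        scaled = transform(part, scaler)
        windows[name] = make_windows(scaled, window, meta, cov_scaler)
    if "train" not in windows:
        raise ValueError("training partition too short to form windows")
    return PreparedData(
        series=series,
        train=train,
        validation=val,
        test=test,
        scaler=scaler,
        covariate_scaler=cov_scaler,
        windows=windows,
        window_cfg=window,
        split=split,
        meta=meta,
    )


@dataclass
class DetectionResult:
    interval: EnsembleForecast          # absolute scale, test rows
    report: OutlierReport
    members: list = field(default_factory=list)


def detect_on_test(
    prepared: PreparedData,
    ensemble_cfg: EnsembleConfig,
    backend_config,
    mode: str = "teacher_forced",
    members: list[FittedForecaster] | None = None,
) -> DetectionResult:
    """Train an ensemble and flag test-set observations outside its interval."""
    if members is None:
        members = train_ensemble(
            ensemble_cfg,
            backend_config,
            prepared.windows["train"],
            prepared.windows.get("validation"),
        )
    history = prepared.history_with_context("test")
    steps = prepared.test.n_samples
    future_cov = None
    if mode == "iterative" and prepared.window_cfg.covariate_names:
        future_cov = prepared.scaled_matrix(prepared.test)[
            :, prepared.test.n_genera :
        ]
    preds = ensemble_forecast(members, history, steps, mode, future_cov)
    interval = build_interval(preds, ensemble_cfg,
                              genus_names=prepared.test.genera)
    interval_abs = interval.to_absolute(prepared.scaler)
    report = detect_outliers(prepared.test, interval_abs)
    return DetectionResult(interval=interval_abs, report=report, members=members)


def evaluate_model(
    prepared: PreparedData,
    model: FittedForecaster,
    overfit_threshold: float = 3.0,
    mode: str = "teacher_forced",
) -> MetricsReport:
    """Teacher-forced predictions per split, scored on the absolute scale."""
    from microcast.forecasters import forecast
    from microcast.preprocess import inverse_transform

    observed, predicted = {}, {}
    parts = {
        "train": prepared.train,
        "validation": prepared.validation,
        "test": prepared.test,
    }
    lag = prepared.window_cfg.lag
    for name, part in parts.items():
        if part.n_samples == 0:
            continue
        history = prepared.history_with_context(name)
        n_context = len(history) - part.n_samples
        # rows that have a full observed lag window behind them
        steps = len(history) - max(lag, n_context)
        if steps < 1:
            continue
        pred_scaled = forecast(model, history, steps, mode="teacher_forced")
        pred_abs = inverse_transform(pred_scaled, prepared.scaler)
        observed[name] = part.counts[-steps:]
        predicted[name] = pred_abs
    return build_report(
        observed, predicted, genera=prepared.series.genera,
        overfit_threshold=overfit_threshold,
    )
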