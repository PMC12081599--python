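"""Scaling, chronological splitting and lag-window framing.

Abundances are min-max scaled per genus into [0, 1] using parameters fitted on
the training partition only (fitting on the full series would leak test
information into the downstream outlier test). The scaled series is framed as
supervised examples: the input at step ``t`` is the ``lag`` preceding rows
(genera plus any configured covariate columns) and the target is row ``t`` over
all genera. Splits are contiguous blocks in time order — train, then
validation, then test — with no shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microcast.io import AbundanceSeries, SampleMetadata


@dataclass
class SplitSpec:
    """Chronological split proportions.

    ``train_val_fraction`` of the series (default 0.8) forms the train+val
    block, the remainder is the test block; the final
    ``val_fraction_of_train`` of the train+val block (default 0.1) is held out
    for early stopping.
    """

    train_val_fraction: float = 0.8
    val_fraction_of_train: float = 0.1

    def __post_init__(self):
        if not 0 < self.train_val_fraction < 1:
            raise ValueError("train_val_fraction must be in (0, 1)")
        if not 0 <= self.val_fraction_of_train < 1:
            raise ValueError("val_fraction_of_train must be in [0, 1)")

    def boundaries(self, n: int) -> tuple[int, int]:
        """Return (end of train, end of validation) row positions."""
        n_trainval = int(np.floor(self.train_val_fraction * n))
        n_val = int(np.floor(self.val_fraction_of_train * n_trainval))
        return n_trainval - n_val, n_trainval


@dataclass
class WindowConfig:
    """Lag-window framing: ``lag`` preceding steps predict the next row."""

    lag: int = 3
    horizon: int = 1
    covariate_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


@dataclass
class ScalerParams:
    """Per-genus min/max for the [0, 1] transform and its inverse.

    A constant (degenerate) genus — typically one zero-filled during
    harmonization — maps to 0.0 under the transform and back to its constant
    under the inverse.
    """

    minimum: pd.Series
    maximum: pd.Series
    fitted_on: str = "train"

    def __post_init__(self):
        if not self.minimum.index.equals(self.maximum.index):
            raise ValueError("min/max genus axes differ")
        if (self.maximum < self.minimum).any():
            bad = self.maximum.index[self.maximum < self.minimum][0]
            raise ValueError(f"max < min for genus {bad!r}")

    @property
    def genera(self) -> list:
        return list(self.minimum.index)

    @property
    def degenerate(self) -> pd.Series:
        """Boolean mask of constant genera (max == min)."""
        return self.maximum == self.minimum

    @property
    def span(self) -> pd.Series:
        return self.maximum - self.minimum

    def content_hash(self) -> str:
        import hashlib

        payload = repr(
            (list(self.minimum.index), self.minimum.to_list(), self.maximum.to_list())
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def chronological_split(
    series: AbundanceSeries,
    split: SplitSpec | None = None,
    window: WindowConfig | None = None,
) -> tuple[AbundanceSeries, AbundanceSeries, AbundanceSeries]:
    """Split into contiguous (train, validation, test) blocks in time order.

    When a :class:`WindowConfig` is given, each non-empty partition must be
    long enough to form at least one window (``lag + horizon`` rows).
    """
    split = split or SplitSpec()
    n = series.n_samples
    i_train, i_val = split.boundaries(n)
    parts = (
        series.select_rows(range(0, i_train)),
        series.select_rows(range(i_train, i_val)),
        series.select_rows(range(i_val, n)),
    )
    min_len = (window.lag + window.horizon) if window else 1
    for name, part in zip(("train", "validation", "test"), parts):
        if name == "validation" and split.val_fraction_of_train == 0:
            continue
        if part.n_samples < min_len:
            raise ValueError(
                f"{name} partition has {part.n_samples} samples; "
                f"minimum is {min_len} (lag + horizon)"
            )
    return parts


def fit_scaler(series: AbundanceSeries, split: SplitSpec | None = None) -> ScalerParams:
    """Fit per-genus min/max on the training partition only."""
    split = split or SplitSpec()
    i_train, _ = split.boundaries(series.n_samples)
    if i_train < 1:
        raise ValueError("empty training partition")
    train = series.data.iloc[:i_train]
    return ScalerParams(
        minimum=train.min(axis=0).astype(float),
        maximum=train.max(axis=0).astype(float),
        fitted_on=f"train[0:{i_train}]",
    )


def _check_axes(genera, params: ScalerParams):
    unseen = [g for g in genera if g not in params.minimum.index]
    if unseen:
        raise KeyError(f"genera not seen by the scaler: {unseen}")
    if len(genera) != len(params.minimum):
        missing = [g for g in params.genera if g not in set(genera)]
        raise KeyError(f"series is missing fitted genera: {missing}")


def transform(series: AbundanceSeries | np.ndarray, params: ScalerParams):
    """Map abundances to the scaled space: (x - min) / (max - min) per genus.

    Values outside the fitted range are NOT clipped — test-set excursions must
    stay visible to the outlier detector. Arrays are assumed column-aligned
    with ``params.genera``.
    """
    if isinstance(series, AbundanceSeries):
        _check_axes(series.genera, params)
        lo = params.minimum.reindex(series.genera)
        span = params.span.reindex(series.genera)
        values = series.counts
    else:
        values = np.asarray(series, dtype=float)
        lo = params.minimum
        span = params.span
    span_arr = span.to_numpy(dtype=float)
    safe = np.where(span_arr == 0, 1.0, span_arr)
    scaled = (values - lo.to_numpy(dtype=float)) / safe
    scaled = np.where(span_arr == 0, 0.0, scaled)
    if isinstance(series, AbundanceSeries):
        return series.with_counts(scaled)
    return scaled


def inverse_transform(scaled: AbundanceSeries | np.ndarray, params: ScalerParams):
    """Map scaled values back to absolute abundances (exact inverse).

    Monotone per genus, so prediction-interval bounds may be back-transformed
    directly. Degenerate genera return their training constant.
    """
    if isinstance(scaled, AbundanceSeries):
        _check_axes(scaled.genera, params)
        lo = params.minimum.reindex(scaled.genera).to_numpy(dtype=float)
        span = params.span.reindex(scaled.genera).to_numpy(dtype=float)
        values = scaled.counts
    else:
        values = np.asarray(scaled, dtype=float)
        lo = params.minimum.to_numpy(dtype=float)
        span = params.span.to_numpy(dtype=float)
    absolute = np.where(span == 0, lo, values * span + lo)
    if isinstance(scaled, AbundanceSeries):
        return scaled.with_counts(absolute)
    return absolute


@dataclass
class WindowedDataset:
    """Supervised lag-window examples.

    ``X`` has shape (n_windows, lag, width) where width = n_genera +
    n_covariates; ``y`` has shape (n_windows, n_genera). ``target_positions``
    holds the row position of each target within the source partition.
    """

    X: np.ndarray
    y: np.ndarray
    genus_names: list
    covariate_names: list
    lag: int
    target_positions: np.ndarray
    target_timestamps: list

    def __post_init__(self):
        if self.X.ndim != 3 or self.y.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("inconsistent window shapes")

    @property
    def n_windows(self) -> int:
        return len(self.X)

    @property
    def width(self) -> int:
        return self.X.shape[2]

    @property
    def n_genera(self) -> int:
        return self.y.shape[1]

    @property
    def X_flat(self) -> np.ndarray:
        """Windows flattened to (n, lag * width) for tabular learners."""
        return self.X.reshape(len(self.X), -1)


def fit_covariate_scaler(
    meta: SampleMetadata, train_sample_ids: list
) -> ScalerParams:
    """Min-max parameters for covariate columns, fitted on training samples."""
    cov = meta.covariates_for(train_sample_ids).astype(float)
    return ScalerParams(
        minimum=cov.min(axis=0), maximum=cov.max(axis=0), fitted_on="train-covariates"
    )


def make_windows(
    scaled: AbundanceSeries,
    cfg: WindowConfig | None = None,
    covariates: SampleMetadata | None = None,
    covariate_scaler: ScalerParams | None = None,
) -> WindowedDataset:
    """Frame a scaled partition as (lag-window, next-row) pairs.

    For each ``t`` in ``[lag, T - horizon + 1)`` the input is rows
    ``[t - lag, t)`` over all genera (plus covariate columns aligned to those
    rows when configured) and the target is row ``t + horizon - 1`` over all
    genera — so with the default horizon the window count is ``T - lag``.
    """
    cfg = cfg or WindowConfig()
    T = scaled.n_samples
    if T <= cfg.lag + cfg.horizon - 1:
        raise ValueError(
            f"partition of length {T} cannot form a window with "
            f"lag={cfg.lag}, horizon={cfg.horizon}"
        )
    values = scaled.counts
    if cfg.covariate_names:
        if covariates is None:
            raise ValueError("covariate_names configured but no metadata given")
        try:
            cov = covariates.covariates_for(scaled.sample_ids)[cfg.covariate_names]
        except KeyError as exc:
            raise ValueError(f"covariate missing within windows: {exc}") from exc
        if cov.isna().any().any():
            sid = cov.index[cov.isna().any(axis=1)][0]
            pos = scaled.sample_ids.index(sid)
            raise ValueError(
                f"covariate missing for sample {sid!r} at timestamp "
                f"{scaled.timestamps[pos]!r}"
            )
        cov_values = cov.to_numpy(dtype=float)
        if covariate_scaler is not None:
            cov_values = transform(cov_values, covariate_scaler)
        values = np.hstack([values, cov_values])
    G = scaled.n_genera
    starts = range(0, T - cfg.lag - cfg.horizon + 1)
    X = np.stack([values[s : s + cfg.lag] for s in starts])
    targets = np.array([s + cfg.lag + cfg.horizon - 1 for s in starts])
    y = scaled.counts[targets]
    return WindowedDataset(
        X=X,
        y=y,
        genus_names=scaled.genera,
        covariate_names=list(cfg.covariate_names),
        lag=cfg.lag,
        target_positions=targets,
        target_timestamps=[scaled.timestamps[int(t)] for t in targets],
    )
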