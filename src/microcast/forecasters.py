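"""Forecaster backends behind one contract: recurrent nets, random forest, VARMA.

All backends consume lag windows over the scaled genus matrix (plus optional
covariate columns) and emit one row of genus predictions per step. The
recurrent backends are single- or multi-layer LSTM/GRU networks trained with
Adam on an MAE loss with dropout and early stopping; the random forest
flattens the lag window into a feature vector and fits a multi-output
regressor with 100 trees and the absolute-error split criterion; the VARMA
baseline tests each genus column for a unit root (augmented Dickey-Fuller),
applies first-order differencing when needed, grid-searches (p, q) by AIC and
fits with a configurable deterministic trend.

Multi-step prediction comes in two modes: ``teacher_forced`` (one-step-ahead,
every lag window holds observed rows) and ``iterative`` (predictions are fed
back into the lag window, as used for trajectory plots).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from microcast._rnn import RecurrentNet
from microcast.preprocess import WindowedDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class RecurrentConfig:
    """Architecture and training settings for the LSTM/GRU backends.

    Defaults follow the reference architecture: one recurrent layer with 2048
    cells, ReLU activation, dropout, Adam optimizer with MAE loss, and early
    stopping on the validation loss. ``patience=None`` disables early
    stopping.
    """

    cell_type: str = "lstm"
    layers: int = 1
    cells: int = 2048
    activation: str = "relu"
    dropout_rate: float = 0.2
    optimizer: str = "adam"
    loss: str = "mae"
    patience: int | None = 10
    max_epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.cell_type not in ("lstm", "gru"):
            raise ValueError(f"cell_type must be lstm|gru, got {self.cell_type!r}")
        if self.cells < 1 or self.layers < 1:
            raise ValueError("cells and layers must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss.lower() != "mae":
            raise ValueError("only the mae loss is supported")


@dataclass
class RfConfig:
    """Random-forest backend: 100 trees, absolute-error split criterion."""

    n_trees: int = 100
    split_criterion: str = "absolute_error"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        aliases = {"mae": "absolute_error", "mse": "squared_error"}
        self.split_criterion = aliases.get(
            self.split_criterion.lower(), self.split_criterion
        )


@dataclass
class VarmaConfig:
    """VARMA baseline: unit-root testing, differencing, (p, q) grid search."""

    p: int | None = None
    d: int | None = None
    q: int | None = None
    trend: str = "linear-time"
    grid_p: Sequence[int] = (0, 1, 2, 3)
    grid_q: Sequence[int] = (0, 1, 2, 3)
    stationarity_alpha: float = 0.05
    min_variance: float = 1e-12
    maxiter: int = 100

    _TREND_MAP = {"none": "n", "constant": "c", "linear-time": "ct"}

    def __post_init__(self):
        for v in (self.p, self.d, self.q):
            if v is not None and v < 0:
                raise ValueError("p, d, q must be >= 0")
        if self.trend not in self._TREND_MAP:
            raise ValueError(f"trend must be one of {list(self._TREND_MAP)}")
        if not list(self.grid_p) or not list(self.grid_q):
            raise ValueError("grid must be non-empty")

    @property
    def statsmodels_trend(self) -> str:
        return self._TREND_MAP[self.trend]


# ---------------------------------------------------------------------------
# fitted forecasters
# ---------------------------------------------------------------------------


class FittedForecaster:
    """Uniform surface over the fitted backends.

    Attributes: ``backend`` tag, ``lag``, ``width`` (genera + covariates),
    ``genus_names``, and a per-backend ``training_log``.
    """

    backend: str = "base"

    def __init__(self, lag: int, genus_names: list, covariate_names: list):
        self.lag = lag
        self.genus_names = list(genus_names)
        self.covariate_names = list(covariate_names)
        self.training_log: dict = {}

    @property
    def n_genera(self) -> int:
        return len(self.genus_names)

    @property
    def width(self) -> int:
        return self.n_genera + len(self.covariate_names)

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _check_window(self, window: np.ndarray) -> np.ndarray:
        window = np.asarray(window, dtype=float)
        if window.shape != (self.lag, self.width):
            raise ValueError(
                f"window shape {window.shape} != (lag={self.lag}, "
                f"width={self.width})"
            )
        if np.isnan(window).any():
            raise ValueError("NaN in prediction window")
        return window


class RandomForestForecaster(FittedForecaster):
    backend = "rf"

    def __init__(self, model, lag, genus_names, covariate_names):
        super().__init__(lag, genus_names, covariate_names)
        self.model = model

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        flat = X.reshape(len(X), -1)
        pred = self.model.predict(flat)
        return pred.reshape(len(X), self.n_genera)


class RecurrentForecaster(FittedForecaster):
    backend = "recurrent"

    def __init__(self, net: RecurrentNet, lag, genus_names, covariate_names):
        super().__init__(lag, genus_names, covariate_names)
        self.net = net
        self.training_log = {
            "loss": net.history["loss"],
            "val_loss": net.history["val_loss"],
            "stopped_epoch": net.stopped_epoch,
        }

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(np.asarray(X, dtype=float))


class CallableForecaster(FittedForecaster):
    """Wrap a plain function of the lag window; used for mocks and oracles."""

    backend = "callable"

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], lag,
                 genus_names, covariate_names=()):
        super().__init__(lag, genus_names, list(covariate_names))
        self.fn = fn

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        return np.stack([np.asarray(self.fn(w), dtype=float) for w in X])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    config: RecurrentConfig | RfConfig,
    windows: WindowedDataset,
    validation: WindowedDataset | None = None,
) -> FittedForecaster:
    """Fit a windowed backend (recurrent or random forest)."""
    if isinstance(config, RfConfig):
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(
            n_estimators=config.n_trees,
            criterion=config.split_criterion,
            random_state=config.seed,
            n_jobs=1,
        )
        model.fit(windows.X_flat, windows.y)
        out = RandomForestForecaster(
            model, windows.lag, windows.genus_names, windows.covariate_names
        )
        out.training_log = {
            "train_mae": float(
                np.mean(np.abs(model.predict(windows.X_flat) - windows.y))
            )
        }
        return out
    if isinstance(config, RecurrentConfig):
        if config.patience is not None and (
            validation is None or validation.n_windows == 0
        ):
            raise ValueError("early stopping enabled but validation set is empty")
        net = RecurrentNet(
            cell_type=config.cell_type,
            input_dim=windows.width,
            hidden=config.cells,
            output_dim=windows.n_genera,
            layers=config.layers,
            activation=config.activation,
            dropout=config.dropout_rate,
            seed=config.seed,
        )
        net.fit(
            windows.X,
            windows.y,
            X_val=validation.X if validation is not None else None,
            y_val=validation.y if validation is not None else None,
            max_epochs=config.max_epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            patience=config.patience if config.patience is not None
            else config.max_epochs,
        )
        return RecurrentForecaster(
            net, windows.lag, windows.genus_names, windows.covariate_names
        )
    raise TypeError(f"unsupported config type {type(config).__name__}")


# ---------------------------------------------------------------------------
# VARMA
# ---------------------------------------------------------------------------


def check_stationarity(matrix: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Augmented Dickey-Fuller per column; True where stationary at ``alpha``.

    Constant columns carry no unit root and are reported stationary.
    """
    from statsmodels.tsa.stattools import adfuller

    matrix = np.asarray(matrix, dtype=float)
    out = np.zeros(matrix.shape[1], dtype=bool)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        if np.ptp(col) == 0:
            out[j] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvalue = adfuller(col, autolag="AIC")[1]
        out[j] = pvalue < alpha
    return out


class VarmaForecaster(FittedForecaster):
    """Fitted VARMA model with differencing bookkeeping.

    Predictions are made on the (possibly differenced) scale and integrated
    back to levels. Genera dropped by the variance filter are forecast as
    their training mean.
    """

    backend = "varma"

    def __init__(self, results, cfg: VarmaConfig, d: int, order: tuple,
                 genus_names, active: np.ndarray, constants: np.ndarray,
                 last_level: np.ndarray):
        # context window: enough rows for the ARMA state after differencing
        super().__init__(lag=max(3, order[0] + d, order[1] + d),
                         genus_names=genus_names, covariate_names=[])
        self.results = results
        self.cfg = cfg
        self.d = d
        self.order = order
        self.active = active            # boolean mask of modelled genera
        self.constants = constants      # fill value for filtered-out genera
        self.last_level = last_level    # last observed row of training data
        self.training_log = {"aic": float(results.aic), "order": order, "d": d}

    def _expand(self, pred_active: np.ndarray) -> np.ndarray:
        full = np.tile(self.constants, (len(pred_active), 1))
        full[:, self.active] = pred_active
        return full

    @property
    def _k(self) -> int:
        return int(self.active.sum())

    def _as_steps_by_k(self, fc, steps: int) -> np.ndarray:
        return np.asarray(fc, dtype=float).reshape(steps, self._k)

    def forecast_from_training_end(self, steps: int) -> np.ndarray:
        """Out-of-sample forecast continuing the training series."""
        fc = self._as_steps_by_k(self.results.forecast(steps=steps), steps)
        if self.d == 1:
            fc = self.last_level[self.active] + np.cumsum(fc, axis=0)
        return self._expand(fc)

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        out = []
        for window in np.asarray(X, dtype=float):
            sub = window[:, self.active]
            endog = np.diff(sub, axis=0) if self.d == 1 else sub
            if self._k == 1:
                endog = endog[:, 0]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fc = self._as_steps_by_k(
                    self.results.apply(endog).forecast(steps=1), 1
                )
            if self.d == 1:
                fc = sub[-1] + fc
            out.append(self._expand(fc)[0])
        return np.stack(out)


def fit_varma(matrix: np.ndarray, cfg: VarmaConfig | None = None,
              genus_names: list | None = None) -> VarmaForecaster:
    """Fit the VARMA baseline on a scaled training matrix (T × G).

    Pipeline: per-column unit-root check at ``stationarity_alpha``; if any
    column is non-stationary, difference once (d=1) and re-test; select
    (p, q) from the grid by AIC (ties toward smaller p+q); fit with the
    configured deterministic trend. Near-constant columns are excluded by a
    variance filter and forecast as their mean.
    """
    from statsmodels.tsa.statespace.sarimax import SARIMAX
    from statsmodels.tsa.statespace.varmax import VARMAX

    cfg = cfg or VarmaConfig()
    matrix = np.asarray(matrix, dtype=float)
    T, G = matrix.shape
    if T < 20:
        raise ValueError(f"need >= 20 time points to fit VARMA, got {T}")
    genus_names = list(genus_names) if genus_names is not None else [
        f"g{j}" for j in range(G)
    ]
    variances = matrix.var(axis=0)
    active = variances > cfg.min_variance
    if not active.all():
        logger.warning(
            "variance filter dropped %d near-constant genera", int((~active).sum())
        )
    if active.sum() < 1:
        raise ValueError("no genus with usable variance for VARMA")
    sub = matrix[:, active]
    if cfg.d is not None:
        d = cfg.d
    else:
        stationary = check_stationarity(sub, cfg.stationarity_alpha)
        d = 0 if stationary.all() else 1
        if d == 1:
            still_bad = ~check_stationarity(np.diff(sub, axis=0),
                                            cfg.stationarity_alpha)
            if still_bad.any():
                logger.warning(
                    "%d columns remain non-stationary after first differencing",
                    int(still_bad.sum()),
                )
    endog = np.diff(sub, axis=0) if d == 1 else sub
    if cfg.p is not None and cfg.q is not None:
        candidates = [(cfg.p, cfg.q)]
    else:
        candidates = [
            (p, q) for p in cfg.grid_p for q in cfg.grid_q if (p, q) != (0, 0)
        ]
        # ties toward the smaller p+q: evaluate small orders first, keep on <
        candidates.sort(key=lambda pq: (pq[0] + pq[1], pq[0], pq[1]))
    best = None
    for p, q in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if endog.shape[1] == 1:
                    # the vector model degenerates to ARMA for one series
                    res = SARIMAX(
                        endog[:, 0], order=(p, 0, q),
                        trend=cfg.statsmodels_trend,
                    ).fit(disp=False, maxiter=cfg.maxiter)
                else:
                    res = VARMAX(
                        endog, order=(p, q), trend=cfg.statsmodels_trend
                    ).fit(disp=False, maxiter=cfg.maxiter)
            aic = float(res.aic)
            if not np.isfinite(aic):
                continue
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.info("VARMA(%d,%d) failed: %s", p, q, exc)
            continue
        if best is None or aic < best[0]:
            best = (aic, (p, q), res)
    if best is None:
        raise RuntimeError("VARMA grid exhausted without a converged fit")
    _, order, results = best
    return VarmaForecaster(
        results=results,
        cfg=cfg,
        d=d,
        order=order,
        genus_names=genus_names,
        active=active,
        constants=matrix.mean(axis=0),
        last_level=matrix[-1],
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_step(model: FittedForecaster, last_window: np.ndarray) -> np.ndarray:
    """Predict one row of genus values from a single lag window."""
    window = model._check_window(last_window)
    pred = model.predict_batch(window[None, ...])[0]
    if not np.isfinite(pred).all():
        raise FloatingPointError("non-finite prediction")
    return pred


def forecast(
    model: FittedForecaster,
    history: np.ndarray,
    steps: int,
    mode: str = "teacher_forced",
    future_covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-step prediction in teacher-forced or iterative mode.

    ``history`` is a scaled (T × width) matrix, genus columns first, covariate
    columns (if any) last. Teacher-forced mode predicts the last ``steps``
    rows of ``history``, each from the observed lag rows preceding it —
    prediction at time t depends only on observations before t. Iterative
    mode starts after the end of ``history`` and feeds its own genus
    predictions back into the window; configured covariates must then be
    supplied for the future steps.
    """
    if steps <= 0:
        raise ValueError("steps must be positive")
    history = np.asarray(history, dtype=float)
    if history.ndim != 2 or history.shape[1] != model.width:
        raise ValueError(
            f"history width {history.shape} incompatible with model width "
            f"{model.width}"
        )
    lag = model.lag
    G = model.n_genera
    n_cov = model.width - G
    if mode == "teacher_forced":
        if len(history) < lag + steps:
            raise ValueError(
                f"teacher-forced forecast of {steps} steps needs at least "
                f"lag + steps = {lag + steps} history rows"
            )
        offset = len(history) - steps
        windows = np.stack(
            [history[offset + k - lag : offset + k] for k in range(steps)]
        )
        return model.predict_batch(windows)
    if mode == "iterative":
        if len(history) < lag:
            raise ValueError("history shorter than lag")
        if n_cov and (
            future_covariates is None or len(future_covariates) < steps
        ):
            raise ValueError(
                "iterative forecasting with covariates requires "
                "future_covariates for every step"
            )
        window = history[-lag:].copy()
        out = np.empty((steps, G))
        for k in range(steps):
            pred = predict_step(model, window)
            out[k] = pred
            new_row = np.empty(model.width)
            new_row[:G] = pred
            if n_cov:
                new_row[G:] = future_covariates[k]
            window = np.vstack([window[1:], new_row])
        return out
    raise ValueError(f"mode must be teacher_forced|iterative, got {mode!r}")


# ---------------------------------------------------------------------------
# save / load
# ---------------------------------------------------------------------------


def save_forecaster(model: FittedForecaster, directory, scaler_hash: str = "") -> None:
    """Persist a fitted model as a directory: config JSON + native weights."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "backend": model.backend,
        "lag": model.lag,
        "genus_names": model.genus_names,
        "covariate_names": model.covariate_names,
        "scaler_hash": scaler_hash,
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    if model.backend == "recurrent":
        np.savez(directory / "weights.npz", **model.net.get_params())
        (directory / "net.json").write_text(json.dumps(model.net.get_config()))
    elif model.backend == "rf":
        import joblib

        joblib.dump(model.model, directory / "model.joblib")
    elif model.backend == "varma":
        import pickle

        with open(directory / "varma.pkl", "wb") as fh:
            pickle.dump(
                {
                    "results": model.results,
                    "cfg": model.cfg,
                    "d": model.d,
                    "order": model.order,
                    "active": model.active,
                    "constants": model.constants,
                    "last_level": model.last_level,
                },
                fh,
            )
    else:
        raise ValueError(f"cannot save backend {model.backend!r}")


def load_forecaster(directory, expect_scaler_hash: str | None = None) -> FittedForecaster:
    """Load a saved model; optionally verify the scaler hash it was trained with."""
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    if expect_scaler_hash is not None and meta["scaler_hash"] != expect_scaler_hash:
        raise ValueError(
            "scaler hash mismatch: model was trained with a different scaling "
            f"({meta['scaler_hash']} != {expect_scaler_hash})"
        )
    if meta["backend"] == "recurrent":
        net_cfg = json.loads((directory / "net.json").read_text())
        with np.load(directory / "weights.npz") as blob:
            params = {k: blob[k] for k in blob.files}
        net = RecurrentNet.from_config(net_cfg, params)
        return RecurrentForecaster(
            net, meta["lag"], meta["genus_names"], meta["covariate_names"]
        )
    if meta["backend"] == "rf":
        import joblib

        model = joblib.load(directory / "model.joblib")
        return RandomForestForecaster(
            model, meta["lag"], meta["genus_names"], meta["covariate_names"]
        )
    if meta["backend"] == "varma":
        import pickle

        with open(directory / "varma.pkl", "rb") as fh:
            state = pickle.load(fh)
        return VarmaForecaster(
            results=state["results"], cfg=state["cfg"], d=state["d"],
            order=state["order"], genus_names=meta["genus_names"],
            active=state["active"], constants=state["constants"],
            last_level=state["last_level"],
        )
    raise ValueError(f"unknown backend {meta['backend']!r}")
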