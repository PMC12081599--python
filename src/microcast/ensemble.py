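"""Ensemble prediction intervals and outlier flagging.

The early-warning signal is built by training N forecasters of the same
architecture that differ only in their random seed (default N = 50), taking
the arithmetic mean of their predictions as the point forecast, and turning
the inter-model standard deviation into a z-based prediction interval:

    lower = mean - z * std,    upper = mean + z * std,

with z the exact two-sided standard-normal critical value for the configured
coverage (1.959964 at 95%). An observation strictly outside its genus/time
interval is flagged as an outlier, with the direction and the distance beyond
the violated bound.

The spread captures inter-model variance only — no observation-noise term is
added — so the interval under-covers relative to nominal by construction;
this mirrors how ensemble intervals are built in practice and is documented
rather than corrected. Intervals are computed in scaled space and
back-transformed per genus; because the min-max scaler is affine and
monotone, this is identical to computing them on the absolute scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from microcast._seeding import derive_seed
from microcast.forecasters import FittedForecaster, fit, forecast
from microcast.io import AbundanceSeries
from microcast.preprocess import ScalerParams, WindowedDataset, inverse_transform

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    """Ensemble size, interval coverage and member seeding.

    ``seeds`` may be given explicitly (must be distinct, one per member);
    otherwise member seeds are derived deterministically from ``base_seed``.
    ``std_ddof=1`` uses the sample standard deviation across members.
    """

    n_members: int = 50
    coverage: float = 0.95
    z: float | None = None
    seeds: list | None = None
    base_seed: int = 0
    std_ddof: int = 1
    on_member_failure: str = "fail"

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2 (std undefined otherwise)")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        exact = float(stats.norm.ppf(0.5 + self.coverage / 2))
        if self.z is None:
            self.z = exact
        elif abs(self.z - exact) > 5e-3:
            raise ValueError(
                f"z={self.z} inconsistent with coverage {self.coverage} "
                f"(expected ~{exact:.6f})"
            )
        if self.std_ddof not in (0, 1):
            raise ValueError("std_ddof must be 0 or 1")
        if self.seeds is not None:
            self.seeds = [int(s) for s in self.seeds]
            if len(self.seeds) != self.n_members:
                raise ValueError("need one seed per member")
            if len(set(self.seeds)) != self.n_members:
                raise ValueError("member seeds must be distinct")
        if self.on_member_failure not in ("fail", "drop"):
            raise ValueError("on_member_failure must be fail|drop")

    def member_seeds(self) -> list:
        if self.seeds is not None:
            return list(self.seeds)
        return [derive_seed(self.base_seed, "member", i) for i in range(self.n_members)]


@dataclass
class EnsembleForecast:
    """Per genus/time mean, spread and interval bounds from N member models."""

    member_predictions: np.ndarray  # N × T × G
    mean: np.ndarray
    std: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    z: float
    scale: str = "scaled"
    genus_names: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_predictions)

    def to_absolute(self, params: ScalerParams) -> "EnsembleForecast":
        """Back-transform all quantities to absolute abundances.

        The min-max inverse is affine and increasing per genus, so the
        back-transformed bounds equal bounds recomputed from back-transformed
        members.
        """
        if self.scale == "absolute":
            return self
        members_abs = np.stack(
            [inverse_transform(m, params) for m in self.member_predictions]
        )
        span = params.span.to_numpy(dtype=float)
        return EnsembleForecast(
            member_predictions=members_abs,
            mean=inverse_transform(self.mean, params),
            std=self.std * span,
            lower=inverse_transform(self.lower, params),
            upper=inverse_transform(self.upper, params),
            z=self.z,
            scale="absolute",
            genus_names=self.genus_names or list(params.genera),
        )


@dataclass
class OutlierReport:
    """Flagged (time, genus) cells, sorted by timestamp then genus."""

    flags: pd.DataFrame

    COLUMNS = ("timestamp", "genus", "observed", "lower", "upper",
               "direction", "exceedance")

    def __post_init__(self):
        if list(self.flags.columns) != list(self.COLUMNS):
            self.flags = self.flags.reindex(columns=list(self.COLUMNS))

    @property
    def n_flags(self) -> int:
        return len(self.flags)

    def cells(self) -> set:
        return set(zip(self.flags["timestamp"], self.flags["genus"]))

    def write(self, path) -> None:
        self.flags.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "OutlierReport":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def train_ensemble(
    cfg: EnsembleConfig,
    backend_config,
    windows: WindowedDataset,
    validation: WindowedDataset | None = None,
) -> list[FittedForecaster]:
    """Train ``n_members`` same-architecture models differing only by seed."""
    members = []
    for i, seed in enumerate(cfg.member_seeds()):
        member_cfg = replace(backend_config, seed=seed)
        try:
            members.append(fit(member_cfg, windows, validation))
        except Exception:
            if cfg.on_member_failure == "fail":
                raise
            logger.warning("dropping failed ensemble member %d", i, exc_info=True)
    if len(members) < 2:
        raise RuntimeError("fewer than 2 ensemble members fitted")
    return members


def ensemble_forecast(
    members: list[FittedForecaster],
    history: np.ndarray,
    steps: int,
    mode: str = "teacher_forced",
    future_covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Stack member forecasts into an N × steps × G array."""
    return np.stack(
        [forecast(m, history, steps, mode, future_covariates) for m in members]
    )


def build_interval(
    member_predictions: np.ndarray,
    cfg: EnsembleConfig,
    genus_names: list | None = None,
    scale: str = "scaled",
) -> EnsembleForecast:
    """Mean, member standard deviation and z-interval across the ensemble."""
    preds = np.asarray(member_predictions, dtype=float)
    if preds.ndim != 3:
        raise ValueError("member predictions must be N × T × G")
    bad = np.argwhere(np.isnan(preds))
    if len(bad):
        n, t, g = map(int, bad[0])
        raise ValueError(f"NaN prediction from member {n} at cell (t={t}, g={g})")
    mean = preds.mean(axis=0)
    std = preds.std(axis=0, ddof=cfg.std_ddof)
    return EnsembleForecast(
        member_predictions=preds,
        mean=mean,
        std=std,
        lower=mean - cfg.z * std,
        upper=mean + cfg.z * std,
        z=cfg.z,
        scale=scale,
        genus_names=list(genus_names) if genus_names else [],
    )


def detect_outliers(
    observed: AbundanceSeries | np.ndarray,
    interval: EnsembleForecast,
    params: ScalerParams | None = None,
    timestamps=None,
) -> OutlierReport:
    """Flag observations strictly outside the prediction interval.

    ``observed`` is on the absolute-abundance scale (an
    :class:`AbundanceSeries` or a T × G array, NaN rows meaning missing
    samples, which are skipped with a log entry). The interval is
    back-transformed via ``params`` when still in scaled space. Values equal
    to a bound are NOT outliers; ``exceedance`` is the distance beyond the
    violated bound.
    """
    if interval.scale == "scaled":
        if params is None:
            raise ValueError("scaled interval needs scaler params to compare "
                             "against absolute observations")
        interval = interval.to_absolute(params)
    if isinstance(observed, AbundanceSeries):
        genera = observed.genera
        times = list(observed.timestamps)
        values = observed.counts
    else:
        values = np.asarray(observed, dtype=float)
        genera = interval.genus_names or [f"g{j}" for j in range(values.shape[1])]
        times = list(timestamps) if timestamps is not None else list(range(len(values)))
    if values.shape != interval.mean.shape:
        raise ValueError(
            f"observed shape {values.shape} != interval shape {interval.mean.shape}"
        )
    rows = []
    for t in range(values.shape[0]):
        if np.isnan(values[t]).all():
            logger.info("missing observation row at %r skipped", times[t])
            continue
        for j, genus in enumerate(genera):
            obs = values[t, j]
            if np.isnan(obs):
                logger.info("missing observation (%r, %r) skipped", times[t], genus)
                continue
            lo, up = interval.lower[t, j], interval.upper[t, j]
            if obs > up:
                rows.append((times[t], genus, obs, lo, up, "above", obs - up))
            elif obs < lo:
                rows.append((times[t], genus, obs, lo, up, "below", lo - obs))
    flags = pd.DataFrame(rows, columns=list(OutlierReport.COLUMNS))
    flags = flags.sort_values(["timestamp", "genus"], kind="stable").reset_index(
        drop=True
    )
    return OutlierReport(flags=flags)
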