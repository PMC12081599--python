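"""Per-genus trajectory plots: observations, split-wise predictions, interval."""

from __future__ import annotations

import numpy as np

from microcast.ensemble import EnsembleForecast
from microcast.io import AbundanceSeries


def plot_genus_forecast(
    genus: str,
    observed: AbundanceSeries,
    interval: EnsembleForecast,
    interval_timestamps=None,
    predictions_by_split: dict | None = None,
    ax=None,
):
    """Observed abundance of one genus with the shaded prediction interval.

    ``predictions_by_split`` optionally maps split names (train, validation,
    test) to (timestamps, T × G prediction matrix) pairs, drawn in distinct
    colors in the conventional layout. Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    j = observed.genera.index(genus)
    ax.plot(
        np.asarray(observed.timestamps), observed.counts[:, j],
        color="black", lw=1.0, marker=".", ms=3, label="observed",
    )
    colors = {"train": "tab:orange", "validation": "tab:green",
              "test": "tab:brown"}
    for split, (times, preds) in (predictions_by_split or {}).items():
        ax.plot(np.asarray(times), np.asarray(preds)[:, j],
                color=colors.get(split, "tab:blue"), lw=1.2,
                label=f"{split} prediction")
    gi = interval.genus_names.index(genus) if interval.genus_names else j
    times = (
        np.asarray(interval_timestamps)
        if interval_timestamps is not None
        else np.asarray(observed.timestamps)[-interval.mean.shape[0]:]
    )
    ax.fill_between(times, interval.lower[:, gi], interval.upper[:, gi],
                    color="tab:brown", alpha=0.25,
                    label=f"{interval.n_members}-member interval")
    ax.set_xlabel("time")
    ax.set_ylabel("absolute abundance")
    ax.set_title(genus)
    ax.legend(fontsize=8)
    return ax
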