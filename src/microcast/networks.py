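"""Genus co-occurrence networks and forecaster feature importance.

Pairwise correlation (Spearman, Pearson or Kendall) across all genus pairs,
Benjamini-Hochberg correction of the p-values, and edge retention by both a
magnitude convention (|coefficient| >= 0.6 by default) and the FDR criterion.
Genera left without any retained edge are excluded from the node set. Hub
genera — those with the largest number of connections or the highest summed
correlation strength — can then be compared against the genera a trained
forecaster actually relies on, ranked by permutation importance (or by an
externally supplied per-genus score file, e.g. Shapley values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from microcast.forecasters import FittedForecaster
from microcast.io import AbundanceSeries
from microcast.preprocess import WindowedDataset

logger = logging.getLogger(__name__)

_METRICS = {
    "spearman": stats.spearmanr,
    "pearson": stats.pearsonr,
    "kendall": stats.kendalltau,
}


@dataclass
class CorrelationNetwork:
    """Thresholded undirected genus-genus correlation graph."""

    metric: str
    edges: pd.DataFrame  # genus_a, genus_b, coefficient, p_value, q_value
    edge_threshold: float
    fdr_alpha: float | None
    tested_genera: list = field(default_factory=list)

    @property
    def nodes(self) -> list:
        """Genera with at least one retained edge."""
        return sorted(set(self.edges["genus_a"]) | set(self.edges["genus_b"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.genus_a, row.genus_b, coefficient=row.coefficient,
                       p_value=row.p_value, q_value=row.q_value)
        return g

    def write_edge_list(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class ImportanceRanking:
    """Per-genus importance scores with a total ordering.

    ``provider`` is ``native-permutation`` for scores computed here or
    ``external`` for scores loaded from a file (e.g. Shapley values, whose
    signs are preserved; the ranking itself uses magnitudes). Ties are broken
    lexicographically by genus name.
    """

    scores: dict
    provider: str = "native-permutation"

    def __post_init__(self):
        for g, s in self.scores.items():
            if not np.isfinite(s):
                raise ValueError(f"non-finite importance for {g!r}")

    def ranking(self) -> list:
        return sorted(self.scores, key=lambda g: (-abs(self.scores[g]), g))

    def top(self, k: int) -> list:
        return self.ranking()[:k]

    def write(self, path) -> None:
        pd.Series(self.scores, name="importance").rename_axis("genus").to_csv(
            path, sep="\t"
        )

    @classmethod
    def read(cls, path, provider: str = "external") -> "ImportanceRanking":
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(scores=table.iloc[:, 0].to_dict(), provider=provider)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def correlation_matrix(series: AbundanceSeries, metric: str = "spearman"):
    """Full symmetric correlation and p-value matrices over non-constant genera."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {list(_METRICS)}")
    frame = series.data
    keep = [g for g in frame.columns if frame[g].nunique() > 1]
    dropped = [g for g in frame.columns if g not in keep]
    if dropped:
        logger.info("constant genera excluded from correlation: %s", dropped)
    genera = keep
    n = len(genera)
    coef = np.eye(n)
    pval = np.zeros((n, n))
    fn = _METRICS[metric]
    for i, j in combinations(range(n), 2):
        r, p = fn(frame[genera[i]], frame[genera[j]])
        coef[i, j] = coef[j, i] = r
        pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(coef, index=genera, columns=genera),
        pd.DataFrame(pval, index=genera, columns=genera),
    )


def build_network(
    series: AbundanceSeries,
    metric: str = "spearman",
    edge_threshold: float = 0.6,
    fdr_alpha: float | None = 0.05,
) -> CorrelationNetwork:
    """Test all genus pairs and retain edges by magnitude and FDR.

    An edge (a, b) is kept iff |coefficient| >= ``edge_threshold`` and, when
    ``fdr_alpha`` is not None, its Benjamini-Hochberg q-value is <= the
    alpha. Edges are stored in canonical a < b order.
    """
    if series.n_samples < 10:
        raise ValueError("need at least 10 samples for a correlation network")
    if series.n_genera < 2:
        raise ValueError("need at least 2 genera")
    coef, pval = correlation_matrix(series, metric)
    genera = list(coef.index)
    records = []
    for i, j in combinations(range(len(genera)), 2):
        records.append((genera[i], genera[j], coef.iat[i, j], pval.iat[i, j]))
    table = pd.DataFrame(records, columns=["genus_a", "genus_b", "coefficient",
                                           "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["q_value"] = []
    keep = table["coefficient"].abs() >= edge_threshold
    if fdr_alpha is not None:
        keep &= table["q_value"] <= fdr_alpha
    edges = table[keep].reset_index(drop=True)
    return CorrelationNetwork(
        metric=metric,
        edges=edges,
        edge_threshold=edge_threshold,
        fdr_alpha=fdr_alpha,
        tested_genera=genera,
    )


def node_strength(network: CorrelationNetwork) -> pd.DataFrame:
    """Degree and summed |coefficient| per node, tie-broken by genus name."""
    rows: dict = {}
    for row in network.edges.itertuples(index=False):
        for g in (row.genus_a, row.genus_b):
            degree, strength = rows.get(g, (0, 0.0))
            rows[g] = (degree + 1, strength + abs(row.coefficient))
    out = pd.DataFrame(
        [(g, d, s) for g, (d, s) in rows.items()],
        columns=["genus", "degree", "strength"],
    )
    return out.sort_values(
        ["strength", "degree", "genus"], ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: FittedForecaster,
    windows: WindowedDataset,
    repeats: int = 5,
    seed: int = 0,
) -> ImportanceRanking:
    """Score each input genus by the MAE increase under column permutation.

    For each genus, its lag columns are jointly permuted across windows (the
    same row permutation for all lag steps, preserving within-window
    coherence), the model is re-evaluated, and the score is the mean MAE
    inflation over ``repeats`` seeded permutations. Constant features score 0
    by definition.
    """
    if windows.n_windows < 10:
        raise ValueError("need at least 10 windows for permutation importance")
    rng = np.random.default_rng(seed)
    base_pred = model.predict_batch(windows.X)
    base_mae = float(np.mean(np.abs(base_pred - windows.y)))
    scores = {}
    for j, genus in enumerate(windows.genus_names):
        col = windows.X[:, :, j]
        if np.ptp(col) == 0:
            scores[genus] = 0.0
            continue
        inflation = 0.0
        for _ in range(repeats):
            perm = rng.permutation(windows.n_windows)
            Xp = windows.X.copy()
            Xp[:, :, j] = col[perm]
            pred = model.predict_batch(Xp)
            inflation += float(np.mean(np.abs(pred - windows.y))) - base_mae
        scores[genus] = inflation / repeats
    return ImportanceRanking(scores=scores, provider="native-permutation")


def compare_rankings(
    importance: ImportanceRanking,
    network: CorrelationNetwork,
    k: int = 10,
) -> dict:
    """Overlap between the model's top-k genera and the network's hubs.

    Returns the three top-k sets (importance, degree, strength) with their
    pairwise intersection sizes and Jaccard indices.
    """
    strengths = node_strength(network)
    n_nodes = len(strengths)
    if k > n_nodes:
        logger.warning("k=%d larger than node count %d; clamping", k, n_nodes)
        k = n_nodes
    top_importance = set(importance.top(k))
    by_degree = strengths.sort_values(
        ["degree", "strength", "genus"], ascending=[False, False, True],
        kind="stable",
    )
    top_degree = set(by_degree["genus"].head(k))
    top_strength = set(strengths["genus"].head(k))

    def _overlap(a: set, b: set) -> dict:
        union = a | b
        return {
            "intersection": sorted(a & b),
            "overlap": len(a & b),
            "jaccard": len(a & b) / len(union) if union else 1.0,
        }

    return {
        "k": k,
        "top_importance": sorted(top_importance),
        "top_degree": sorted(top_degree),
        "top_strength": sorted(top_strength),
        "importance_vs_degree": _overlap(top_importance, top_degree),
        "importance_vs_strength": _overlap(top_importance, top_strength),
        "degree_vs_strength": _overlap(top_degree, top_strength),
    }
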