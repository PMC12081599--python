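"""Reading, validation and harmonization of genus-level feature tables.

The canonical in-memory object is :class:`AbundanceSeries`: a time-ordered
samples × genera matrix of non-negative abundances (reads per OTU aggregated to
genus) for one subject or site. Tables arrive as TSV/CSV exports of BIOM-style
feature tables (the QIIME2 dialect with a leading ``#OTU ID`` header line is
tolerated); sample metadata arrives as a TSV/CSV keyed by sample id.

Timestamps are taken from the sample identifiers (ISO-8601 dates or plain
integer indices) or supplied explicitly; internally samples are ordered by time
and addressed by integer step. Irregular spacing is kept as-is — missing time
points are represented by the absence of a row, never by NaN rows, and no
resampling or imputation is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Environmental covariates commonly recorded alongside wastewater sampling.
DEFAULT_COVARIATE_SCHEMA = (
    "precipitation",
    "temperature",
    "flow",
    "tss",
    "ammonium",
    "bod5",
    "phosphorus",
)


def _parse_timestamp(label: object):
    """Parse a sample label into a sortable time value (int or Timestamp)."""
    text = str(label).strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    ts = pd.to_datetime(text, errors="coerce")
    if not pd.isna(ts):
        return ts
    # ids like "site-0042": take the trailing integer as the time step
    import re

    suffix = re.search(r"(\d+)\s*$", text)
    if suffix:
        return int(suffix.group(1))
    raise ValueError(f"unparseable timestamp for sample {label!r}")


@dataclass
class AbundanceSeries:
    """Time-ordered genus abundance matrix for a single subject or site.

    Parameters
    ----------
    data
        Samples × genera table; the index holds sample identifiers, the
        columns genus names. Values are non-negative abundances.
    timestamps
        One time value per sample, strictly increasing after ordering.
    subject_id
        Label of the person or sampling site the series belongs to.
    """

    data: pd.DataFrame
    timestamps: Sequence = None
    subject_id: str = ""

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.timestamps is None:
            self.timestamps = [_parse_timestamp(s) for s in self.data.index]
        self.timestamps = pd.Index(self.timestamps)
        if len(self.timestamps) != len(self.data):
            raise ValueError(
                f"{len(self.timestamps)} timestamps for {len(self.data)} samples"
            )
        genera = list(self.data.columns)
        dupes = pd.Index(genera)[pd.Index(genera).duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicate genus names: {sorted(map(str, dupes))}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = map(int, np.argwhere(np.isnan(values))[0])
            raise ValueError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"genus {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = map(int, np.argwhere(values < 0)[0])
            raise ValueError(
                f"negative abundance {values[r, c]} at sample "
                f"{self.data.index[r]!r}, genus {self.data.columns[c]!r}"
            )
        order = np.argsort(np.asarray(self.timestamps), kind="stable")
        self.data = self.data.iloc[order]
        self.timestamps = self.timestamps[order]
        diffs_ok = all(
            self.timestamps[i] < self.timestamps[i + 1]
            for i in range(len(self.timestamps) - 1)
        )
        if not diffs_ok:
            raise ValueError("timestamps are not strictly increasing (duplicates?)")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def genera(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """T × G abundance matrix as floats."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_genera(self) -> int:
        return self.data.shape[1]

    def select_rows(self, positions: Sequence[int]) -> "AbundanceSeries":
        positions = list(positions)
        return AbundanceSeries(
            data=self.data.iloc[positions].copy(),
            timestamps=self.timestamps[positions],
            subject_id=self.subject_id,
        )

    def with_counts(self, counts: np.ndarray) -> "AbundanceSeries":
        """Same axes, new values (used by scaling transforms)."""
        frame = pd.DataFrame(
            np.asarray(counts, dtype=float),
            index=self.data.index,
            columns=self.data.columns,
        )
        out = object.__new__(AbundanceSeries)
        out.data = frame
        out.timestamps = self.timestamps
        out.subject_id = self.subject_id
        return out


@dataclass
class SampleMetadata:
    """Per-sample metadata: timestamp, illness flag, environmental covariates."""

    table: pd.DataFrame
    covariate_schema: tuple = DEFAULT_COVARIATE_SCHEMA

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate metadata rows for sample {dup!r}")
        if "health_flag" not in self.table.columns:
            self.table = self.table.assign(health_flag=False)
        self.table["health_flag"] = self.table["health_flag"].map(_as_bool)
        unknown = [
            c
            for c in self.table.columns
            if c not in ("timestamp", "health_flag")
            and c.lower() not in self.covariate_schema
        ]
        if unknown:
            raise ValueError(
                f"covariates {unknown} not in declared schema "
                f"{list(self.covariate_schema)}"
            )

    @property
    def covariate_names(self) -> list:
        return [
            c for c in self.table.columns if c not in ("timestamp", "health_flag")
        ]

    def covariates_for(self, sample_ids: Sequence) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"no metadata for samples {missing}")
        return self.table.loc[list(sample_ids), self.covariate_names]

    def health_flags(self, sample_ids: Sequence) -> pd.Series:
        flags = self.table["health_flag"].reindex(list(sample_ids))
        return flags


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y", "sick")
    return bool(v) and not pd.isna(v)


@dataclass
class GenusRoster:
    """Ordered unique genus names with per-name provenance.

    ``provenance`` tags each name as ``observed`` (seen in at least one table)
    or ``supplement`` (added from an external list, e.g. baseline gut taxa).
    """

    names: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.names = [str(n).strip() for n in self.names]
        if len(set(self.names)) != len(self.names):
            seen: set[str] = set()
            dupes = [n for n in self.names if n in seen or seen.add(n)]
            raise ValueError(f"duplicate roster names: {sorted(set(dupes))}")
        for n in self.names:
            self.provenance.setdefault(n, "supplement")

    @classmethod
    def from_supplement(cls, names: Iterable[str]) -> "GenusRoster":
        names = [str(n).strip() for n in names]
        return cls(names=names, provenance={n: "supplement" for n in names})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path,
    orientation: str = "samples-as-rows",
    subject_id: str = "",
    timestamps: Mapping | Sequence | None = None,
) -> AbundanceSeries:
    """Read a TSV/CSV feature table into a canonical :class:`AbundanceSeries`.

    Parameters
    ----------
    orientation
        ``samples-as-rows`` (samples on the index) or ``samples-as-columns``
        (the BIOM/QIIME2 export convention: one row per taxon). A leading
        ``# Constructed from biom file`` comment line and an ``#OTU ID``
        header cell are tolerated.
    timestamps
        Optional explicit time values, either a sequence aligned with the
        sample axis or a mapping ``sample_id -> time``. By default timestamps
        are parsed from the sample identifiers themselves (integers or
        ISO-8601 dates).
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        lines = fh.readlines()
    # QIIME2 BIOM-TSV export starts with a pure comment line
    while lines and lines[0].startswith("#") and "\t" not in lines[0] and "," not in lines[0]:
        lines.pop(0)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(lines)), sep=_sep_for(path), index_col=0)
    frame.index = [str(i).strip() for i in frame.index]
    frame.columns = [str(c).strip() for c in frame.columns]
    if orientation == "samples-as-columns":
        frame = frame.T
    if timestamps is not None and isinstance(timestamps, Mapping):
        timestamps = [timestamps[s] for s in frame.index]
    return AbundanceSeries(data=frame, timestamps=timestamps, subject_id=subject_id)


def write_abundance_table(series: AbundanceSeries, path, orientation: str = "samples-as-rows") -> None:
    """Write the canonical TSV form (lossless for integer counts)."""
    path = Path(path)
    frame = series.data
    if (frame.to_numpy() == np.round(frame.to_numpy())).all():
        frame = frame.astype(np.int64)
    if orientation == "samples-as-columns":
        frame = frame.T
        frame.index.name = "#OTU ID"
    else:
        frame.index.name = "sample_id"
    frame.to_csv(path, sep=_sep_for(path))


def read_metadata(path, covariate_schema: tuple = DEFAULT_COVARIATE_SCHEMA) -> SampleMetadata:
    """Read a per-sample metadata table keyed by sample id."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    table.index = [str(i).strip() for i in table.index]
    table.columns = [str(c).strip() for c in table.columns]
    return SampleMetadata(table=table, covariate_schema=covariate_schema)


# ---------------------------------------------------------------------------
# harmonization / filtering
# ---------------------------------------------------------------------------


def harmonize_genera(
    tables: Sequence[AbundanceSeries],
    roster: GenusRoster | None = None,
    normalize_case: bool = False,
) -> list[AbundanceSeries]:
    """Re-index every table on the union genus axis, zero-filling absences.

    Genera observed in any table, plus roster supplements, form a shared
    ordered axis; a genus absent from one subject's samples but present in
    others (or in the roster) is assigned zero abundance. Matching is exact
    string match after whitespace trimming; case-variant collisions are
    rejected unless ``normalize_case`` lower-cases names first.
    """
    if not tables:
        raise ValueError("need at least one table")
    tables = list(tables)
    if normalize_case:
        tables = [
            AbundanceSeries(
                data=t.data.rename(columns=lambda c: str(c).strip().lower()),
                timestamps=t.timestamps,
                subject_id=t.subject_id,
            )
            for t in tables
        ]
    union: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.genera:
            g = str(g).strip()
            if g not in seen:
                union.append(g)
                seen.add(g)
    if not normalize_case:
        folded: dict[str, str] = {}
        for g in seen:
            key = g.lower()
            if key in folded and folded[key] != g:
                raise ValueError(
                    f"case-variant genus names {folded[key]!r} vs {g!r}; "
                    "enable normalize_case to merge"
                )
            folded[key] = g
    if roster is not None:
        for g in roster.names:
            g = g.lower() if normalize_case else g
            if g not in seen:
                union.append(g)
                seen.add(g)
    out = []
    for t in tables:
        frame = t.data.reindex(columns=union, fill_value=0.0)
        out.append(
            AbundanceSeries(data=frame, timestamps=t.timestamps, subject_id=t.subject_id)
        )
    return out


def filter_sick_days(
    series: AbundanceSeries,
    meta: SampleMetadata,
    missing_policy: str = "keep",
) -> AbundanceSeries:
    """Drop samples flagged as taken on a reported-illness day.

    Samples without a metadata row are kept with a warning by default
    (``missing_policy="keep"``) or dropped (``"drop"``).
    """
    if missing_policy not in ("keep", "drop"):
        raise ValueError(f"missing_policy must be keep|drop, got {missing_policy!r}")
    flags = meta.health_flags(series.sample_ids)
    unmatched = [s for s, f in zip(series.sample_ids, flags) if pd.isna(f)]
    if unmatched:
        msg = f"{len(unmatched)} samples without metadata: {unmatched[:5]}"
        if missing_policy == "keep":
            warnings.warn(msg + " — keeping them", stacklevel=2)
        else:
            logger.info("dropping %s", msg)
    keep = []
    removed = []
    for pos, (sid, flag) in enumerate(zip(series.sample_ids, flags)):
        if pd.isna(flag):
            if missing_policy == "keep":
                keep.append(pos)
            else:
                removed.append(sid)
        elif flag:
            removed.append(sid)
        else:
            keep.append(pos)
    if removed:
        logger.info("excluded %d sick-day samples: %s", len(removed), removed)
    if not keep:
        raise ValueError("empty series: every sample was excluded")
    return series.select_rows(keep)
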