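"""Camera-trap record handling.

A *record* is one photograph: site, species label, timestamp, number of
individuals in the frame, and a photo-burst id (trail cameras fire a fixed
burst of three frames per trigger).  Analysis units are built from records:

* bursts collapse to single *detection events* (one time, the max count);
* events binarise into a site x occasion *detection history* with an
  effort mask for camera-inactive days;
* photo-level counts sum into per-site human/livestock pressure covariates;
* event clock times convert to radians on [0, 2pi) for diel analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .overlap import DielSample

__all__ = [
    "RECORD_COLUMNS",
    "LIVESTOCK_SPECIES",
    "DetectionHistory",
    "read_records",
    "collapse_bursts",
    "build_history",
    "count_covariate",
    "to_radians",
    "diel_sample",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["site_id", "species", "datetime", "count", "burst_id"]

#: species labels pooled into the livestock count covariate
LIVESTOCK_SPECIES = ("cattle", "buffalo", "goat")

TWO_PI = 2.0 * np.pi


@dataclass
class DetectionHistory:
    """Binary site x occasion detection matrix with an effort mask."""

    species: str
    site_ids: list
    occasion_dates: list
    y: np.ndarray          # int8, 0/1 (value in masked cells is 0)
    mask: np.ndarray       # bool, True where the camera was active

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.shape != self.mask.shape:
            raise ValueError("y and mask shapes differ")
        if np.any((self.y != 0) & ~self.mask):
            raise ValueError("masked cells must carry no detections")

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def naive_occupancy(self) -> float:
        """Fraction of sites with at least one detection (lower bound on psi)."""
        return float((self.y.sum(axis=1) > 0).mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.mask, self.y, -1),
            index=pd.Index(self.site_ids, name="site_id"),
            columns=[str(d) for d in self.occasion_dates],
        )
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str):
        vals = df.to_numpy(dtype=int)
        return cls(species=species, site_ids=list(df.index),
                   occasion_dates=list(df.columns),
                   y=np.where(vals < 0, 0, vals), mask=vals >= 0)

    @classmethod
    def from_csv(cls, path, species: str):
        return cls.from_frame(pd.read_csv(path, index_col="site_id"), species)


def read_records(path) -> pd.DataFrame:
    """Read a records CSV and parse timestamps; schema is RECORD_COLUMNS."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    df["datetime"] = pd.to_datetime(df["datetime"], errors="coerce")
    return df


def collapse_bursts(records: pd.DataFrame, gap_seconds: float = 30.0) -> pd.DataFrame:
    """Collapse photo bursts to detection events.

    One event per ``burst_id`` within site and species; the event time is
    the first photo's time and the event count the maximum per-photo count
    in the burst.  When ``burst_id`` is absent, photos of the same species
    at the same site within ``gap_seconds`` of the previous photo are
    grouped into one event (the camera's re-trigger delay).  Rows with
    unparseable timestamps are dropped with a logged warning; the number
    dropped is stored in ``events.attrs['n_rejected']``.
    """
    df = records.copy()
    if df.empty:
        out = pd.DataFrame(columns=["site_id", "species", "datetime", "count",
                                    "burst_id", "n_photos"])
        out.attrs["n_rejected"] = 0
        return out
    dt = pd.to_datetime(df["datetime"], errors="coerce")
    bad = dt.isna()
    if bad.any():
        logger.warning("dropping %d records with unparseable datetimes", bad.sum())
    df = df.loc[~bad].copy()
    df["datetime"] = dt[~bad]
    df = df.sort_values(["site_id", "species", "datetime"], kind="stable")

    if "burst_id" in df.columns and df["burst_id"].notna().all():
        keys = ["site_id", "species", "burst_id"]
        grouped = df.groupby(keys, sort=False)
    else:
        gaps = df.groupby(["site_id", "species"], sort=False)["datetime"].diff()
        new_event = gaps.isna() | (gaps.dt.total_seconds() > gap_seconds)
        df["_event"] = new_event.cumsum()
        grouped = df.groupby(["site_id", "species", "_event"], sort=False)

    events = grouped.agg(
        datetime=("datetime", "min"),
        count=("count", "max"),
        n_photos=("count", "size"),
    ).reset_index()
    if "_event" in events.columns:
        events["burst_id"] = events.pop("_event").astype(str)
    events = events[["site_id", "species", "datetime", "count", "burst_id",
                     "n_photos"]].reset_index(drop=True)
    events.attrs["n_rejected"] = int(bad.sum())
    return events


def _as_effort_frame(effort) -> pd.DataFrame:
    if isinstance(effort, pd.DataFrame):
        df = effort.copy()
    else:  # mapping site -> (start, end)
        df = pd.DataFrame(
            [(s, a, b) for s, (a, b) in effort.items()],
            columns=["site_id", "start", "end"],
        )
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def build_history(events: pd.DataFrame, species: str, effort,
                  occasion_days: int = 1) -> DetectionHistory:
    """Bin events into a binary detection history.

    ``effort`` gives each camera's active date range (DataFrame with
    site_id/start/end, or a mapping site -> (start, end)); occasions are
    consecutive blocks of ``occasion_days`` days starting at the earliest
    active date.  A cell is 1 iff at least one event of the species fell at
    that site in that occasion; cells outside a camera's active range are
    masked.  Events at sites absent from the effort table raise; events
    outside their own camera's active window are dropped with a warning.
    """
    if occasion_days < 1:
        raise ValueError("occasion_days must be >= 1")
    eff = _as_effort_frame(effort)
    site_ids = list(eff["site_id"])
    origin = eff["start"].min().normalize()
    end = eff["end"].max().normalize()
    n_occ = int((end - origin).days // occasion_days) + 1
    occasion_dates = [
        (origin + pd.Timedelta(days=k * occasion_days)).date()
        for k in range(n_occ)
    ]
    site_index = {s: i for i, s in enumerate(site_ids)}

    mask = np.zeros((len(site_ids), n_occ), dtype=bool)
    day0 = ((eff["start"].dt.normalize() - origin).dt.days // occasion_days).to_numpy()
    day1 = ((eff["end"].dt.normalize() - origin).dt.days // occasion_days).to_numpy()
    for i, (a, b) in enumerate(zip(day0, day1)):
        mask[i, a : b + 1] = True

    y = np.zeros((len(site_ids), n_occ), dtype=np.int8)
    ev = events.loc[events["species"] == species]
    dropped = 0
    for site, t in zip(ev["site_id"], pd.to_datetime(ev["datetime"])):
        if site not in site_index:
            raise KeyError(f"event at site {site!r} absent from effort table")
        i = site_index[site]
        j = int((t.normalize() - origin).days // occasion_days)
        if j < 0 or j >= n_occ or not mask[i, j]:
            dropped += 1
            continue
        y[i, j] = 1
    if dropped:
        logger.warning("dropped %d %s events outside camera-active windows",
                       dropped, species)
    return DetectionHistory(species=species, site_ids=site_ids,
                            occasion_dates=occasion_dates, y=y, mask=mask)


def count_covariate(records: pd.DataFrame, species_group, site_ids=None) -> pd.Series:
    """Per-site total individual count over all photos of a species group.

    Photo-level: the count field is summed over *every* photograph (not
    collapsed events) whose species is in ``species_group``; e.g. the
    livestock group pools cattle/oxen, buffalo and goats.
    """
    if isinstance(species_group, str):
        species_group = [species_group]
    sel = records.loc[records["species"].isin(set(species_group))]
    totals = sel.groupby("site_id")["count"].sum()
    if site_ids is not None:
        totals = totals.reindex(site_ids, fill_value=0)
    return totals.astype(int).rename("count")


def to_radians(times) -> np.ndarray:
    """Clock times -> radians: t = 2*pi * (seconds since midnight) / 86400.

    Accepts datetimes/timestamps, ``HH:MM[:SS]`` strings, or fractional
    hours/days are *not* guessed — inputs must carry clock components.
    """
    s = pd.Series(times)
    if s.empty:
        return np.array([], dtype=float)
    if pd.api.types.is_datetime64_any_dtype(s) or isinstance(s.iloc[0], pd.Timestamp):
        dt = pd.to_datetime(s)
        secs = dt.dt.hour * 3600 + dt.dt.minute * 60 + dt.dt.second + dt.dt.microsecond / 1e6
    else:
        td = pd.to_timedelta(s.astype(str), errors="coerce")
        if td.isna().any():
            dt = pd.to_datetime(s, errors="raise")
            secs = dt.dt.hour * 3600 + dt.dt.minute * 60 + dt.dt.second
        else:
            secs = td.dt.total_seconds() % 86400
    return (TWO_PI * secs.to_numpy(dtype=float) / 86400.0) % TWO_PI


def diel_sample(events: pd.DataFrame, species: str, mode: str = "all") -> DielSample:
    """Radian detection times for one species' collapsed events.

    ``mode='all'`` uses every event; ``mode='hourly'`` keeps at most one
    event per site per calendar hour (a thinning sometimes used to damp
    bursts of repeat triggers).
    """
    ev = events.loc[events["species"] == species]
    if mode == "hourly":
        t = pd.to_datetime(ev["datetime"])
        ev = ev.loc[~pd.DataFrame({
            "site": ev["site_id"], "hour": t.dt.floor("h")
        }).duplicated().to_numpy()]
    elif mode != "all":
        raise ValueError("mode must be 'all' or 'hourly'")
    return DielSample(species=species, times=to_radians(ev["datetime"]))
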