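"""Turn raw camera-trap records into detection histories and model-ready covariates.

The survey design this module targets is a short single-season camera-trap
study: cameras run overnight (by default 16:30 until 08:30 the next morning),
each site is surveyed for a handful of consecutive "trapping nights", and a
photo stream per site is collapsed into independent *events* before any
counting.  Outputs are

* a detection history ``y[s, i, j] in {0, 1, NaN}`` over species x sites x
  nights (NaN marks nights the camera was not active),
* a per-night count of dog events (used downstream as a detection covariate),
* standardized habitat/infrastructure covariates with a collinearity screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Study species.  The enum is open: records of other taxa are ignored with a
#: logged warning when histories are built.
SPECIES = ("indian_fox", "jackal", "jungle_cat", "dog")

#: Default camera deployment window (a trapping night spans midnight).
NIGHT_START = time(16, 30)
NIGHT_END = time(8, 30)


# ---------------------------------------------------------------------------
# photo records -> events
# ---------------------------------------------------------------------------

def read_photos(path) -> pd.DataFrame:
    """Read a ``photos.csv`` (site_id, species, timestamp ISO-8601).

    Unparseable timestamps raise a ``ValueError`` naming the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"unparseable timestamp at line {bad[0] + 2}: "
            f"{df['timestamp'].iloc[bad[0]]!r}"
        )
    df["timestamp"] = ts
    return df


def collapse_photos_to_events(
    photos: pd.DataFrame, window_minutes: float = 10.0
) -> pd.DataFrame:
    """Collapse per-species photo streams into events with a chained-gap rule.

    Within each site x species stream (sorted by time) a new event starts
    if and only if the gap to the *previous photo* exceeds ``window_minutes``;
    a gap of exactly the window does not split (strict inequality).  Photo
    counts are conserved in ``n_photos``.

    Returns a frame with columns site_id, species, start_time, n_photos,
    sorted by (site_id, species, start_time).
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    if len(photos) == 0:
        return pd.DataFrame(columns=["site_id", "species", "start_time", "n_photos"])
    df = photos.sort_values(["site_id", "species", "timestamp"], kind="mergesort")
    gap = df.groupby(["site_id", "species"], sort=False)["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=window_minutes))
    event_id = new_event.cumsum()
    events = (
        df.assign(_event=event_id)
        .groupby("_event", sort=True)
        .agg(
            site_id=("site_id", "first"),
            species=("species", "first"),
            start_time=("timestamp", "first"),
            n_photos=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return events.sort_values(
        ["site_id", "species", "start_time"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# deployment schedule and detection histories
# ---------------------------------------------------------------------------

def make_schedule(
    site_ids,
    n_nights: int = 6,
    first_night: date = date(2016, 11, 1),
    inactive: set[tuple[str, int]] | None = None,
    start: time = NIGHT_START,
    end: time = NIGHT_END,
) -> pd.DataFrame:
    """Build a deployment schedule frame.

    Columns: site_id, night (1-based), date (the evening the night starts),
    start, end, active.  ``inactive`` lists (site_id, night) pairs with no
    camera activity (represented as missing in the detection history).
    """
    inactive = inactive or set()
    rows = []
    for sid in site_ids:
        for j in range(1, n_nights + 1):
            rows.append(
                {
                    "site_id": str(sid),
                    "night": j,
                    "date": first_night + timedelta(days=j - 1),
                    "start": start,
                    "end": end,
                    "active": (str(sid), j) not in inactive,
                }
            )
    return pd.DataFrame(rows)


def night_windows(schedule: pd.DataFrame) -> pd.DataFrame:
    """Attach absolute start/end datetimes to each scheduled night.

    A night whose end clock time precedes its start spans midnight and ends
    the following calendar day.
    """
    sched = schedule.copy()
    starts, ends = [], []
    for _, row in sched.iterrows():
        d = row["date"]
        if isinstance(d, str):
            d = date.fromisoformat(d)
        elif isinstance(d, pd.Timestamp):
            d = d.date()
        s, e = _as_time(row["start"]), _as_time(row["end"])
        start_dt = datetime.combine(d, s)
        end_d = d + timedelta(days=1) if e <= s else d
        ends.append(datetime.combine(end_d, e))
        starts.append(start_dt)
    sched["start_dt"] = starts
    sched["end_dt"] = ends
    return sched


def _as_time(value) -> time:
    if isinstance(value, time):
        return value
    if isinstance(value, str):
        return time.fromisoformat(value)
    raise TypeError(f"cannot interpret {value!r} as a clock time")


@dataclass
class DetectionHistory:
    """Detection/non-detection array over species x sites x nights.

    ``y`` is float with values 0.0, 1.0 and NaN; NaN appears exactly where the
    schedule was inactive.
    """

    y: np.ndarray
    species: tuple[str, ...]
    sites: tuple[str, ...]

    @property
    def n_nights(self) -> int:
        return self.y.shape[2]

    @property
    def n_active(self) -> int:
        """Number of active site-nights (each counted once, not per species)."""
        return int(np.isfinite(self.y[0]).sum())

    def history_string(self, species: str, site: str) -> str:
        """Compact per-site history, e.g. ``"100101"``; missing printed ``.``."""
        row = self.y[self.species.index(species), self.sites.index(site)]
        return "".join("." if np.isnan(v) else str(int(v)) for v in row)

    def to_frame(self) -> pd.DataFrame:
        """Long format: species, site, night, y (y empty for missing nights)."""
        recs = []
        for s, sp in enumerate(self.species):
            for i, site in enumerate(self.sites):
                for j in range(self.n_nights):
                    v = self.y[s, i, j]
                    recs.append(
                        {
                            "species": sp,
                            "site_id": site,
                            "night": j + 1,
                            "y": "" if np.isnan(v) else int(v),
                        }
                    )
        return pd.DataFrame(recs)


def _locate_events(events: pd.DataFrame, sched: pd.DataFrame) -> pd.DataFrame:
    """Assign each event to the active night window containing its time."""
    out = events.copy()
    nights = np.empty(len(out), dtype=int)
    for k, (_, ev) in enumerate(out.iterrows()):
        rows = sched[sched["site_id"] == str(ev["site_id"])]
        t = ev["start_time"]
        if isinstance(t, str):
            t = pd.Timestamp(t)
        hit = rows[(rows["start_dt"] <= t) & (t <= rows["end_dt"]) & rows["active"]]
        if len(hit) == 0:
            raise ValueError(
                f"event at site {ev['site_id']} ({t}) falls outside every "
                "active deployment window"
            )
        nights[k] = int(hit["night"].iloc[0])
    out["night"] = nights
    return out


def build_detection_history(
    events: pd.DataFrame,
    schedule: pd.DataFrame,
    species: tuple[str, ...] = SPECIES,
) -> DetectionHistory:
    """Binary detection history from collapsed events and a schedule.

    ``y[s,i,j] = 1`` iff at least one event of species ``s`` occurred at site
    ``i`` during active night ``j``; 0 on active event-free nights; NaN on
    inactive nights.  Events outside every active window raise; events of
    species not in ``species`` are skipped with a warning.
    """
    sched = night_windows(schedule)
    sites = tuple(dict.fromkeys(sched["site_id"].astype(str)))
    n_nights = int(sched["night"].max())
    y = np.zeros((len(species), len(sites), n_nights))
    active = np.zeros((len(sites), n_nights), dtype=bool)
    site_ix = {s: i for i, s in enumerate(sites)}
    for _, row in sched.iterrows():
        active[site_ix[str(row["site_id"])], int(row["night"]) - 1] = bool(row["active"])
    y[:, ~active] = np.nan

    known = events[events["species"].isin(species)]
    unknown = set(events["species"]) - set(species)
    if unknown:
        logger.warning("ignoring records of unlisted species: %s", sorted(unknown))
    if len(known):
        located = _locate_events(known, sched)
        for _, ev in located.iterrows():
            s = species.index(ev["species"])
            y[s, site_ix[str(ev["site_id"])], ev["night"] - 1] = 1.0
    return DetectionHistory(y=y, species=tuple(species), sites=sites)


def dog_activity_matrix(
    events: pd.DataFrame, schedule: pd.DataFrame, dog_species: str = "dog"
) -> np.ndarray:
    """Count dog events per site x night (zero where inactive or event-free)."""
    sched = night_windows(schedule)
    sites = tuple(dict.fromkeys(sched["site_id"].astype(str)))
    n_nights = int(sched["night"].max())
    counts = np.zeros((len(sites), n_nights), dtype=int)
    site_ix = {s: i for i, s in enumerate(sites)}
    dogs = events[events["species"] == dog_species]
    if len(dogs):
        located = _locate_events(dogs, sched)
        for _, ev in located.iterrows():
            counts[site_ix[str(ev["site_id"])], ev["night"] - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

NON_COVARIATE_COLUMNS = ("site_id", "trail")


def standardize_covariates(
    table: pd.DataFrame, exclude: tuple[str, ...] = NON_COVARIATE_COLUMNS
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Center and scale continuous covariates to mean 0, sd 1 (ddof=1).

    The binary ``trail`` indicator and ``site_id`` are passed through
    untouched.  Returns the standardized table and a ``{column: {mean, sd}}``
    scaling map for back-transforming response-curve axes.  A constant column
    is an error (it cannot be scaled and carries no information).
    """
    out = table.copy()
    scaling: dict[str, dict[str, float]] = {}
    for col in table.columns:
        if col in exclude:
            continue
        vals = table[col].astype(float)
        if vals.nunique() < 2:
            raise ValueError(f"covariate column {col!r} is constant")
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        out[col] = (vals - mu) / sd
        scaling[col] = {"mean": mu, "sd": sd}
    return out, scaling


def collinearity_screen(
    table: pd.DataFrame,
    r_max: float = 0.60,
    exclude: tuple[str, ...] = NON_COVARIATE_COLUMNS,
) -> pd.DataFrame:
    """List covariate pairs with |Pearson r| above ``r_max``.

    Pairwise-complete observations are used.  An empty frame is a pass.
    """
    cols = [c for c in table.columns if c not in exclude]
    rows = []
    for a, b in combinations(cols, 2):
        pair = table[[a, b]].astype(float).dropna()
        r = float(pair[a].corr(pair[b]))
        if abs(r) > r_max:
            rows.append({"var_a": a, "var_b": b, "r": r})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r"])
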