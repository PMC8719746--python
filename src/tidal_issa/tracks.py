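"""GPS-track ingestion, filtering, regularization, and step construction.

Tracks arrive as Movebank-style CSVs of fixes (bird, timestamp, planar x/y,
tag-estimated accuracy and speed).  Fixes are filtered to foraging-relevant
records (accuracy < 10 m, daylight, tag speed <= 5 m/s to drop flight),
resampled from the native 5-min interval to regular 10-min steps, and turned
into movement steps (straight-line displacements with a signed turn angle
relative to the previous heading, counterclockwise positive, in (-pi, pi]).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ElevationGrid
from .landscape import TideSeries
from .solar import solar_elevation

REQUIRED_COLUMNS = ("bird_id", "timestamp", "x", "y", "accuracy", "speed")

#: Default mapping from Movebank export headers to canonical names.
MOVEBANK_COLUMNS = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "utm-easting": "x",
    "utm-northing": "y",
    "eobs:horizontal-accuracy-estimate": "accuracy",
    "ground-speed": "speed",
}


def read_track_csv(path: str | Path | io.IOBase,
                   column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a fixes CSV into the canonical frame.

    Rows are sorted by (bird_id, timestamp); duplicate (bird, timestamp)
    rows collapse to the first occurrence (tag retransmission artifact).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(
            f"unparseable timestamp {df['timestamp'].iloc[row]!r} at data row {row}"
        )
    df = df.assign(timestamp=ts.dt.tz_localize(None))
    df = df.astype({c: float for c in ("x", "y", "accuracy", "speed")})
    df = (
        df.sort_values(["bird_id", "timestamp"], kind="stable")
        .drop_duplicates(subset=["bird_id", "timestamp"], keep="first")
        .reset_index(drop=True)
    )
    if (df["accuracy"] < 0).any() or (df["speed"] < 0).any():
        raise ValueError("accuracy and speed must be non-negative")
    return df[list(REQUIRED_COLUMNS)]


def read_bursts_csv(path: str | Path | io.IOBase, dialect: str = "long") -> pd.DataFrame:
    """Read accelerometer bursts.

    Two CSV dialects are supported:

    * ``"long"`` — one row per sample: bird_id, timestamp, ax, ay, az
      (samples of one burst share a timestamp; within-burst order is row
      order).
    * ``"packed"`` — one row per burst: bird_id, timestamp, ax, ay, az where
      each axis column holds space-separated sample values.

    Returns a frame with one row per burst: bird_id, timestamp, and object
    columns ax/ay/az holding float arrays.
    """
    df = pd.read_csv(path)
    for col in ("bird_id", "timestamp", "ax", "ay", "az"):
        if col not in df.columns:
            raise ValueError(f"burst CSV missing column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    if dialect == "packed":
        rows = [
            (r.bird_id, r.timestamp,
             np.fromstring(str(r.ax), sep=" "),
             np.fromstring(str(r.ay), sep=" "),
             np.fromstring(str(r.az), sep=" "))
            for r in df.itertuples()
        ]
    elif dialect == "long":
        rows = [
            (bird, t,
             g["ax"].to_numpy(dtype=float),
             g["ay"].to_numpy(dtype=float),
             g["az"].to_numpy(dtype=float))
            for (bird, t), g in df.groupby(["bird_id", "timestamp"], sort=True)
        ]
    else:
        raise ValueError(f"unknown burst dialect {dialect!r}")
    return pd.DataFrame(rows, columns=["bird_id", "timestamp", "ax", "ay", "az"])


def filter_fixes(
    fixes: pd.DataFrame,
    lat: float,
    lon: float,
    *,
    max_accuracy: float = 10.0,
    max_speed: float = 5.0,
    min_solar_elevation: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep foraging-relevant fixes; returns (filtered frame, removal counts).

    Rules (applied in sequence, so counts sum to total removed):
    accuracy strictly below ``max_accuracy`` metres; solar elevation at the
    site >= ``min_solar_elevation`` degrees (daylight); tag speed <=
    ``max_speed`` m/s (flight exclusion; boundary inclusive).
    """
    counts: dict[str, int] = {}
    ok_acc = fixes["accuracy"].to_numpy() < max_accuracy
    counts["accuracy"] = int((~ok_acc).sum())
    df = fixes[ok_acc]

    if len(df):
        elev = solar_elevation(df["timestamp"], lat, lon)
        ok_day = elev >= min_solar_elevation
    else:
        ok_day = np.zeros(0, dtype=bool)
    counts["daylight"] = int((~ok_day).sum())
    df = df[ok_day]

    ok_speed = df["speed"].to_numpy() <= max_speed
    counts["speed"] = int((~ok_speed).sum())
    df = df[ok_speed]
    return df.reset_index(drop=True), counts


def resample_track(
    fixes: pd.DataFrame,
    interval: float = 600.0,
    tolerance: float = 60.0,
) -> list[pd.DataFrame]:
    """Regularize one bird's fixes to ``interval`` seconds (greedy walk).

    Starting from the first fix, each subsequent fix is kept when its gap to
    the previous kept fix falls within ``interval +/- tolerance``; shorter
    gaps are skipped (over-sampling), longer gaps start a new segment.
    Segments with fewer than 3 fixes are dropped (a turn angle needs three
    points).
    """
    if fixes["bird_id"].nunique() > 1:
        raise ValueError("resample_track expects a single bird")
    t = fixes["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64) / 1e9
    order = np.argsort(t, kind="stable")
    t = t[order]

    segments: list[list[int]] = []
    current: list[int] = []
    for i in range(len(t)):
        if not current:
            current = [i]
            continue
        gap = t[i] - t[current[-1]]
        if gap < interval - tolerance:
            continue
        if gap <= interval + tolerance:
            current.append(i)
        else:
            segments.append(current)
            current = [i]
    if current:
        segments.append(current)

    out = []
    for seg in segments:
        if len(seg) >= 3:
            out.append(fixes.iloc[order[seg]].reset_index(drop=True))
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Map angles into (-pi, pi] (reversal maps to +pi)."""
    out = np.mod(-a + np.pi, 2 * np.pi)
    return np.pi - out


STEP_COLUMNS = [
    "bird_id", "stratum_id", "case", "t_start", "t_end",
    "x_start", "y_start", "x_end", "y_end",
    "step_length", "turn_angle", "heading", "heading_prev", "angle_defined",
]


def build_steps(segment: pd.DataFrame, stratum_prefix: str = "") -> pd.DataFrame:
    """Observed steps from one regular segment.

    A segment of n fixes yields n-2 steps: the first displacement only
    provides the heading needed for the first step's turn angle.  A step
    whose previous displacement has zero length gets ``angle_defined=False``
    (its length still feeds the length kernel; it is excluded from angle
    fitting and from availability sampling, which needs a heading).
    """
    if len(segment) < 3:
        raise ValueError("segment must have at least 3 fixes")
    x = segment["x"].to_numpy(dtype=float)
    y = segment["y"].to_numpy(dtype=float)
    t = segment["timestamp"].to_numpy()
    bird = segment["bird_id"].iloc[0]

    dx = np.diff(x)
    dy = np.diff(y)
    lengths = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)

    prev_len = lengths[:-1]
    defined = prev_len > 0
    turn = np.where(defined, _wrap_angle(headings[1:] - headings[:-1]), np.nan)

    n_steps = len(x) - 2
    return pd.DataFrame({
        "bird_id": bird,
        "stratum_id": [f"{stratum_prefix}{i}" for i in range(n_steps)],
        "case": "observed",
        "t_start": t[1:-1],
        "t_end": t[2:],
        "x_start": x[1:-1],
        "y_start": y[1:-1],
        "x_end": x[2:],
        "y_end": y[2:],
        "step_length": lengths[1:],
        "turn_angle": turn,
        "heading": headings[1:],
        "heading_prev": headings[:-1],
        "angle_defined": defined,
    })[STEP_COLUMNS]


def steps_from_fixes(fixes: pd.DataFrame, interval: float = 600.0,
                     tolerance: float = 60.0) -> pd.DataFrame:
    """Resample every bird's fixes and concatenate observed steps."""
    frames = []
    for bird, df in fixes.groupby("bird_id", sort=True):
        for j, seg in enumerate(resample_track(df, interval, tolerance)):
            frames.append(build_steps(seg, stratum_prefix=f"{bird}/s{j}/"))
    if not frames:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def apply_depth_window(steps: pd.DataFrame, lo: float = -0.5,
                       hi: float = 1.0) -> pd.DataFrame:
    """Restrict the selection analysis to depths within ``[lo, hi]`` metres.

    Any member (observed or available) whose end-of-step depth falls outside
    the window is removed.  A stratum whose observed member is removed, or
    (when available members exist) with none surviving, is dropped entirely.
    """
    if "depth_end" not in steps.columns:
        raise ValueError("steps need a depth_end column; attach covariates first")
    d = steps["depth_end"].to_numpy(dtype=float)
    kept = steps[(d >= lo) & (d <= hi)]
    has_avail = (steps["case"] == "available").any()
    by = kept.groupby("stratum_id", sort=False)["case"]
    n_obs = by.apply(lambda s: (s == "observed").sum())
    n_av = by.apply(lambda s: (s == "available").sum())
    good = n_obs[n_obs == 1].index
    if has_avail:
        good = good.intersection(n_av[n_av >= 1].index)
    return kept[kept["stratum_id"].isin(good)].reset_index(drop=True)


def attach_depth(fixes: pd.DataFrame, elev: ElevationGrid,
                 tide: TideSeries) -> pd.DataFrame:
    """Annotate fixes with time-specific water depth at their cell."""
    h = tide.interpolate(fixes["timestamp"])
    z = elev.value_at(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    return fixes.assign(depth=h - z)
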