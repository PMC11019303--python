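"""From raw GPS tables to a regular 3-h pack-level step series.

The pipeline is: merge collared individuals to one trajectory per pack,
snap fixes to a regular 3-h grid, build directed steps with length and
turning-angle attributes, classify each step by season and time of day,
and drop packs with too few complete steps.

Fixes are held in a pandas DataFrame with columns
``pack_id, individual_id, timestamp, x, y`` (timestamp UTC, coordinates
projected meters).  Steps carry one row per consecutive slot pair.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .solar import classify_solar

log = logging.getLogger(__name__)

PERIOD = pd.Timedelta(hours=3)
TOLERANCE = pd.Timedelta(minutes=15)

#: calendar-month -> breeding season (month numbers)
SEASON_BY_MONTH = {
    **dict.fromkeys((6, 7, 8, 9), "denning"),
    **dict.fromkeys((2, 3, 4, 5), "predenning"),
    **dict.fromkeys((10, 11, 12, 1), "postdenning"),
}

#: schedule-based diel classes by hour-of-day (8 slots/day at 3 h):
#: 2 crepuscular, 3 daytime, 3 nighttime
SCHEDULE_TOD = {
    6: "crepuscular",
    18: "crepuscular",
    9: "daytime",
    12: "daytime",
    15: "daytime",
    21: "nighttime",
    0: "nighttime",
    3: "nighttime",
}

FIX_COLUMNS = ["pack_id", "individual_id", "timestamp", "x", "y"]


def read_fixes(path, column_map: dict[str, str] | None = None, sep=None) -> pd.DataFrame:
    """Read a delimited GPS table; ``column_map`` maps file columns to
    the canonical names ``pack_id/individual_id/timestamp/x/y``."""
    df = pd.read_csv(path, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df[FIX_COLUMNS]


def write_fixes(path, fixes: pd.DataFrame, sep="\t") -> None:
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, sep=sep, index=False)


def _slot_index(timestamps: pd.Series, period: pd.Timedelta) -> np.ndarray:
    """Nearest epoch-anchored grid slot per timestamp."""
    ns = timestamps.astype("datetime64[ns]").astype("int64")
    return np.round(ns / period.value).astype("int64")


def regularize(
    fixes: pd.DataFrame,
    period: pd.Timedelta = PERIOD,
    tolerance: pd.Timedelta = TOLERANCE,
) -> pd.DataFrame:
    """Snap fixes to the regular grid; at most one fix per slot.

    The grid is anchored at UTC midnight (epoch-aligned multiples of
    ``period``).  A fix more than ``tolerance`` away from every grid
    point is dropped; when several fixes compete for one slot the
    nearest in time wins and the drop is logged.
    """
    df = fixes.sort_values("timestamp").reset_index(drop=True).copy()
    slots = _slot_index(df["timestamp"], period)
    ns = df["timestamp"].astype("datetime64[ns]").astype("int64")
    offset = np.abs(ns - slots * period.value)
    keep = offset <= tolerance.value
    dropped_off_grid = int((~keep).sum())
    df = df[keep].copy()
    df["slot"] = slots[keep]
    df["_offset"] = offset[keep]
    before = len(df)
    df = (
        df.sort_values(["pack_id", "slot", "_offset"])
        .drop_duplicates(["pack_id", "slot"], keep="first")
        .drop(columns="_offset")
    )
    if dropped_off_grid or len(df) < before:
        log.info(
            "regularize: dropped %d off-grid and %d duplicate-slot fixes",
            dropped_off_grid,
            before - len(df),
        )
    df["timestamp"] = pd.to_datetime(df["slot"] * period.value)
    return df.sort_values(["pack_id", "slot"]).reset_index(drop=True)


def merge_to_pack_trajectory(
    fixes: pd.DataFrame,
    pack_id,
    primary_individual=None,
    period: pd.Timedelta = PERIOD,
    tolerance: pd.Timedelta = TOLERANCE,
    max_pack_spread: float = 5_000.0,
) -> pd.DataFrame:
    """Collapse multiple collared individuals of one pack to one fix
    per time slot.

    The designated primary collar wins every slot it reports in; empty
    slots are filled from the other collars (earliest ``individual_id``
    on ties).  The primary defaults to the individual with the most
    fixes.  Simultaneous fixes farther apart than ``max_pack_spread``
    meters violate the cohesive-pack assumption and only produce a
    warning.  Provenance is kept in the ``individual_id`` column.
    """
    sub = fixes[fixes["pack_id"] == pack_id]
    if sub.empty:
        raise ValueError(f"no fixes for pack {pack_id!r}")
    # regularize per collar so one individual's fixes never displace
    # another's before the primary-wins merge rule is applied
    reg = pd.concat(
        [
            regularize(grp, period, tolerance)
            for _, grp in sub.groupby("individual_id", sort=False)
        ],
        ignore_index=True,
    )
    if primary_individual is None:
        counts = reg["individual_id"].value_counts()
        primary_individual = counts.index[np.argmax(counts.to_numpy())]
    # cohesion check on slots with several reporters
    for slot, grp in reg.groupby("slot"):
        if len(grp) > 1:
            xs, ys = grp["x"].to_numpy(), grp["y"].to_numpy()
            spread = np.hypot(xs[:, None] - xs, ys[:, None] - ys).max()
            if spread > max_pack_spread:
                warnings.warn(
                    f"pack {pack_id!r} slot {slot}: simultaneous fixes "
                    f"{spread:.0f} m apart exceed max_pack_spread; keeping primary",
                    stacklevel=2,
                )
    is_primary = (reg["individual_id"] == primary_individual).astype(int)
    reg = reg.assign(_rank=1 - is_primary)
    merged = (
        reg.sort_values(["slot", "_rank", "individual_id"])
        .drop_duplicates("slot", keep="first")
        .drop(columns="_rank")
    )
    return merged.sort_values("slot").reset_index(drop=True)


def build_steps(
    fixes: pd.DataFrame,
    period: pd.Timedelta = PERIOD,
    min_length_km: float = 0.125,
) -> pd.DataFrame:
    """One step per consecutive pair of occupied grid slots.

    The turn cosine compares the step's heading with the previous
    step's; it is undefined (NaN) after a gap or after a zero-length
    step (no heading).  ``complete`` flags steps whose endpoints, prior
    fix and turn are all defined.  Zero lengths are replaced by
    ``min_length_km`` before taking the log (half a typical grid cell),
    so ``log_sl`` is always finite.
    """
    out = []
    fixes = fixes.copy()
    if "slot" not in fixes:
        fixes["slot"] = _slot_index(fixes["timestamp"], period)
    for pack_id, grp in fixes.groupby("pack_id", sort=False):
        grp = grp.sort_values("slot")
        slot = grp["slot"].to_numpy()
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        t = grp["timestamp"].to_numpy()
        consec = slot[1:] == slot[:-1] + 1
        dx = x[1:] - x[:-1]
        dy = y[1:] - y[:-1]
        length_km = np.hypot(dx, dy) / 1000.0
        heading = np.arctan2(dy, dx)
        heading = np.where(length_km > 0, heading, np.nan)
        n = len(dx)
        prev_heading = np.full(n, np.nan)
        if n > 1:
            prev_ok = consec[1:] & consec[:-1]
            prev_heading[1:] = np.where(prev_ok, heading[:-1], np.nan)
        turn = heading - prev_heading
        turn = (turn + np.pi) % (2 * np.pi) - np.pi  # wrap to (-pi, pi]
        cos_ta = np.cos(turn)
        df = pd.DataFrame(
            {
                "pack_id": pack_id,
                "t_start": t[:-1],
                "t_end": t[1:],
                "x_start": x[:-1],
                "y_start": y[:-1],
                "x_end": x[1:],
                "y_end": y[1:],
                "heading": heading,
                "prev_heading": prev_heading,
                "step_length_km": length_km,
                "log_sl": np.log(np.maximum(length_km, min_length_km)),
                "turn_angle": turn,
                "cos_ta": cos_ta,
            }
        )
        df = df[consec].reset_index(drop=True)
        df["complete"] = np.isfinite(df["cos_ta"])
        out.append(df)
    steps = pd.concat(out, ignore_index=True)
    return steps


def classify_time_and_season(
    steps: pd.DataFrame,
    site_latitude: float | None = None,
    site_longitude: float | None = None,
    mode: str = "solar",
    crepuscular_band: float = 6.0,
) -> pd.DataFrame:
    """Attach season (calendar month of ``t_end``) and time-of-day.

    ``mode='solar'`` classifies by solar altitude at ``t_end`` at the
    site coordinates (crepuscular = within ``crepuscular_band`` degrees
    of the horizon); ``mode='schedule'`` uses the fixed 8-slot diel
    schedule (hour-of-day lookup) that the bundled simulator also uses.
    """
    steps = steps.copy()
    t_end = pd.DatetimeIndex(steps["t_end"])
    steps["season"] = [SEASON_BY_MONTH[m] for m in t_end.month]
    if mode == "schedule":
        steps["tod"] = [SCHEDULE_TOD[h] for h in t_end.hour]
    elif mode == "solar":
        if site_latitude is None or site_longitude is None:
            raise ValueError("solar classification needs site coordinates")
        steps["tod"] = classify_solar(
            t_end, site_latitude, site_longitude, crepuscular_band
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return steps


def filter_trajectories(
    steps: pd.DataFrame, min_complete: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop packs with fewer than ``min_complete`` complete steps.

    Returns the retained steps and a per-pack summary (complete-step
    count, span, retained flag).  An all-excluded input yields an empty
    step table, not an error.
    """
    rows = []
    keep_packs = []
    for pack_id, grp in steps.groupby("pack_id", sort=False):
        n_complete = int(grp["complete"].sum())
        retained = n_complete >= min_complete
        rows.append(
            {
                "pack_id": pack_id,
                "n_steps": len(grp),
                "n_complete": n_complete,
                "span_days": (grp["t_end"].max() - grp["t_start"].min())
                / pd.Timedelta(days=1),
                "retained": retained,
            }
        )
        if retained:
            keep_packs.append(pack_id)
    summary = pd.DataFrame(rows)
    retained_steps = steps[steps["pack_id"].isin(keep_packs)].reset_index(drop=True)
    return retained_steps, summary


def write_steps(path, steps: pd.DataFrame, sep="\t") -> None:
    out = steps.copy()
    for col in ("t_start", "t_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, sep=sep, index=False)
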