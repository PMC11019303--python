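"""Solar altitude for day/night/crepuscular classification.

A compact NOAA-style solar position computation (Fourier-series equation
of time and declination), accurate to well under half a degree of
elevation — ample for assigning 3-h GPS steps to diel classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation(timestamps, latitude: float, longitude: float) -> np.ndarray:
    """Solar elevation angle (degrees) at UTC ``timestamps``.

    Parameters
    ----------
    timestamps
        Anything ``pd.DatetimeIndex`` accepts; interpreted as UTC.
    latitude, longitude
        Site coordinates in decimal degrees (east positive).
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    doy = ts.dayofyear.to_numpy(float)
    hours = (
        ts.hour.to_numpy(float)
        + ts.minute.to_numpy(float) / 60.0
        + ts.second.to_numpy(float) / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1.0 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * longitude  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle
    lat = np.deg2rad(latitude)
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def classify_solar(
    timestamps,
    latitude: float,
    longitude: float,
    crepuscular_band: float = 6.0,
) -> np.ndarray:
    """Map timestamps to {'daytime','nighttime','crepuscular'}.

    Crepuscular means solar elevation within ``+-crepuscular_band``
    degrees of the horizon (civil twilight plus a symmetric daylight
    margin by default); otherwise the sign of the elevation decides.
    """
    elev = solar_elevation(timestamps, latitude, longitude)
    out = np.where(elev > crepuscular_band, "daytime", "nighttime")
    out = np.where(np.abs(elev) <= crepuscular_band, "crepuscular", out)
    return out.astype(object)
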