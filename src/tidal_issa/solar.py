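"""Solar elevation from the standard NOAA solar-position equations.

Used to decide "daylight": a fix is kept when the sun's elevation at the
fix's timestamp and the study site's latitude/longitude is at or above a
threshold (0 deg = geometric sunrise/sunset; about -6 deg approximates civil
twilight).  Accuracy of this low-precision ephemeris is a few hundredths of
a degree over 1900-2100, far finer than needed for a daylight gate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def solar_elevation(timestamps, lat: float, lon: float) -> np.ndarray:
    """Solar elevation angle (degrees) at UTC ``timestamps``.

    Parameters
    ----------
    timestamps : datetime-like scalar or sequence (treated as UTC)
    lat, lon : site coordinates in decimal degrees (east positive)
    """
    scalar = np.ndim(timestamps) == 0
    arr = [timestamps] if scalar else list(timestamps)
    ts = pd.DatetimeIndex(pd.to_datetime(arr, utc=True)).tz_localize(None)

    # Julian centuries since J2000.0
    jd = ts.asi8 / 86400e9 + 2440587.5
    t = (jd - 2451545.0) / 36525.0

    # Geometric mean longitude and anomaly of the sun (deg)
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    mr = np.deg2rad(m)

    # Equation of center, true longitude, apparent longitude
    c = (np.sin(mr) * (1.914602 - t * (0.004817 + 0.000014 * t))
         + np.sin(2 * mr) * (0.019993 - 0.000101 * t)
         + np.sin(3 * mr) * 0.000289)
    true_long = l0 + c
    omega = 125.04 - 1934.136 * t
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.deg2rad(omega))

    # Obliquity of the ecliptic (corrected)
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.8150 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(np.deg2rad(omega))
    eps_r = np.deg2rad(eps)

    # Solar declination
    decl = np.arcsin(np.sin(eps_r) * np.sin(np.deg2rad(app_long)))

    # Equation of time (minutes)
    y = np.tan(eps_r / 2.0) ** 2
    l0r = np.deg2rad(l0)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * l0r)
        - 2.0 * ecc * np.sin(mr)
        + 4.0 * ecc * y * np.sin(mr) * np.cos(2 * l0r)
        - 0.5 * y * y * np.sin(4 * l0r)
        - 1.25 * ecc * ecc * np.sin(2 * mr)
    )

    # True solar time -> hour angle (deg)
    minutes = (ts.hour * 60 + ts.minute + ts.second / 60.0
               + ts.microsecond / 6e7).to_numpy(dtype=float)
    tst = np.mod(minutes + eot + 4.0 * lon, 1440.0)
    ha = np.where(tst / 4.0 < 0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)

    lat_r = np.deg2rad(lat)
    zenith = np.arccos(
        np.clip(
            np.sin(lat_r) * np.sin(decl)
            + np.cos(lat_r) * np.cos(decl) * np.cos(np.deg2rad(ha)),
            -1.0, 1.0,
        )
    )
    elev = 90.0 - np.rad2deg(zenith)
    return float(elev[0]) if scalar else elev
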