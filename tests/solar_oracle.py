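"""Independent solar-position oracle for sunrise checks.

Implements the PSA solar ephemeris (Blanco-Muriel et al. 2001), a different
formulation from the production NOAA-equation route, and locates sunrise by
bisecting the altitude crossing of the effective horizon. Used only by
tests and the acceptance script.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone


def psa_sun_altitude(t: datetime, lat: float, lon: float) -> float:
    """Apparent solar altitude (degrees) at UTC instant t (PSA algorithm)."""
    jd = 2440587.5 + t.timestamp() / 86400.0
    n = jd - 2451545.0
    omega = 2.1429 - 0.0010394594 * n
    mean_long = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_long = (
        mean_long
        + 0.03341607 * math.sin(mean_anom)
        + 0.00034894 * math.sin(2 * mean_anom)
        - 0.0001134
        - 0.0000203 * math.sin(omega)
    )
    obliquity = 0.4090928 - 6.2140e-9 * n + 0.0000396 * math.cos(omega)
    ra = math.atan2(math.cos(obliquity) * math.sin(ecl_long), math.cos(ecl_long))
    if ra < 0:
        ra += 2 * math.pi
    decl = math.asin(math.sin(obliquity) * math.sin(ecl_long))

    ut_hours = (t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9)
    gmst = 6.6974243242 + 0.0657098283 * n + ut_hours
    lmst = math.radians(gmst * 15.0 + lon)
    hour_angle = lmst - ra
    phi = math.radians(lat)
    sin_alt = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(hour_angle)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))


def psa_sunrise_utc(date, lat: float, lon: float, elev_m: float = 0.0) -> datetime:
    """Sunrise (UTC) by bisection of the PSA altitude against the horizon.

    Horizon altitude is -0.833 deg (refraction + semidiameter) minus the
    elevation dip 1.76' * sqrt(elev_m).
    """
    target = -(0.833 + 1.76 * math.sqrt(max(elev_m, 0.0)) / 60.0)
    # search between local midnight and local noon (approximate, via longitude)
    local_offset = timedelta(hours=lon / 15.0)
    lo = datetime(date.year, date.month, date.day, 0, 0, tzinfo=timezone.utc) - local_offset
    hi = lo + timedelta(hours=12)
    f_lo = psa_sun_altitude(lo, lat, lon) - target
    f_hi = psa_sun_altitude(hi, lat, lon) - target
    if not (f_lo < 0 < f_hi):
        raise ValueError(f"no sunrise bracket at lat {lat} on {date}")
    for _ in range(40):
        mid = lo + (hi - lo) / 2
        if psa_sun_altitude(mid, lat, lon) - target < 0:
            lo = mid
        else:
            hi = mid
    return lo + (hi - lo) / 2


#: Twenty (name, lat, lon, elev_m, date) places spanning latitudes/seasons.
TEST_BATTERY = [
    ("pittsburgh_solstice", 40.4406, -79.9959, 300.0, (2016, 6, 21)),
    ("pittsburgh_winter", 40.4406, -79.9959, 300.0, (2016, 12, 21)),
    ("nyc_spring", 40.7900, -73.9526, 30.0, (2015, 3, 20)),
    ("nyc_fall", 40.7900, -73.9526, 30.0, (2015, 9, 23)),
    ("quito", -0.18, -78.47, 2850.0, (2017, 1, 15)),
    ("singapore", 1.35, 103.82, 15.0, (2018, 7, 4)),
    ("reykjavik_summer", 64.13, -21.90, 20.0, (2016, 5, 1)),
    ("reykjavik_fall", 64.13, -21.90, 20.0, (2016, 10, 1)),
    ("sydney_winter", -33.87, 151.21, 40.0, (2019, 6, 21)),
    ("sydney_summer", -33.87, 151.21, 40.0, (2019, 12, 21)),
    ("cape_town", -33.92, 18.42, 25.0, (2020, 4, 10)),
    ("tokyo", 35.68, 139.69, 40.0, (2015, 11, 2)),
    ("denver", 39.74, -104.99, 1609.0, (2018, 2, 14)),
    ("la_paz", -16.50, -68.15, 3640.0, (2017, 8, 21)),
    ("helsinki_spring", 60.17, 24.94, 10.0, (2021, 4, 15)),
    ("anchorage_fall", 61.22, -149.90, 30.0, (2019, 9, 10)),
    ("mumbai", 19.08, 72.88, 10.0, (2016, 6, 1)),
    ("buenos_aires", -34.60, -58.38, 25.0, (2018, 10, 30)),
    ("london", 51.51, -0.13, 10.0, (2022, 1, 5)),
    ("nairobi", -1.29, 36.82, 1795.0, (2020, 12, 1)),
]
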