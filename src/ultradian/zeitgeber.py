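"""Zeitgeber-time conversion of death times.

Postmortem time-of-death (TOD) studies order single-timepoint subjects along
the daily cycle. Because sunrise — the entraining light cue — varies with
date, latitude, longitude and elevation, clock time is converted to Zeitgeber
time (ZT): hours relative to local sunrise at the place of death, with ZT 0 at
sunrise. A death ``t`` hours after the previous sunrise maps to ZT ``t`` when
``t < 18``; otherwise it is expressed as a negative offset to the *next*
sunrise, so every subject lands in the half-open window [-6, 18).

Sunrise is computed with the NOAA low-accuracy solar equations (refraction
zenith 90.833 deg), with an elevation dip correction of 1.76' * sqrt(elev_m)
added to the zenith. Time-zone and daylight-saving handling is delegated to
the IANA database via :mod:`zoneinfo`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, timedelta, timezone
from typing import Optional
from zoneinfo import ZoneInfo

__all__ = [
    "SubjectRecord",
    "NoSunriseError",
    "ZeitgeberError",
    "sunrise_utc",
    "tod_to_zt",
    "add_zt_column",
    "ZT_LOW",
    "ZT_HIGH",
]

#: Half-open ZT window: previous-sunrise branch for t < 18 h, next-sunrise
#: branch (negative values) down to -6 h.
ZT_LOW = -6.0
ZT_HIGH = 18.0

#: Maximum supported absolute latitude (degrees); beyond this, polar
#: day/night would need dedicated handling.
MAX_LATITUDE = 66.0

_STANDARD_ZENITH = 90.833  # degrees: refraction + solar semidiameter


class ZeitgeberError(ValueError):
    """Invalid subject data for ZT conversion."""


class NoSunriseError(ZeitgeberError):
    """The sun does not rise (or set) at this latitude on this date."""


@dataclass
class SubjectRecord:
    """One donor: death time/place, cohort, batch/site and covariates.

    ``death_local`` is a naive local datetime interpreted in the IANA zone
    ``tz``; ``lon`` is east-positive degrees; ``elev_m`` is elevation of the
    death place in metres. ``zt`` is derived, in hours in [-6, 18).
    """

    subject_id: str
    cohort: str
    death_local: datetime
    tz: str
    lat: float
    lon: float
    elev_m: float = 0.0
    site: str = ""
    age: Optional[float] = None
    sex: Optional[str] = None
    ph: Optional[float] = None
    pmi: Optional[float] = None
    zt: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if abs(self.lat) > MAX_LATITUDE:
            raise ZeitgeberError(
                f"subject {self.subject_id}: |latitude| {abs(self.lat):.2f} exceeds "
                f"{MAX_LATITUDE} (polar day/night not supported)"
            )


def _julian_century(t: datetime) -> float:
    """Julian centuries since J2000.0 for an aware UTC datetime."""
    jd = 2440587.5 + t.timestamp() / 86400.0
    return (jd - 2451545.0) / 36525.0


def _solar_declination_eot(jc: float) -> tuple[float, float]:
    """Solar declination (radians) and equation of time (minutes).

    NOAA low-accuracy equations (as in the NOAA solar calculator spreadsheet).
    """
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    eps_rad = math.radians(eps)
    decl = math.asin(math.sin(eps_rad) * math.sin(math.radians(app_long)))

    y = math.tan(eps_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mrad)
        + 4 * ecc * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mrad)
    )
    return decl, eot


def _zenith(elev_m: float) -> float:
    """Effective sunrise zenith: standard refraction plus horizon dip.

    Dip of the apparent horizon is ~1.76 arcmin per sqrt(metre) of elevation,
    which makes sunrise earlier at altitude.
    """
    dip_deg = 1.76 * math.sqrt(max(elev_m, 0.0)) / 60.0
    return _STANDARD_ZENITH + dip_deg


def sunrise_utc(date: _date, lat: float, lon: float, elev_m: float = 0.0) -> datetime:
    """UTC instant of sunrise at (lat, lon, elev_m) on the given UTC date.

    Parameters
    ----------
    date : datetime.date
        Civil date (UTC) of the sunrise sought.
    lat, lon : float
        Degrees; longitude east-positive.
    elev_m : float
        Elevation of the observer in metres (dip correction).

    Raises
    ------
    NoSunriseError
        If the sun never crosses the effective horizon on that date.
    """
    if abs(lat) > MAX_LATITUDE:
        raise ZeitgeberError(f"|latitude| {abs(lat):.2f} exceeds {MAX_LATITUDE}")
    zen = math.radians(_zenith(elev_m))
    phi = math.radians(lat)

    # Start from local solar noon and iterate: declination and the equation
    # of time are re-evaluated at the current sunrise estimate (two passes
    # bring the result well under a second of drift).
    est = datetime(date.year, date.month, date.day, 12, 0, tzinfo=timezone.utc) - timedelta(
        hours=lon / 15.0
    )
    for _ in range(3):
        jc = _julian_century(est)
        decl, eot = _solar_declination_eot(jc)
        cos_ha = (math.cos(zen) - math.sin(phi) * math.sin(decl)) / (
            math.cos(phi) * math.cos(decl)
        )
        if cos_ha > 1.0 or cos_ha < -1.0:
            raise NoSunriseError(
                f"no sunrise at lat {lat:.2f} on {date.isoformat()} (polar day/night)"
            )
        ha_deg = math.degrees(math.acos(cos_ha))
        noon_min = 720.0 - 4.0 * lon - eot
        sunrise_min = noon_min - 4.0 * ha_deg
        est = datetime(date.year, date.month, date.day, tzinfo=timezone.utc) + timedelta(
            minutes=sunrise_min
        )
    return est


def _death_utc(record: SubjectRecord) -> datetime:
    if record.death_local is None:
        raise ZeitgeberError(f"subject {record.subject_id}: missing death time")
    if record.lat is None or record.lon is None or math.isnan(record.lat) or math.isnan(record.lon):
        raise ZeitgeberError(f"subject {record.subject_id}: missing death coordinates")
    local = record.death_local
    if local.tzinfo is None:
        local = local.replace(tzinfo=ZoneInfo(record.tz))
    return local.astimezone(timezone.utc)


def tod_to_zt(record: SubjectRecord) -> float:
    """Zeitgeber time of death, hours in [-6, 18).

    ZT = t hours after the previous sunrise when t < 18, otherwise the
    (negative) offset to the next sunrise. The boundary t == 18 maps to the
    negative branch (half-open window).
    """
    death = _death_utc(record)

    sunrises = []
    base = death.date()
    for d in (-2, -1, 0, 1, 2):
        try:
            sunrises.append(sunrise_utc(base + timedelta(days=d), record.lat, record.lon, record.elev_m))
        except NoSunriseError:
            raise
    prev = max((s for s in sunrises if s <= death), default=None)
    nxt = min((s for s in sunrises if s > death), default=None)
    if prev is None or nxt is None:  # pragma: no cover - +-2 d always brackets
        raise ZeitgeberError(f"subject {record.subject_id}: could not bracket sunrise")

    t = (death - prev).total_seconds() / 3600.0
    if t < ZT_HIGH:
        zt = t
    else:
        zt = -(nxt - death).total_seconds() / 3600.0
        # sunrise-to-sunrise is not exactly 24 h; near t = 18 the seasonal
        # drift (< ~2 min/day) can push the negative branch marginally past
        # -6, which we clamp back onto the window edge
        if ZT_LOW - 0.1 <= zt < ZT_LOW:
            zt = ZT_LOW
    if not (ZT_LOW <= zt < ZT_HIGH):  # pragma: no cover - ~24 h day guarantees this
        raise ZeitgeberError(f"subject {record.subject_id}: ZT {zt:.3f} outside [-6, 18)")
    record.zt = zt
    return zt


def add_zt_column(subjects) -> "pandas.DataFrame":  # noqa: F821 - forward ref
    """Compute a ``zt`` column for a subject metadata table.

    Expects the columns of the subject TSV schema (subject_id, death_datetime
    ISO-8601, tz, lat, lon, elev_m, ...). Returns a copy with ``zt`` added.
    """
    import pandas as pd

    out = subjects.copy()
    zts = []
    for row in out.itertuples(index=False):
        rec = SubjectRecord(
            subject_id=str(row.subject_id),
            cohort=str(getattr(row, "cohort", "")),
            death_local=datetime.fromisoformat(str(row.death_datetime)),
            tz=str(row.tz),
            lat=float(row.lat),
            lon=float(row.lon),
            elev_m=float(getattr(row, "elev_m", 0.0)),
            site=str(getattr(row, "site", "")),
        )
        zts.append(tod_to_zt(rec))
    out["zt"] = pd.Series(zts, index=out.index, dtype=float)
    return out
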