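"""Screening and quality control of sighting and telemetry records.

Opportunistic sightings are retained only when verified ("confirmed"), and
Canadian records dated in the sedentary summering period (25 May - 20
August, inclusive) are removed because they do not represent active
migration.  GPS telemetry tracks pass three sequential plausibility filters
per bird: strictly increasing timestamps, displacement rate <= 100 km/h
between consecutive retained fixes, and removal of spike fixes forming an
acute turn angle (< 5 degrees) with both legs longer than 50 km.  Retained
ground fixes (instantaneous velocity <= 2.6 m/s) are chained into stopover
sites broken by moves of more than 15 km, and each site is represented by
the arithmetic centroid of its member fixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "screen_sightings",
    "classify_flight",
    "qc_telemetry",
    "cluster_stopovers",
    "assemble_migration_locations",
]

SUMMER_START = (5, 25)  # 25 May
SUMMER_END = (8, 20)  # 20 August


@dataclass(frozen=True)
class QCThresholds:
    """Filter constants; defaults are the published field-method values."""

    flight_velocity_ms: float = 2.6
    max_speed_kmh: float = 100.0
    min_turn_angle_deg: float = 5.0
    turn_leg_km: float = 50.0
    stopover_break_km: float = 15.0


def _in_summer(dates: pd.Series) -> pd.Series:
    md = dates.dt.month * 100 + dates.dt.day
    return (md >= SUMMER_START[0] * 100 + SUMMER_START[1]) & (md <= SUMMER_END[0] * 100 + SUMMER_END[1])


def screen_sightings(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain confirmed sightings outside the Canadian summering window.

    Returns ``(retained, rejections)``; rejections carry a ``reason`` column
    with machine-readable codes (``bad_date``, ``not_confirmed``,
    ``canada_summer``).  Dates may arrive as strings; unparseable dates are
    rejected, never raised.
    """
    rec = records.copy()
    dates = pd.to_datetime(rec["date"], errors="coerce", format="mixed")
    reason = pd.Series(pd.NA, index=rec.index, dtype="string")
    reason[dates.isna()] = "bad_date"
    not_conf = rec["classification"].astype(str).str.lower() != "confirmed"
    reason[reason.isna() & not_conf] = "not_confirmed"
    ca_summer = (rec["country"].astype(str).str.upper() == "CA") & _in_summer(dates.fillna(pd.Timestamp("1900-01-01")))
    reason[reason.isna() & ca_summer] = "canada_summer"
    rejected = rec.loc[reason.notna()].copy()
    rejected["reason"] = reason[reason.notna()]
    retained = rec.loc[reason.isna()].copy()
    retained["date"] = dates[reason.isna()]
    return retained, rejected


def classify_flight(velocity, threshold_ms: float = 2.6):
    """Flight/ground classification from instantaneous velocity (m/s).

    Strict: flight iff velocity > threshold.  Missing velocities classify as
    ground (a misclassified flight fix joins a stopover cluster rather than
    being lost); negative velocities are an error.
    """
    v = np.asarray(velocity, dtype=float)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValueError("negative instantaneous velocity")
    n_missing = int(np.sum(~np.isfinite(v)))
    if n_missing:
        log.warning("classify_flight: %d missing velocities treated as ground", n_missing)
    flight = np.where(np.isfinite(v), v > threshold_ms, False)
    if np.isscalar(velocity) or np.ndim(velocity) == 0:
        return "flight" if bool(flight) else "ground"
    return np.where(flight, "flight", "ground")


def _turn_angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Interior angle at apex b of the triple a-b-c, degrees."""
    u = a - b
    v = c - b
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0 or nv == 0:
        return 180.0
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def qc_telemetry(
    fixes: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plausibility filtering of per-bird GPS fixes.

    ``fixes`` needs bird_id, timestamp, x, y (meters) columns and must be in
    per-bird collection order.  Rules applied sequentially per bird against
    the last *retained* fix:

    1. timestamp not strictly later -> ``rejected_time``
    2. displacement rate > ``max_speed_kmh`` -> ``rejected_speed``
    3. apex of a turn sharper than ``min_turn_angle_deg`` with both legs
       longer than ``turn_leg_km`` -> ``rejected_angle`` (re-checked until
       no retained triple violates, making the pass idempotent)

    Returns ``(retained, rejections)``; rejections carry ``reason``.
    """
    if fixes.empty:
        empty = fixes.copy()
        rej = fixes.copy()
        rej["reason"] = pd.Series(dtype="string")
        return empty, rej
    keep_idx: list = []
    reject: list[tuple] = []  # (index, reason)
    leg_m = thresholds.turn_leg_km * 1e3
    for _, grp in fixes.groupby("bird_id", sort=False):
        ts = grp["timestamp"].to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        idx = grp.index.to_numpy()
        retained: list[int] = []  # positions within grp
        for i in range(len(grp)):
            if retained:
                j = retained[-1]
                dt = (ts[i] - ts[j]) / np.timedelta64(1, "h")
                if dt <= 0:
                    reject.append((idx[i], "rejected_time"))
                    continue
                dist_km = np.hypot(*(xy[i] - xy[j])) / 1e3
                if dist_km / dt > thresholds.max_speed_kmh:
                    reject.append((idx[i], "rejected_speed"))
                    continue
            retained.append(i)
            # spike removal on the last retained triple, repeated to a fixed point
            while len(retained) >= 3:
                p, q, r = retained[-3], retained[-2], retained[-1]
                legs_ok = (
                    np.hypot(*(xy[q] - xy[p])) > leg_m and np.hypot(*(xy[r] - xy[q])) > leg_m
                )
                if legs_ok and _turn_angle_deg(xy[p], xy[q], xy[r]) < thresholds.min_turn_angle_deg:
                    reject.append((idx[q], "rejected_angle"))
                    del retained[-2]
                else:
                    break
        keep_idx.extend(idx[retained])
    retained_df = fixes.loc[keep_idx].copy()
    retained_df["status"] = "retained"
    if reject:
        rej_index, reasons = zip(*reject)
        rejections = fixes.loc[list(rej_index)].copy()
        rejections["reason"] = list(reasons)
    else:
        rejections = fixes.iloc[0:0].copy()
        rejections["reason"] = pd.Series(dtype="string")
    return retained_df, rejections


def cluster_stopovers(
    ground_fixes: pd.DataFrame,
    break_km: float = 15.0,
) -> pd.DataFrame:
    """Chain consecutive per-bird ground fixes into stopover sites.

    A new site starts whenever the move from the previous ground fix exceeds
    ``break_km``.  Every ground fix belongs to exactly one site.  Returns one
    row per site: bird_id, site, n_fixes, centroid_x, centroid_y, first_time,
    last_time, member_fix_ids.
    """
    rows = []
    if ground_fixes.empty:
        return pd.DataFrame(
            columns=["bird_id", "site", "n_fixes", "centroid_x", "centroid_y", "first_time", "last_time", "member_fix_ids"]
        )
    for bird, grp in ground_fixes.groupby("bird_id", sort=False):
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        step = np.hypot(*np.diff(xy, axis=0).T) / 1e3
        site_id = np.concatenate([[0], np.cumsum(step > break_km)])
        for s in np.unique(site_id):
            sel = site_id == s
            sub = grp.loc[sel]
            rows.append(
                {
                    "bird_id": bird,
                    "site": int(s),
                    "n_fixes": int(sel.sum()),
                    "centroid_x": float(sub["x"].mean()),
                    "centroid_y": float(sub["y"].mean()),
                    "first_time": sub["timestamp"].iloc[0],
                    "last_time": sub["timestamp"].iloc[-1],
                    "member_fix_ids": list(sub.index),
                }
            )
    return pd.DataFrame(rows)


def assemble_migration_locations(
    sites: pd.DataFrame,
    flight_fixes: pd.DataFrame,
) -> pd.DataFrame:
    """One analysis location per stopover centroid plus one per flight fix."""
    parts = []
    if not sites.empty:
        cent = pd.DataFrame(
            {
                "bird_id": sites["bird_id"],
                "x": sites["centroid_x"],
                "y": sites["centroid_y"],
                "date": pd.to_datetime(sites["first_time"]),
                "kind": "stopover_centroid",
            }
        )
        parts.append(cent)
    if not flight_fixes.empty:
        fl = pd.DataFrame(
            {
                "bird_id": flight_fixes["bird_id"],
                "x": flight_fixes["x"],
                "y": flight_fixes["y"],
                "date": pd.to_datetime(flight_fixes["timestamp"]),
                "kind": "flight_fix",
            }
        )
        parts.append(fl)
    if not parts:
        return pd.DataFrame(columns=["bird_id", "x", "y", "date", "kind", "year", "source"])
    out = pd.concat(parts, ignore_index=True)
    out["year"] = out["date"].dt.year
    out["source"] = "telemetry"
    return out
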