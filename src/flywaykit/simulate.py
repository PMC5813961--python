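"""Synthetic flyway generator with known ground truth.

Emulates the statistical structure the corridor and trend analyses assume:
a ~3,900-km south-to-north flyway with a gently curving centerline,
latitude-varying lateral spread, opportunistic sightings spanning
1942-2016 and GPS telemetry tracks spanning 2010-2016 (4-5 fixes per day,
stopovers, in-flight fixes, and optionally planted implausible-location
artifacts).

Lateral structure: each location falls west or east of the centerline with
probability 1/2 and its distance from the centerline is half-normal.  The
side-specific scale parameter is the *mean* absolute offset s (so the
half-normal sigma is s*sqrt(pi/2)); s declines linearly in time at the
side's contraction rate, which makes the contraction rate exactly the
year-slope of the mean signed offset on that side -- the quantity the trend
model estimates.  An eastward drift translates the whole centerline.  All
ground-truth per-window slopes are therefore available in closed form:

    positional slope = drift + (c_west - c_east) / 2
    west-side offset slope = +c_west,  east-side = -c_east
    absolute-offset slope = -(c_west + c_east) / 2      (narrowing when > 0
                                                         contraction)

Defaults mirror the study system: 13 windows of 300 km, ~5,000 sightings,
58 telemetered birds, eastward drift 1.2 km/year concentrated contraction
of the west flank at 0.9 km/year with a stable east flank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import EquidistantConic

__all__ = [
    "SyntheticScenario",
    "simulate_sightings",
    "simulate_telemetry",
    "inject_artifacts",
    "write_fixtures",
]

_HN = float(np.sqrt(np.pi / 2.0))  # mean-to-sigma factor for the half-normal


def _default_spread_west() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(70.0, 125.0, 13), 3))


def _default_spread_east() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(50.0, 100.0, 13), 3))


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters of the synthetic flyway."""

    y_south_m: float = -1.33e6  # ~28N on the central meridian
    window_height_m: float = 300e3
    n_windows: int = 13
    # centerline control points (y_m, x_m), south to north
    centerline: tuple[tuple[float, float], ...] = (
        (-1.33e6, 1.0e5),
        (0.6e6, 0.0),
        (2.57e6, -2.5e5),
    )
    spread_west0_km: tuple[float, ...] = field(default_factory=_default_spread_west)
    spread_east0_km: tuple[float, ...] = field(default_factory=_default_spread_east)
    contraction_west_km_per_year: float = 0.9
    contraction_east_km_per_year: float = 0.0
    drift_km_per_year: float = 1.2
    years_opp: tuple[int, int] = (1942, 2016)
    years_tel: tuple[int, int] = (2010, 2016)
    n_sightings: int = 5000
    n_birds: int = 58
    fixes_per_day: tuple[int, int] = (4, 5)
    artifact_rate: float = 0.0
    flight_speed_ms: tuple[float, float] = (8.0, 25.0)
    ground_speed_ms: tuple[float, float] = (0.0, 2.0)
    summer_contamination: float = 0.0  # fraction of CA records given summer dates
    nonconfirmed_rate: float = 0.0  # fraction downgraded to 'probable'
    canada_lat: float = 49.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structure --------------------------------------------------------

    @property
    def flyway_length_m(self) -> float:
        return self.n_windows * self.window_height_m

    @property
    def y_north_m(self) -> float:
        return self.y_south_m + self.flyway_length_m

    def validate(self) -> None:
        if self.n_windows < 1:
            raise ValueError("n_windows >= 1 required")
        if len(self.spread_west0_km) != self.n_windows or len(self.spread_east0_km) != self.n_windows:
            raise ValueError("per-window spread arrays must have length n_windows")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")
        if self.ground_speed_ms[1] > 2.6 or self.flight_speed_ms[0] <= 2.6:
            raise ValueError("ground/flight speed ranges must be disjoint around 2.6 m/s")
        tmax = self.years_opp[1] - 1942
        for name, s0, c in [
            ("west", self.spread_west0_km, self.contraction_west_km_per_year),
            ("east", self.spread_east0_km, self.contraction_east_km_per_year),
        ]:
            final = np.asarray(s0) - c * tmax
            if np.any(final <= 0):
                raise ValueError(
                    f"{name} spread becomes nonpositive by year {self.years_opp[1]} "
                    f"(min {final.min():.2f} km); reduce contraction or raise the baseline spread"
                )

    def window_of_y(self, y) -> np.ndarray:
        w = np.floor((np.asarray(y, dtype=float) - self.y_south_m) / self.window_height_m).astype(int) + 1
        return np.clip(w, 1, self.n_windows)

    def centerline_x(self, y, year) -> np.ndarray:
        pts = np.asarray(self.centerline, dtype=float)
        base = np.interp(np.asarray(y, dtype=float), pts[:, 0], pts[:, 1])
        t = np.asarray(year, dtype=float) - 1942.0
        return base + self.drift_km_per_year * 1e3 * t

    def spread_km(self, side: str, window, year) -> np.ndarray:
        s0 = np.asarray(self.spread_west0_km if side == "west" else self.spread_east0_km)
        c = self.contraction_west_km_per_year if side == "west" else self.contraction_east_km_per_year
        w = np.asarray(window, dtype=int) - 1
        t = np.asarray(year, dtype=float) - 1942.0
        return s0[w] - c * t

    def true_slopes(self) -> pd.DataFrame:
        """Closed-form per-window trend slopes implied by the parameters, km/yr."""
        cw = self.contraction_west_km_per_year
        ce = self.contraction_east_km_per_year
        d = self.drift_km_per_year
        w = np.arange(1, self.n_windows + 1)
        return pd.DataFrame(
            {
                "window": w,
                "positional": d + 0.5 * (cw - ce),
                "west_offset": cw,
                "east_offset": -ce,
                "abs_offset": -0.5 * (cw + ce),
            }
        ).set_index("window")

    def stationary(self) -> "SyntheticScenario":
        """The null scenario: no drift, no contraction."""
        return replace(
            self,
            drift_km_per_year=0.0,
            contraction_west_km_per_year=0.0,
            contraction_east_km_per_year=0.0,
        )


def _lateral_offset(scn: SyntheticScenario, window, year, side_sign, rng) -> np.ndarray:
    side = np.where(np.asarray(side_sign) < 0, "west", "east")
    s = np.where(
        side == "west",
        scn.spread_km("west", window, year),
        scn.spread_km("east", window, year),
    )
    mag = np.abs(rng.standard_normal(np.shape(side_sign))) * s * _HN * 1e3
    return side_sign * mag


_SPRING = ((3, 20), (5, 20))
_AUTUMN = ((9, 5), (11, 10))
_SUMMER = ((6, 1), (8, 10))


def _random_dates(years: np.ndarray, windows_mdmd, rng) -> pd.Series:
    """Random dates within a (month, day)..(month, day) window per record."""
    out = []
    for yr, (start, end) in zip(years, windows_mdmd):
        d0 = pd.Timestamp(int(yr), *start)
        d1 = pd.Timestamp(int(yr), *end)
        span = (d1 - d0).days
        out.append(d0 + pd.Timedelta(days=int(rng.integers(0, span + 1))))
    return pd.Series(out)


def simulate_sightings(
    scenario: SyntheticScenario,
    n: int | None = None,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Draw opportunistic sighting records; returns ``(records, truth)``.

    Records carry the raw-CSV fields (id, lat, lon, date, country,
    classification, group_size) plus convenience columns (x, y, year,
    window, side) for in-memory use.  ``truth`` holds the scenario
    parameters and the closed-form per-window slopes.
    """
    scenario.validate()
    n = scenario.n_sightings if n is None else int(n)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    y = rng.uniform(scenario.y_south_m, scenario.y_north_m, n)
    year = rng.integers(scenario.years_opp[0], scenario.years_opp[1] + 1, n)
    window = scenario.window_of_y(y)
    side = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    offset = _lateral_offset(scenario, window, year, side, rng)
    x = scenario.centerline_x(y, year) + offset
    proj = EquidistantConic()
    lon, lat = proj.inverse(x, y)
    country = np.where(lat > scenario.canada_lat, "CA", "US")
    season = rng.random(n) < 0.43  # spring fraction of records
    mdmd = [(_SPRING if s else _AUTUMN) for s in season]
    if scenario.summer_contamination > 0:
        contaminate = (country == "CA") & (rng.random(n) < scenario.summer_contamination)
        for i in np.where(contaminate)[0]:
            mdmd[i] = _SUMMER
    dates = _random_dates(year, mdmd, rng)
    classification = np.where(rng.random(n) < scenario.nonconfirmed_rate, "probable", "confirmed")
    records = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "date": dates.dt.strftime("%Y-%m-%d"),
            "country": country,
            "classification": classification,
            "group_size": rng.integers(1, 9, n),
            "x": x,
            "y": y,
            "year": year,
            "true_window": window,
            "true_side": np.where(side < 0, "west", "east"),
            "source": "opportunistic",
        }
    )
    truth = {
        "kind": "sightings",
        "n": n,
        "true_slopes_km_per_year": scenario.true_slopes().to_dict(orient="index"),
        "drift_km_per_year": scenario.drift_km_per_year,
        "contraction_west_km_per_year": scenario.contraction_west_km_per_year,
        "contraction_east_km_per_year": scenario.contraction_east_km_per_year,
    }
    return records, truth


def simulate_telemetry(
    scenario: SyntheticScenario,
    n_birds: int | None = None,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Generate per-bird GPS tracks; returns ``(fixes, truth)``.

    Each bird performs one northward migration in a random telemetry year:
    stopover centers placed every 100-400 km along the flyway with lateral
    offsets from the scenario's current-era distribution, 1-4 days of
    jittered ground fixes (<= 5 km) per stopover, and in-flight fixes
    interpolated between consecutive stopovers.  Timestamps advance at
    equal intervals of ``24 / fixes_per_day`` hours.  ``truth`` records the
    planted stopovers per bird.
    """
    scenario.validate()
    n_birds = scenario.n_birds if n_birds is None else int(n_birds)
    if n_birds < 1:
        raise ValueError("n_birds >= 1 required")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    proj = EquidistantConic()
    rows = []
    planted = []
    for b in range(n_birds):
        bird = f"B{b:03d}"
        year = int(rng.integers(scenario.years_tel[0], scenario.years_tel[1] + 1))
        fpd = int(rng.integers(scenario.fixes_per_day[0], scenario.fixes_per_day[1] + 1))
        step_h = 24.0 / fpd
        t = pd.Timestamp(year, 4, int(rng.integers(1, 15)))
        # stopover centers along the flyway
        ys = []
        ycur = scenario.y_south_m + float(rng.uniform(5e3, 50e3))
        while ycur < scenario.y_north_m - 5e3:  # jitter (<= 3.5 km) stays inside the flyway
            ys.append(ycur)
            ycur += float(rng.uniform(100e3, 400e3))
        side = np.where(rng.random(len(ys)) < 0.5, -1.0, 1.0)
        win = scenario.window_of_y(np.asarray(ys))
        off = _lateral_offset(scenario, win, np.full(len(ys), year), side, rng)
        xs = scenario.centerline_x(np.asarray(ys), year) + off
        prev = None
        for s_i, (sx, sy) in enumerate(zip(xs, ys)):
            if prev is not None:
                # flight fixes interpolated between consecutive stopovers
                px, py = prev
                dist = float(np.hypot(sx - px, sy - py))
                nf = int(np.ceil(dist / 250e3))
                for k in range(1, nf + 1):
                    frac = k / (nf + 1)
                    t += pd.Timedelta(hours=step_h)
                    rows.append(
                        {
                            "bird_id": bird,
                            "timestamp": t,
                            "x": px + frac * (sx - px),
                            "y": py + frac * (sy - py),
                            "velocity_ms": float(rng.uniform(*scenario.flight_speed_ms)),
                            "truth_kind": "flight",
                            "truth_site": -1,
                        }
                    )
            n_days = int(rng.integers(1, 5))
            n_fix = max(1, n_days * fpd)
            planted.append(
                {"bird_id": bird, "site": s_i, "x": float(sx), "y": float(sy), "n_fixes": n_fix, "year": year}
            )
            for _ in range(n_fix):
                t += pd.Timedelta(hours=step_h)
                r = float(rng.uniform(0, 3.5e3))
                ang = float(rng.uniform(0, 2 * np.pi))
                rows.append(
                    {
                        "bird_id": bird,
                        "timestamp": t,
                        "x": sx + r * np.cos(ang),
                        "y": sy + r * np.sin(ang),
                        "velocity_ms": float(rng.uniform(*scenario.ground_speed_ms)),
                        "truth_kind": "ground",
                        "truth_site": s_i,
                    }
                )
            prev = (sx, sy)
    fixes = pd.DataFrame(rows)
    lon, lat = proj.inverse(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    fixes["lat"] = lat
    fixes["lon"] = lon
    fixes["year"] = fixes["timestamp"].dt.year
    fixes["source"] = "telemetry"
    truth = {
        "kind": "telemetry",
        "n_birds": n_birds,
        "n_fixes": len(fixes),
        "planted_stopovers": planted,
    }
    if scenario.artifact_rate > 0:
        fixes, labels = inject_artifacts(fixes, scenario.artifact_rate, rng)
        truth["artifacts"] = labels.to_dict(orient="records")
    return fixes, truth


def inject_artifacts(fixes: pd.DataFrame, rate: float, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrupt a fraction of fixes, each violating exactly one QC rule.

    Rules cycle through displacement-rate (> 100 km/h), angular spike
    (< 5 degrees with legs > 50 km) and timestamp swap.  Returns
    ``(corrupted, labels)`` where labels map fix row positions to the
    planted rule.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = fixes.reset_index(drop=True).copy()
    labels = []
    if rate == 0 or out.empty:
        return out, pd.DataFrame(columns=["row", "bird_id", "rule"])
    rng = np.random.default_rng(seed)
    k = int(round(rate * len(out)))
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    ts = out["timestamp"].to_numpy()
    bird = out["bird_id"].to_numpy()
    used = np.zeros(len(out), dtype=bool)
    candidates = rng.permutation(len(out))
    rules = ["speed", "angle", "time"]
    r_i = 0
    for i in candidates:
        if len(labels) >= k:
            break
        if i < 2 or i > len(out) - 3:
            continue
        if bird[i] != bird[i - 2] or bird[i] != bird[i + 2]:
            continue
        if used[max(0, i - 3) : i + 4].any():
            continue
        rule = rules[r_i % 3]
        if rule == "angle":
            gap = float(np.hypot(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1]))
            dt_h = min(
                (ts[i] - ts[i - 1]) / np.timedelta64(1, "h"),
                (ts[i + 1] - ts[i]) / np.timedelta64(1, "h"),
            )
            dperp = 200e3
            if gap > 10e3 or dperp / 1e3 / max(dt_h, 1e-9) > 95:
                rule = "speed"  # neighbors unsuitable for a clean spike
        if rule == "speed":
            dt_h = (ts[i] - ts[i - 1]) / np.timedelta64(1, "h")
            if dt_h <= 0:
                continue
            x[i] = x[i - 1] + 1.3 * 100e3 * dt_h
            y[i] = y[i - 1]
        elif rule == "angle":
            mx, my = (x[i - 1] + x[i + 1]) / 2, (y[i - 1] + y[i + 1]) / 2
            x[i], y[i] = mx + 200e3, my  # perpendicular-ish spike east
        else:  # time: swap with the next fix
            ts[i], ts[i + 1] = ts[i + 1], ts[i]
        used[i - 3 if i >= 3 else 0 : i + 4] = True
        labels.append({"row": int(i if rule != "time" else i + 1), "bird_id": str(bird[i]), "rule": rule})
        r_i += 1
    out["x"], out["y"] = x, y
    out["timestamp"] = ts
    proj = EquidistantConic()
    lon, lat = proj.inverse(x, y)
    out["lat"], out["lon"] = lat, lon
    return out, pd.DataFrame(labels)


def write_fixtures(
    outdir: str | Path,
    sightings: pd.DataFrame,
    telemetry: pd.DataFrame,
    truth: dict,
) -> dict[str, Path]:
    """Write fixture CSVs in the raw-input dialects plus a truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_path = outdir / "sightings.csv"
    t_path = outdir / "telemetry.csv"
    j_path = outdir / "truth.json"
    sightings[["id", "lat", "lon", "date", "country", "classification", "group_size"]].to_csv(
        s_path, index=False, float_format="%.9f"
    )
    tel = telemetry.copy()
    tel["timestamp"] = pd.to_datetime(tel["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    tel[["bird_id", "timestamp", "lat", "lon", "velocity_ms"]].to_csv(t_path, index=False, float_format="%.9f")
    j_path.write_text(json.dumps(truth, indent=2, default=float))
    return {"sightings": s_path, "telemetry": t_path, "truth": j_path}
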