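"""Windowed-quantile delineation of migration corridors.

A corridor at core level L (50, 75 or 95 percent) is the band between the
symmetric easting percentiles (100-L)/2 and 100-(100-L)/2, computed within
equal-height latitudinal analysis windows.  Percentiles from the
opportunistic-sighting and telemetry datasets are combined as averages
weighted by the per-window sample sizes, the per-window edge estimates are
connected into west and east boundary lines, and the two lines are closed
into a simple polygon.  Uncertainty comes from a nonparametric bootstrap of
both datasets; the analysis-window height is chosen by minimising the
corridor's fractal dimension among heights whose 95% corridor still
contains 95% of the data.

The public surface follows the model/results convention:
``CorridorModel(opportunistic, telemetry, ...).fit()`` returns a
:class:`CorridorResults` carrying per-window edge tables, polygons,
confidence bands and width/area summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import fractal_dimension, polygon_metrics, ring_polygon
from .windows import WindowGrid, assign_windows

__all__ = [
    "CoreLevel",
    "CorridorModel",
    "CorridorResults",
    "CorridorEstimate",
    "window_percentiles",
    "combine_weighted",
    "build_corridor_polygon",
    "select_window_height",
    "width_profile",
]

DEFAULT_LEVELS = (50, 75, 95)


@dataclass(frozen=True)
class CoreLevel:
    """A core corridor level and its symmetric percentile pair."""

    level: int

    def __post_init__(self) -> None:
        if not 0 < self.level < 100:
            raise ValueError("core level must be in (0, 100)")

    @property
    def lower_pct(self) -> float:
        return (100.0 - self.level) / 2.0

    @property
    def upper_pct(self) -> float:
        return 100.0 - self.lower_pct


def window_percentiles(xs, level: int | CoreLevel, method: str = "linear") -> tuple[float, float]:
    """West/east edge of one window: symmetric percentiles of the eastings.

    Empty input returns ``(nan, nan)`` (flagged missing, never zero).
    """
    lv = level if isinstance(level, CoreLevel) else CoreLevel(level)
    xs = np.asarray(xs, dtype=float)
    xs = xs[np.isfinite(xs)]
    if xs.size == 0:
        return (float("nan"), float("nan"))
    west, east = np.quantile(xs, [lv.lower_pct / 100.0, lv.upper_pct / 100.0], method=method)
    return float(west), float(east)


def combine_weighted(a_value: float, n_a: int, b_value: float, n_b: int) -> float:
    """Sample-size-weighted average of two dataset-specific estimates.

    A missing estimate (NaN) with zero weight defers to the other dataset;
    both missing yields NaN.
    """
    a_ok = np.isfinite(a_value) and n_a > 0
    b_ok = np.isfinite(b_value) and n_b > 0
    if a_ok and b_ok:
        return float((n_a * a_value + n_b * b_value) / (n_a + n_b))
    if a_ok:
        return float(a_value)
    if b_ok:
        return float(b_value)
    return float("nan")


def _group_quantiles(
    x: np.ndarray, win: np.ndarray, count: int, qs: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window quantiles (count, len(qs)) and counts; NaN where empty.

    ``win`` holds 1-based window indices; entries outside [1, count] are
    ignored.
    """
    out = np.full((count, len(qs)), np.nan)
    n = np.zeros(count, dtype=np.int64)
    ok = (win >= 1) & (win <= count)
    x, win = x[ok], win[ok]
    order = np.argsort(win, kind="stable")
    x, win = x[order], win[order]
    bounds = np.searchsorted(win, np.arange(1, count + 2))
    for w in range(count):
        lo, hi = bounds[w], bounds[w + 1]
        if hi > lo:
            out[w] = np.quantile(x[lo:hi], qs, method=method)
            n[w] = hi - lo
    return out, n


def _prep(dataset: pd.DataFrame | None, grid: WindowGrid) -> tuple[np.ndarray, np.ndarray]:
    if dataset is None or len(dataset) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    # always recompute against this grid; an inherited window column may
    # belong to a different window height
    win = assign_windows(dataset, grid)["window"].to_numpy(dtype=float)
    win = np.where(np.isfinite(win), win, 0).astype(np.int64)
    return dataset["x"].to_numpy(dtype=float), win


def _interpolate_missing(west: np.ndarray, east: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill interior missing windows linearly; terminal gaps stay missing.

    Returns (west, east, valid_mask); valid marks the contiguous run kept.
    """
    W = len(west)
    have = np.isfinite(west) & np.isfinite(east)
    if not have.any():
        raise ValueError("no window has an edge estimate")
    first, last = np.argmax(have), W - 1 - np.argmax(have[::-1])
    idx = np.arange(W, dtype=float)
    known = np.where(have)[0]
    west = west.copy()
    east = east.copy()
    interior = np.arange(first, last + 1)
    west[interior] = np.interp(idx[interior], known.astype(float), west[known])
    east[interior] = np.interp(idx[interior], known.astype(float), east[known])
    valid = np.zeros(W, dtype=bool)
    valid[first : last + 1] = True
    return west, east, valid


def _edge_vertices(
    west: np.ndarray, east: np.ndarray, valid: np.ndarray, grid: WindowGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertex ordinates/abscissae of the west and east boundary lines.

    Vertices sit at window vertical midpoints; the terminal windows of the
    valid run are squared off to their outer window boundaries.
    """
    wins = np.where(valid)[0]
    first, last = wins[0], wins[-1]
    y_mid = grid.y_mid(np.arange(first + 1, last + 2))
    ys = np.concatenate([[grid.y0 + first * grid.height], y_mid, [grid.y0 + (last + 1) * grid.height]])
    wx = np.concatenate([[west[first]], west[first : last + 1], [west[last]]])
    ex = np.concatenate([[east[first]], east[first : last + 1], [east[last]]])
    return ys, wx, ex


def build_corridor_polygon(edges: pd.DataFrame, grid: WindowGrid) -> Polygon:
    """Close the west and east boundary lines into a corridor polygon.

    ``edges`` needs columns window (1-based), west_x, east_x; interior
    missing windows are interpolated, terminal missing windows truncate the
    corridor.  The ring runs up the west line south to north and back down
    the east line.
    """
    full_w = np.full(grid.count, np.nan)
    full_e = np.full(grid.count, np.nan)
    wi = edges["window"].to_numpy(dtype=np.int64) - 1
    full_w[wi] = edges["west_x"].to_numpy(dtype=float)
    full_e[wi] = edges["east_x"].to_numpy(dtype=float)
    west, east, valid = _interpolate_missing(full_w, full_e)
    if np.any(west[valid] > east[valid]):
        bad = np.where(valid & (west > east))[0] + 1
        raise ValueError(f"west edge east of east edge in windows {bad.tolist()}")
    # a zero-width window (single-point or single-x data) would make the ring
    # self-touch; open it by a millimetre, far below any data precision
    east = np.where(valid & (east - west < 1e-3), west + 1e-3, east)
    ys, wx, ex = _edge_vertices(west, east, valid, grid)
    ring = np.concatenate(
        [np.column_stack([wx, ys]), np.column_stack([ex, ys])[::-1]]
    )
    return ring_polygon(ring)


def _fast_containment(
    west: np.ndarray, east: np.ndarray, valid: np.ndarray, grid: WindowGrid, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Boundary-inclusive point-in-corridor test via edge interpolation.

    Equivalent to polygon containment for these monotone-in-y polygons, but
    vectorised; used in bootstrap containment scoring.
    """
    ys, wx, ex = _edge_vertices(west, east, valid, grid)
    inside_y = (y >= ys[0]) & (y <= ys[-1])
    wq = np.interp(y, ys, wx)
    eq = np.interp(y, ys, ex)
    return inside_y & (x >= wq) & (x <= eq)


@dataclass
class CorridorEstimate:
    """Point estimate and uncertainty of one core-level corridor."""

    level: CoreLevel
    edges: pd.DataFrame
    polygon: Polygon
    band_outer: Polygon | None = None
    band_inner: Polygon | None = None

    @property
    def widths_km(self) -> pd.Series:
        e = self.edges
        return pd.Series(
            (e["east_x"].to_numpy() - e["west_x"].to_numpy()) / 1e3,
            index=e["window"],
            name=f"width_km_{self.level.level}",
        )

    @property
    def area_ha(self) -> float:
        return polygon_metrics(self.polygon)["area_ha"]

    @property
    def frac_index(self) -> float:
        return fractal_dimension(self.polygon)


def width_profile(estimate: CorridorEstimate | pd.Series) -> dict[str, float]:
    """Per-window width summary: mean, sample SD, min/max and their windows."""
    widths = estimate.widths_km if isinstance(estimate, CorridorEstimate) else estimate
    widths = widths.dropna()
    if widths.empty:
        raise ValueError("no window widths available")
    return {
        "mean_km": float(widths.mean()),
        "sd_km": float(widths.std(ddof=1)) if len(widths) > 1 else 0.0,
        "min_km": float(widths.min()),
        "min_window": int(widths.idxmin()),
        "max_km": float(widths.max()),
        "max_window": int(widths.idxmax()),
    }


class CorridorModel:
    """Windowed-quantile corridor model for two weighted location datasets.

    Parameters
    ----------
    opportunistic, telemetry
        Location frames with ``x``/``y`` columns in projected meters (either
        may be None or empty; at least one point overall is required).
    window_height
        Analysis-window height in meters (ignored when ``grid`` is given).
    grid
        Explicit :class:`WindowGrid`; default is a grid flush with the
        combined data span.
    levels
        Core levels to estimate.
    quantile_method
        Percentile definition passed to :func:`numpy.quantile`; linear
        interpolation between closest order statistics by default.
    """

    def __init__(
        self,
        opportunistic: pd.DataFrame | None,
        telemetry: pd.DataFrame | None = None,
        window_height: float = 300e3,
        grid: WindowGrid | None = None,
        levels: tuple[int, ...] = DEFAULT_LEVELS,
        quantile_method: str = "linear",
    ) -> None:
        n_opp = 0 if opportunistic is None else len(opportunistic)
        n_tel = 0 if telemetry is None else len(telemetry)
        if n_opp + n_tel == 0:
            raise ValueError("no locations supplied")
        ys = np.concatenate(
            [d["y"].to_numpy(dtype=float) for d in (opportunistic, telemetry) if d is not None and len(d)]
        )
        self.grid = grid if grid is not None else WindowGrid.from_span(ys.min(), ys.max(), window_height)
        self.levels = tuple(CoreLevel(lv) for lv in levels)
        self.quantile_method = quantile_method
        self._opp_x, self._opp_w = _prep(opportunistic, self.grid)
        self._tel_x, self._tel_w = _prep(telemetry, self.grid)
        xs = np.concatenate([self._opp_x, self._tel_x])
        yall = ys
        self._all_xy = (xs, yall)

    @classmethod
    def from_dataframe(cls, locations: pd.DataFrame, **kwargs) -> "CorridorModel":
        """Build from a single frame with a ``source`` column."""
        opp = locations[locations["source"] == "opportunistic"]
        tel = locations[locations["source"] == "telemetry"]
        return cls(opp, tel, **kwargs)

    # -- internals --------------------------------------------------------

    def _qs(self) -> np.ndarray:
        qs = []
        for lv in self.levels:
            qs += [lv.lower_pct / 100.0, lv.upper_pct / 100.0]
        return np.asarray(qs)

    def _combined_edges(
        self, opp_x: np.ndarray, opp_w: np.ndarray, tel_x: np.ndarray, tel_w: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(W, nq) per-dataset and combined quantiles, plus per-window counts."""
        qs = self._qs()
        oq, no = _group_quantiles(opp_x, opp_w, self.grid.count, qs, self.quantile_method)
        tq, nt = _group_quantiles(tel_x, tel_w, self.grid.count, qs, self.quantile_method)
        wsum = (no + nt)[:, None].astype(float)
        with np.errstate(invalid="ignore"):
            comb = (np.nan_to_num(oq) * no[:, None] + np.nan_to_num(tq) * nt[:, None]) / np.where(wsum > 0, wsum, np.nan)
        only_o = (no > 0) & (nt == 0)
        only_t = (nt > 0) & (no == 0)
        comb[only_o] = oq[only_o]
        comb[only_t] = tq[only_t]
        comb[(no == 0) & (nt == 0)] = np.nan
        return comb, oq, tq, np.column_stack([no, nt])

    def _bootstrap(self, B: int, seed) -> np.ndarray:
        """(B, W, nq) combined replicate edges; NaN where a window is empty."""
        rng = np.random.default_rng(seed)
        W, nq = self.grid.count, len(self._qs())
        out = np.empty((B, W, nq))
        for b in range(B):
            if self._opp_x.size:
                io = rng.integers(0, self._opp_x.size, self._opp_x.size)
                ox, ow = self._opp_x[io], self._opp_w[io]
            else:
                ox, ow = self._opp_x, self._opp_w
            if self._tel_x.size:
                it = rng.integers(0, self._tel_x.size, self._tel_x.size)
                tx, tw = self._tel_x[it], self._tel_w[it]
            else:
                tx, tw = self._tel_x, self._tel_w
            out[b] = self._combined_edges(ox, ow, tx, tw)[0]
        return out

    # -- fitting ----------------------------------------------------------

    def fit(self, bootstrap: int = 1000, seed=None, bands: bool = True) -> "CorridorResults":
        """Estimate corridors at every level, with bootstrap confidence bands.

        ``bootstrap`` is the number of resamples B (>= 2 when bands are
        requested); each replicate resamples each dataset with replacement
        at its original size and recomputes the combined per-window edges.
        Confidence limits are the 2.5th/97.5th percentiles of the replicate
        edges.
        """
        comb, oq, tq, counts = self._combined_edges(self._opp_x, self._opp_w, self._tel_x, self._tel_w)
        reps = None
        if bands:
            if bootstrap < 2:
                raise ValueError("bootstrap must be >= 2")
            reps = self._bootstrap(bootstrap, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
                cl = np.nanpercentile(reps, [2.5, 97.5], axis=0)
        estimates: dict[int, CorridorEstimate] = {}
        windows = np.arange(1, self.grid.count + 1)
        for k, lv in enumerate(self.levels):
            cols = {
                "window": windows,
                "y_mid_m": self.grid.y_mid(windows),
                "west_x": comb[:, 2 * k],
                "east_x": comb[:, 2 * k + 1],
                "opp_west": oq[:, 2 * k],
                "opp_east": oq[:, 2 * k + 1],
                "tel_west": tq[:, 2 * k],
                "tel_east": tq[:, 2 * k + 1],
                "n_opp": counts[:, 0],
                "n_tel": counts[:, 1],
            }
            if bands:
                cols.update(
                    cl_west_lo=cl[0, :, 2 * k],
                    cl_west_hi=cl[1, :, 2 * k],
                    cl_east_lo=cl[0, :, 2 * k + 1],
                    cl_east_hi=cl[1, :, 2 * k + 1],
                )
            edges = pd.DataFrame(cols)
            present = edges[np.isfinite(edges["west_x"])]
            polygon = build_corridor_polygon(present, self.grid)
            est = CorridorEstimate(level=lv, edges=edges, polygon=polygon)
            if bands:
                est.band_outer = self._band_polygon(edges, "cl_west_lo", "cl_east_hi")
                est.band_inner = self._band_polygon(edges, "cl_west_hi", "cl_east_lo")
            estimates[lv.level] = est
        return CorridorResults(self, estimates, n_bootstrap=bootstrap if bands else 0)

    def _band_polygon(self, edges: pd.DataFrame, wcol: str, ecol: str) -> Polygon | None:
        df = edges[["window"]].copy()
        w = edges[wcol].to_numpy(dtype=float)
        e = edges[ecol].to_numpy(dtype=float)
        crossed = np.isfinite(w) & np.isfinite(e) & (w > e)
        mid = (w + e) / 2.0
        w = np.where(crossed, mid, w)  # inner band collapses where CLs cross
        e = np.where(crossed, mid, e)
        df["west_x"], df["east_x"] = w, e
        df = df[np.isfinite(df["west_x"]) & np.isfinite(df["east_x"])]
        if df.empty:
            return None
        try:
            return build_corridor_polygon(df, self.grid)
        except ValueError:
            return None

class CorridorResults:
    """Fitted corridors: per-window edges, polygons, bands and summaries."""

    def __init__(self, model: CorridorModel, estimates: dict[int, CorridorEstimate], n_bootstrap: int) -> None:
        self.model = model
        self.grid = model.grid
        self.estimates = estimates
        self.n_bootstrap = n_bootstrap

    def edge_table(self, level: int) -> pd.DataFrame:
        return self.estimates[level].edges.copy()

    def width_profile(self, level: int) -> dict[str, float]:
        return width_profile(self.estimates[level])

    def containment(self, level: int = 95) -> float:
        est = self.estimates[level]
        e = est.edges
        full_w = np.full(self.grid.count, np.nan)
        full_e = np.full(self.grid.count, np.nan)
        wi = e["window"].to_numpy(dtype=np.int64) - 1
        full_w[wi] = e["west_x"].to_numpy(dtype=float)
        full_e[wi] = e["east_x"].to_numpy(dtype=float)
        west, east, valid = _interpolate_missing(full_w, full_e)
        x, y = self.model._all_xy
        return float(np.mean(_fast_containment(west, east, valid, self.grid, x, y)))

    def summary(self) -> pd.DataFrame:
        """One row per core level: area, widths, shape complexity."""
        rows = []
        for lv, est in sorted(self.estimates.items()):
            prof = width_profile(est)
            rows.append(
                {
                    "level": lv,
                    "area_ha": est.area_ha,
                    "mean_width_km": prof["mean_km"],
                    "sd_width_km": prof["sd_km"],
                    "min_width_km": prof["min_km"],
                    "max_width_km": prof["max_km"],
                    "frac_index": est.frac_index,
                    "containment": self.containment(lv),
                }
            )
        return pd.DataFrame(rows).set_index("level")

    def plot(self, ax=None):
        """Corridor outlines (west/east boundary lines) per level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 8))
        for lv, est in sorted(self.estimates.items()):
            xs, ys = est.polygon.exterior.xy
            ax.plot(np.asarray(xs) / 1e3, np.asarray(ys) / 1e3, label=f"{lv}% core")
        ax.set_xlabel("easting (km)")
        ax.set_ylabel("northing (km)")
        ax.legend()
        return ax


@dataclass
class WindowSelectionDiagnostics:
    height: float
    containment: float
    frac_index: float

    @property
    def passes(self) -> bool:
        return self.containment >= 0.95


def select_window_height(
    opportunistic: pd.DataFrame | None,
    telemetry: pd.DataFrame | None,
    heights=tuple(h * 1e3 for h in range(50, 701, 50)),
    bootstrap: int = 1000,
    seed=None,
    containment_target: float = 0.95,
    quantile_method: str = "linear",
) -> tuple[float, pd.DataFrame]:
    """Pick the analysis-window height for the 95% corridor.

    For each candidate height the 95% corridor is built; its data fit is the
    mean, over ``bootstrap`` resampled corridors, of the fraction of all
    original locations contained, and its shape complexity is the fractal
    dimension of the point-estimate polygon.  Among candidates whose fit
    reaches ``containment_target`` the one with the smallest fractal index
    wins; ties go to the smaller height.

    Returns ``(height_m, diagnostics)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for h in heights:
        model = CorridorModel(opportunistic, telemetry, window_height=h, levels=(95,), quantile_method=quantile_method)
        x, y = model._all_xy
        reps = model._bootstrap(bootstrap, rng)
        contain = np.empty(bootstrap)
        for b in range(bootstrap):
            wb, eb = reps[b, :, 0].copy(), reps[b, :, 1].copy()
            try:
                west, east, valid = _interpolate_missing(wb, eb)
            except ValueError:
                contain[b] = np.nan
                continue
            contain[b] = np.mean(_fast_containment(west, east, valid, model.grid, x, y))
        res = model.fit(bands=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frac = res.estimates[95].frac_index
        rows.append(
            {
                "height_km": h / 1e3,
                "containment": float(np.nanmean(contain)),
                "frac_index": frac,
                "passes": bool(np.nanmean(contain) >= containment_target),
            }
        )
    diag = pd.DataFrame(rows)
    return choose_height(diag), diag


def choose_height(diagnostics: pd.DataFrame) -> float:
    """Selection rule: among passing candidates, minimum fractal index;
    ties go to the smaller height.  Returns the height in meters."""
    passing = diagnostics[diagnostics["passes"]]
    if passing.empty:
        raise ValueError(f"no candidate height meets the containment criterion:\n{diagnostics}")
    best = passing.sort_values(["frac_index", "height_km"], kind="stable").iloc[0]
    return float(best["height_km"] * 1e3)
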