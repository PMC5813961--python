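"""Long-term corridor shift and narrowing: Bayesian prior-updating trends.

The positional model regresses the easting of each location on year
(year 0 = 1942) with the analysis window as a categorical factor, in a
cell-means parameterization: one intercept and one year-slope per window,
sharing a single error variance.  Inference is a two-stage Bayesian update:

1. the decades-long opportunistic-sighting record is fitted with flat
   coefficient priors (Gibbs sampling with conjugate normal / inverse-gamma
   full conditionals);
2. each stage-1 posterior coefficient mean and variance defines a normal
   prior for the same coefficient in a second fit to the telemetry data,
   whose posterior is the inferential output.

Corridor-width change is assessed on distances from the per-window median
centerline: absolute distance overall (a negative year-slope means
narrowing) and signed distance separately for locations west and east of
the centerline.  Slopes are summarised in km/year with 95% credible
intervals from the posterior draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .windows import WindowGrid, assign_windows

log = logging.getLogger(__name__)

__all__ = [
    "YEAR_ZERO",
    "build_design",
    "Design",
    "GibbsLinearModel",
    "GibbsResults",
    "TwoStageTrendModel",
    "TwoStageResults",
    "median_by_window",
    "median_difference_bootstrap",
    "centerline_offsets",
    "width_trend",
    "predict_year_positions",
]

YEAR_ZERO = 1942


@dataclass
class Design:
    """A cell-means design: per-window intercept and per-window year slope.

    ``year_center`` is subtracted from the year offset before building the
    slope columns, so the intercept is the expected response at that
    reference time.  Centering near the mean observation year makes the
    intercept and slope posteriors nearly uncorrelated, which is what makes
    transferring *marginal* normal priors between stages faithful.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[tuple[str, int]]  # ("intercept"|"year", window)
    windows: list[int]
    year_center: float = 0.0
    n_dropped: int = 0

    @property
    def slope_cols(self) -> dict[int, int]:
        return {w: j for j, (kind, w) in enumerate(self.columns) if kind == "year"}

    @property
    def intercept_cols(self) -> dict[int, int]:
        return {w: j for j, (kind, w) in enumerate(self.columns) if kind == "intercept"}


def build_design(
    locations: pd.DataFrame,
    grid: WindowGrid,
    response: str = "x",
    year_zero: int = YEAR_ZERO,
    min_distinct_years: int = 2,
    year_center: float = 0.0,
) -> Design:
    """Design matrix for the per-window linear trend model.

    Windows with fewer than ``min_distinct_years`` distinct observation
    years cannot identify a slope and are dropped (their observations are
    excluded, counted in ``n_dropped``).
    """
    df = locations
    if "window" not in df.columns or df["window"].isna().any():
        df = assign_windows(df, grid)
    df = df[df["window"].notna()]
    keep_windows = []
    for w, grp in df.groupby("window"):
        if grp["year"].nunique() >= min_distinct_years:
            keep_windows.append(int(w))
    keep_windows.sort()
    sel = df[df["window"].isin(keep_windows)]
    n_dropped = len(df) - len(sel)
    if not keep_windows:
        raise ValueError("no window has enough distinct years to fit a trend")
    w = sel["window"].to_numpy(dtype=np.int64)
    t = sel["year"].to_numpy(dtype=float) - year_zero - year_center
    n = len(sel)
    p = 2 * len(keep_windows)
    X = np.zeros((n, p))
    columns: list[tuple[str, int]] = []
    for j, win in enumerate(keep_windows):
        mask = w == win
        X[mask, 2 * j] = 1.0
        X[mask, 2 * j + 1] = t[mask]
        columns += [("intercept", win), ("year", win)]
    y = sel[response].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via QR column norms
        _, R = np.linalg.qr(X)
        bad = [columns[j] for j in range(p) if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return Design(X=X, y=y, columns=columns, windows=keep_windows, year_center=year_center, n_dropped=n_dropped)


class GibbsLinearModel:
    """Bayesian linear regression sampled by Gibbs alternation.

    Coefficients get independent normal priors (variance ``inf`` = flat);
    the shared error variance gets a vague inverse-gamma(0.001, 0.001)
    prior, or can be fixed for known-variance analyses.  Full conditionals
    are conjugate: coefficients given the variance are multivariate normal
    (flat priors make the conditional mean the least-squares estimate), the
    variance given coefficients is inverse-gamma.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        columns=None,
        prior_mean: np.ndarray | None = None,
        prior_var: np.ndarray | None = None,
        var_prior: tuple[float, float] = (0.001, 0.001),
        sigma2: float | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.columns = list(columns) if columns is not None else list(range(self.p))
        self.prior_mean = np.zeros(self.p) if prior_mean is None else np.asarray(prior_mean, dtype=float)
        self.prior_var = np.full(self.p, np.inf) if prior_var is None else np.asarray(prior_var, dtype=float)
        if np.any(self.prior_var <= 0):
            raise ValueError("prior variances must be positive")
        self.var_prior = var_prior
        self.fixed_sigma2 = sigma2
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        if np.linalg.matrix_rank(self.XtX) < self.p and not np.any(np.isfinite(self.prior_var)):
            raise ValueError("rank-deficient design with flat priors")

    def fit(self, burn: int = 2000, keep: int = 10000, seed=None, thin: int = 1) -> "GibbsResults":
        if keep < 100:
            raise ValueError("keep >= 100 draws required")
        rng = np.random.default_rng(seed)
        flat = ~np.isfinite(self.prior_var)
        P0 = np.where(flat, 0.0, 1.0 / self.prior_var)
        P0m0 = P0 * self.prior_mean
        all_flat = bool(flat.all())
        if all_flat:
            cf = cho_factor(self.XtX, lower=True)
            beta_hat = cho_solve(cf, self.Xty)
            Lt = np.linalg.cholesky(self.XtX).T  # upper
        beta = np.linalg.lstsq(self.X, self.y, rcond=None)[0] if all_flat else self.prior_mean.copy()
        resid = self.y - self.X @ beta
        sigma2 = self.fixed_sigma2 if self.fixed_sigma2 is not None else max(float(resid @ resid) / max(self.n - self.p, 1), 1e-12)
        a0, b0 = self.var_prior
        total = burn + keep * thin
        draws = np.empty((keep, self.p))
        sig_draws = np.empty(keep)
        kept = 0
        for it in range(total):
            if all_flat:
                z = rng.standard_normal(self.p)
                beta = beta_hat + np.sqrt(sigma2) * solve_triangular(Lt, z, lower=False)
            else:
                A = self.XtX / sigma2 + np.diag(P0)
                rhs = self.Xty / sigma2 + P0m0
                L = np.linalg.cholesky(A)
                mean = cho_solve((L, True), rhs)
                z = rng.standard_normal(self.p)
                beta = mean + solve_triangular(L.T, z, lower=False)
            if self.fixed_sigma2 is None:
                r = self.y - self.X @ beta
                a_post = a0 + 0.5 * self.n
                b_post = b0 + 0.5 * float(r @ r)
                # tiny shapes (no-likelihood limit) can draw an exact fp zero
                sigma2 = b_post / max(rng.gamma(a_post, 1.0), 1e-300)
            if it >= burn and (it - burn) % thin == 0:
                draws[kept] = beta
                sig_draws[kept] = sigma2
                kept += 1
        return GibbsResults(self, draws[:kept], sig_draws[:kept])


class GibbsResults:
    """Posterior draws and summaries for :class:`GibbsLinearModel`."""

    def __init__(self, model: GibbsLinearModel, draws: np.ndarray, sigma2_draws: np.ndarray) -> None:
        self.model = model
        self.draws = draws
        self.sigma2_draws = sigma2_draws
        self.columns = model.columns
        self.year_center = 0.0  # reference time of the intercept columns

    @property
    def params(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def params_var(self) -> np.ndarray:
        return self.draws.var(axis=0, ddof=1)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        return np.quantile(self.draws, [alpha / 2, 1 - alpha / 2], axis=0).T

    def slope_table(self, scale: float = 1e-3) -> pd.DataFrame:
        """Per-window year-slope summary in km/year (response meters).

        Columns: slope_mean_km_per_year, cl_lo, cl_hi, excludes_zero.
        """
        rows = []
        ci = self.conf_int()
        for j, col in enumerate(self.columns):
            if isinstance(col, tuple) and col[0] == "year":
                lo, hi = ci[j] * scale
                mean = self.params[j] * scale
                rows.append(
                    {
                        "window": col[1],
                        "slope_mean_km_per_year": mean,
                        "cl_lo": lo,
                        "cl_hi": hi,
                        "excludes_zero": bool(lo > 0 or hi < 0),
                    }
                )
        return pd.DataFrame(rows).set_index("window")

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": [str(c) for c in self.columns],
                "mean": self.params,
                "sd": self.draws.std(axis=0, ddof=1),
                "cl_2.5": ci[:, 0],
                "cl_97.5": ci[:, 1],
            }
        )

    def split_rhat(self) -> np.ndarray:
        """Split-chain potential scale reduction per coefficient (diagnostic)."""
        half = self.draws.shape[0] // 2
        chains = np.stack([self.draws[:half], self.draws[half : 2 * half]])
        m, n_, _ = chains.shape
        cm = chains.mean(axis=1)
        cv = chains.var(axis=1, ddof=1)
        W = cv.mean(axis=0)
        Bv = n_ * cm.var(axis=0, ddof=1)
        var_hat = (n_ - 1) / n_ * W + Bv / n_
        return np.sqrt(var_hat / np.where(W > 0, W, np.nan))


@dataclass
class TwoStageResults:
    """Stage-1 posterior, transferred priors and the inferential stage-2 fit."""

    stage1: GibbsResults
    prior_mean: np.ndarray
    prior_var: np.ndarray
    stage2: GibbsResults

    def slope_table(self) -> pd.DataFrame:
        return self.stage2.slope_table()

    def summary(self) -> pd.DataFrame:
        return self.stage2.summary()

    def predict(self, years=(1980, 2014)) -> pd.DataFrame:
        return predict_year_positions(self.stage2, years=years)


class TwoStageTrendModel:
    """Prior-updating trend model: opportunistic posterior -> telemetry prior.

    Parameters
    ----------
    opportunistic, telemetry
        Location frames with the response column, ``year`` and ``window``
        (or ``y`` for window assignment against ``grid``).
    grid
        The analysis-window grid shared by both stages.
    response
        Response column, meters (easting ``x`` or a centerline offset).
    """

    def __init__(
        self,
        opportunistic: pd.DataFrame,
        telemetry: pd.DataFrame,
        grid: WindowGrid,
        response: str = "x",
        year_zero: int = YEAR_ZERO,
    ) -> None:
        self.grid = grid
        self.response = response
        self.year_zero = year_zero
        # center the year covariate at the stage-1 mean observation year so
        # that intercept/slope posteriors decouple and marginal normal
        # priors carry the stage-1 information faithfully into stage 2
        self.year_center = float(opportunistic["year"].mean() - year_zero)
        self.design1 = build_design(opportunistic, grid, response, year_zero, year_center=self.year_center)
        self.design2 = build_design(telemetry, grid, response, year_zero, year_center=self.year_center)

    def fit(self, burn: int = 2000, keep: int = 10000, seed=None) -> TwoStageResults:
        rng = np.random.default_rng(seed)
        m1 = GibbsLinearModel(self.design1.y, self.design1.X, columns=self.design1.columns)
        r1 = m1.fit(burn=burn, keep=keep, seed=rng)
        # transfer: stage-1 posterior mean/variance -> stage-2 normal priors
        pm = np.zeros(len(self.design2.columns))
        pv = np.full(len(self.design2.columns), np.inf)
        lookup = {col: j for j, col in enumerate(self.design1.columns)}
        missing = []
        for j, col in enumerate(self.design2.columns):
            if col in lookup:
                pm[j] = r1.params[lookup[col]]
                pv[j] = r1.params_var[lookup[col]]
            else:
                missing.append(col)
        if missing:
            log.warning("no stage-1 information for %s; flat priors used", missing)
        m2 = GibbsLinearModel(
            self.design2.y, self.design2.X, columns=self.design2.columns, prior_mean=pm, prior_var=pv
        )
        r2 = m2.fit(burn=burn, keep=keep, seed=rng)
        r1.year_center = r2.year_center = self.year_center
        return TwoStageResults(stage1=r1, prior_mean=pm, prior_var=pv, stage2=r2)


# -- medians, offsets, width trends --------------------------------------


def median_by_window(locations: pd.DataFrame, grid: WindowGrid) -> pd.Series:
    """Per-window median easting (the corridor centerline), meters.

    Windows without data get NaN.
    """
    df = locations
    if "window" not in df.columns or df["window"].isna().any():
        df = assign_windows(df, grid)
    med = df[df["window"].notna()].groupby("window")["x"].median()
    out = pd.Series(np.nan, index=pd.RangeIndex(1, grid.count + 1, name="window"))
    out.loc[med.index.astype(int)] = med.to_numpy()
    return out


def median_difference_bootstrap(
    opp: pd.DataFrame,
    tel: pd.DataFrame,
    grid: WindowGrid,
    B: int = 1000,
    min_n: int = 30,
    seed=None,
) -> pd.DataFrame:
    """Per-window opportunistic-minus-telemetry median difference, km.

    Both inputs should already be restricted to the overlapping years.
    Windows with fewer than ``min_n`` opportunistic sightings are flagged
    ``evaluated = False``.  Confidence limits are percentile intervals over
    ``B`` paired resamples of both datasets.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    opp = assign_windows(opp, grid) if "window" not in opp.columns or opp["window"].isna().any() else opp
    tel = assign_windows(tel, grid) if "window" not in tel.columns or tel["window"].isna().any() else tel
    ox = opp[opp["window"].notna()]
    tx = tel[tel["window"].notna()]
    rows = []
    for w in range(1, grid.count + 1):
        a = ox.loc[ox["window"] == w, "x"].to_numpy(dtype=float)
        b = tx.loc[tx["window"] == w, "x"].to_numpy(dtype=float)
        evaluated = len(a) >= min_n and len(b) > 0
        if len(a) == 0 or len(b) == 0:
            rows.append({"window": w, "n_opp": len(a), "n_tel": len(b), "difference_km": np.nan,
                         "cl_lo_km": np.nan, "cl_hi_km": np.nan, "evaluated": False})
            continue
        diff = (np.median(a) - np.median(b)) / 1e3
        boots = np.empty(B)
        for i in range(B):
            boots[i] = (
                np.median(a[rng.integers(0, len(a), len(a))]) - np.median(b[rng.integers(0, len(b), len(b))])
            ) / 1e3
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {"window": w, "n_opp": len(a), "n_tel": len(b), "difference_km": diff,
             "cl_lo_km": lo, "cl_hi_km": hi, "evaluated": evaluated}
        )
    return pd.DataFrame(rows).set_index("window")


def centerline_offsets(locations: pd.DataFrame, centerline: pd.Series) -> pd.DataFrame:
    """Signed distance of each location from its window's centerline.

    East positive.  ``side`` is west for strictly negative offsets, east
    otherwise (an offset of exactly zero counts east).  Locations in windows
    without a centerline are skipped with a log entry.
    """
    df = locations[locations["window"].notna()].copy()
    cl = df["window"].astype(int).map(centerline)
    missing = cl.isna()
    if missing.any():
        log.info("centerline_offsets: %d locations skipped (no centerline)", int(missing.sum()))
    df = df[~missing]
    cl = cl[~missing]
    df["centerline_x"] = cl.astype(float)
    df["signed_offset"] = df["x"].astype(float) - df["centerline_x"]
    df["abs_offset"] = df["signed_offset"].abs()
    df["side"] = np.where(df["signed_offset"] < 0, "west", "east")
    return df


def width_trend(
    offsets: pd.DataFrame,
    subset: str,
    grid: WindowGrid,
    burn: int = 2000,
    keep: int = 10000,
    seed=None,
) -> TwoStageResults:
    """Two-stage trend in distance from the centerline.

    ``subset`` selects the response: ``all_abs`` models |offset| for every
    location (negative slope = narrowing); ``west``/``east`` model the
    signed offset restricted to that side (positive west-side slope =
    eastward movement toward the median).
    """
    if subset == "all_abs":
        df = offsets
        response = "abs_offset"
    elif subset in ("west", "east"):
        df = offsets[offsets["side"] == subset]
        response = "signed_offset"
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if df.empty:
        raise ValueError(f"subset {subset!r} is empty")
    opp = df[df["source"] == "opportunistic"]
    tel = df[df["source"] == "telemetry"]
    model = TwoStageTrendModel(opp, tel, grid, response=response)
    return model.fit(burn=burn, keep=keep, seed=seed)


def predict_year_positions(
    posterior: GibbsResults,
    years=(1980, 2014),
    year_zero: int = YEAR_ZERO,
) -> pd.DataFrame:
    """Posterior-mean predicted response per window at given years, km.

    Prediction = mean(alpha_w) + mean(beta_w) * (year - reference), where
    the reference time is the intercept's centering year.  Years outside
    the observation record draw an extrapolation warning.
    """
    years = tuple(years)
    for yr in years:
        if not 1942 <= yr <= 2016:
            warnings.warn(f"year {yr} outside the study period: extrapolation", stacklevel=2)
    icols = {c[1]: j for j, c in enumerate(posterior.columns) if isinstance(c, tuple) and c[0] == "intercept"}
    scols = {c[1]: j for j, c in enumerate(posterior.columns) if isinstance(c, tuple) and c[0] == "year"}
    center = getattr(posterior, "year_center", 0.0)
    rows = []
    for w in sorted(icols):
        a = posterior.params[icols[w]]
        b = posterior.params[scols[w]]
        preds = {f"pred_{yr}_km": (a + b * (yr - year_zero - center)) / 1e3 for yr in years}
        row = {"window": w, **preds}
        if len(years) == 2:
            row["difference_km"] = preds[f"pred_{years[1]}_km"] - preds[f"pred_{years[0]}_km"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")
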