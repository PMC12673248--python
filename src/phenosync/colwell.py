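"""Colwell's predictability metrics for environmental time series.

Turns raw per-site series (daily climate, 8-day NDVI composites) into
Colwell's constancy (C), contingency (M) and predictability (P = C + M).
The pipeline per variable is

    smooth (NDVI only) -> aggregate to a years x time-class matrix
    -> discretize into states -> entropy-based metrics,

where constancy measures how uniform the variable is across the year
(1 = flat seasonal profile) and contingency how repeatably the within-year
pattern recurs across years (1 = perfectly periodic; often read as the
degree of seasonality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

VARIABLES = ("temperature", "precipitation", "ndvi")

#: aggregation cadence per variable: NDVI monthly means, temperature weekly
#: means, precipitation weekly totals
_AGG = {
    "ndvi": ("month", "mean", 12),
    "temperature": ("week", "mean", 52),
    "precipitation": ("week", "sum", 52),
}


@dataclass
class SeriesMatrix:
    """One environmental variable at one site, arranged years x time classes.

    ``values[i, j]`` is the aggregated value of year ``years[i]`` in time
    class ``j`` (month 1..12 or fixed 7-day week 1..52); NaN marks a class
    with no data.
    """

    site_id: str
    variable: str
    years: np.ndarray
    n_time_classes: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.n_time_classes not in (12, 52):
            raise ValueError("n_time_classes must be 12 or 52")
        if self.values.shape != (len(self.years), self.n_time_classes):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.years)} years x {self.n_time_classes} classes"
            )


@dataclass
class FrequencyTable:
    """State x time-class count matrix underlying Colwell's entropies.

    ``counts[i, j]`` = number of years whose cell in time class j fell in
    state i.  Row totals Y_i, column totals X_j and the grand total Z are
    derived properties.
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    n_years: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D state x time-class matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def s(self) -> int:
        return self.counts.shape[0]

    @property
    def t(self) -> int:
        return self.counts.shape[1]

    @property
    def Z(self) -> float:
        return float(self.counts.sum())

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def completeness(self) -> float:
        """Fraction of the n_years x t cells that entered the table."""
        return self.Z / (self.n_years * self.t)


@dataclass
class ColwellMetrics:
    """Constancy C, contingency M, predictability P and their entropies (nats)."""

    constancy: float
    contingency: float
    predictability: float
    HX: float
    HY: float
    HXY: float
    s: int
    t: int
    n_years: int
    completeness: float = 1.0


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log(0) = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def smooth_ndvi(
    series: pd.DataFrame, window_days: int = 45, polyorder: int = 2
) -> pd.DataFrame:
    """Savitzky-Golay smooth an NDVI composite series.

    The physical window length in days is converted to the nearest odd
    number of sample points (given the series' median cadence), floored at
    ``polyorder + 2``; at the default 8-day cadence, 45 days -> 5 points.
    Returns a copy with smoothed ``value``; timestamps are unchanged.
    """
    if (series["variable"] != "ndvi").any():
        raise ValueError("smooth_ndvi expects an NDVI series")
    if window_days <= polyorder:
        raise ValueError("window_days must exceed polyorder")
    series = series.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(series["date"])
    if len(series) < 2:
        raise ValueError("series too short to smooth")
    cadence = float(np.median(np.diff(dates.values).astype("timedelta64[D]").astype(float)))
    w = window_days / cadence
    # nearest odd point count
    lo = int(np.floor(w))
    lo = lo if lo % 2 == 1 else lo - 1
    window = lo if abs(w - lo) <= abs(w - (lo + 2)) else lo + 2
    window = max(window, polyorder + 2)
    if window % 2 == 0:
        window += 1
    if len(series) < window:
        raise ValueError("series too short to smooth")
    out = series.copy()
    out["value"] = savgol_filter(series["value"].to_numpy(float), window, polyorder,
                                 mode="interp")
    return out


def _time_class(dates: pd.Series, scheme: str) -> np.ndarray:
    doy = dates.dt.dayofyear.to_numpy()
    if scheme == "month":
        return dates.dt.month.to_numpy()
    # fixed 7-day blocks from 1 January; the 1-2 leftover days at year end
    # are dropped so every weekly total/mean covers exactly 7 days
    week = (doy - 1) // 7 + 1
    return np.where(week > 52, -1, week)


def aggregate_series(series: pd.DataFrame) -> SeriesMatrix:
    """Aggregate a raw series into its years x time-class matrix.

    NDVI -> 12 monthly means; temperature -> 52 weekly means; precipitation
    -> 52 weekly totals.  Weeks are fixed 7-day blocks from 1 January; the
    1-2 leftover days at year end are dropped so weekly totals are
    comparable.  Classes with no observations are NaN.
    """
    variable = series["variable"].iloc[0]
    if variable not in _AGG:
        raise ValueError(f"unknown variable {variable!r}")
    scheme, how, t = _AGG[variable]
    dates = pd.to_datetime(series["date"])
    years = dates.dt.year.to_numpy()
    uyears = np.unique(years)
    if len(uyears) < 2:
        raise ValueError("series must cover at least 2 years")
    tc = _time_class(dates, scheme)
    df = pd.DataFrame({"year": years, "tc": tc, "value": series["value"].to_numpy(float)})
    df = df[df["tc"] > 0].dropna(subset=["value"])
    agg = df.groupby(["year", "tc"])["value"].agg(how)
    values = np.full((len(uyears), t), np.nan)
    yidx = {y: i for i, y in enumerate(uyears)}
    for (y, j), v in agg.items():
        values[yidx[y], j - 1] = v
    return SeriesMatrix(
        site_id=str(series["site_id"].iloc[0]) if "site_id" in series else "",
        variable=variable,
        years=uyears,
        n_time_classes=t,
        values=values,
    )


def discretize(
    matrix: SeriesMatrix, n_states: int = 11, strategy: str = "equal_width"
) -> FrequencyTable:
    """Bin the matrix cells into states and tabulate state x time-class counts.

    Bin edges span the observed [min, max] of non-missing cells: ``equal_width``
    splits that range evenly; ``equal_frequency`` uses empirical quantiles
    (degenerate/constant input falls back to an equal-width grid with one
    occupied state).  All bins are half-open [lo, hi) except the top bin,
    which is closed so the maximum is counted exactly once.  Missing cells
    contribute nothing (the grand total Z shrinks accordingly).
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    vals = matrix.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("matrix has no non-missing cells")
    vmin, vmax = float(finite.min()), float(finite.max())
    # a numerically constant matrix (e.g. smoothing jitter at 1e-16) must not
    # have its noise stretched across the state grid
    if vmax - vmin <= 1e-12 * max(abs(vmin), abs(vmax), 1.0):
        vmax = vmin
    if strategy == "equal_frequency" and vmax > vmin:
        qs = np.quantile(finite, np.linspace(0, 1, n_states + 1))
        edges = np.asarray(qs, dtype=float)
        if np.any(np.diff(edges) <= 0):  # ties collapse quantiles
            edges = np.linspace(vmin, vmax, n_states + 1)
    elif strategy in ("equal_width", "equal_frequency"):
        if vmax == vmin:
            # constant input: centre a unit-width grid on the single value
            edges = np.linspace(vmin - 0.5, vmin + 0.5, n_states + 1)
        else:
            edges = np.linspace(vmin, vmax, n_states + 1)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    counts = np.zeros((n_states, matrix.n_time_classes))
    ok = np.isfinite(vals)
    state = np.digitize(vals, edges[1:-1], right=False)  # 0..n_states-1
    for j in range(matrix.n_time_classes):
        col = state[ok[:, j], j]
        if col.size:
            counts[:, j] = np.bincount(col, minlength=n_states)
    return FrequencyTable(counts=counts, bin_edges=edges, n_years=len(matrix.years))


def colwell(table: FrequencyTable) -> ColwellMetrics:
    """Compute Colwell's constancy, contingency and predictability.

    With column totals X_j, row totals Y_i and grand total Z,

        HX  = -sum_j (X_j/Z) log(X_j/Z)        (time-class entropy)
        HY  = -sum_i (Y_i/Z) log(Y_i/Z)        (state entropy)
        HXY = -sum_ij (N_ij/Z) log(N_ij/Z)     (joint entropy)

        C = 1 - HY/log(s)                      (constancy)
        M = (HX + HY - HXY)/log(s)             (contingency)
        P = C + M                              (predictability)

    Natural logs are used internally; the normalised metrics are log-base
    invariant.
    """
    Z = table.Z
    if Z <= 0:
        raise ValueError("empty frequency table")
    if table.s < 2:
        raise ValueError("need at least 2 states")
    HX = _entropy(table.column_totals / Z)
    HY = _entropy(table.row_totals / Z)
    HXY = _entropy(table.counts.ravel() / Z)
    logs = np.log(table.s)
    C = 1.0 - HY / logs
    M = (HX + HY - HXY) / logs
    return ColwellMetrics(
        constancy=C,
        contingency=M,
        predictability=C + M,
        HX=HX,
        HY=HY,
        HXY=HXY,
        s=table.s,
        t=table.t,
        n_years=table.n_years,
        completeness=table.completeness,
    )


def site_predictability(
    series: pd.DataFrame,
    n_states: int = 11,
    strategy: str = "equal_width",
    window_days: int = 45,
    polyorder: int = 2,
) -> dict[str, float]:
    """Chain the full metric pipeline for one site across all three variables.

    ``series`` holds the site's long-format data for temperature,
    precipitation and NDVI.  Returns the six named covariates
    ``{constancy,contingency}_{ndvi,precipitation,temperature}``.
    """
    present = set(series["variable"].unique())
    out: dict[str, float] = {}
    for var in VARIABLES:
        if var not in present:
            raise ValueError(f"missing variable {var!r} for site")
        sub = series[series["variable"] == var]
        if var == "ndvi":
            sub = smooth_ndvi(sub, window_days=window_days, polyorder=polyorder)
        m = colwell(discretize(aggregate_series(sub), n_states, strategy))
        out[f"constancy_{var}"] = m.constancy
        out[f"contingency_{var}"] = m.contingency
    return out


def site_predictability_table(
    series: pd.DataFrame,
    n_states: int = 11,
    strategy: str = "equal_width",
    window_days: int = 45,
    polyorder: int = 2,
) -> pd.DataFrame:
    """Per-site, per-variable metric table for a multi-site series file."""
    rows = []
    for site, ss in series.groupby("site_id"):
        for var in VARIABLES:
            sub = ss[ss["variable"] == var]
            if sub.empty:
                continue
            if var == "ndvi":
                sub = smooth_ndvi(sub, window_days=window_days, polyorder=polyorder)
            m = colwell(discretize(aggregate_series(sub), n_states, strategy))
            rows.append(
                {
                    "site_id": site,
                    "variable": var,
                    "constancy": m.constancy,
                    "contingency": m.contingency,
                    "predictability": m.predictability,
                    "s": m.s,
                    "t": m.t,
                    "n_years": m.n_years,
                    "completeness": m.completeness,
                }
            )
    return pd.DataFrame(rows)
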