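"""Growth-curve parameter extraction from plate-reader OD600 time series.

Three kinetic parameters summarise each curve:

* specific growth rate ``mu`` [1/h] — slopes of the natural-log-transformed OD
  are computed by ordinary least squares in a moving window of three consecutive
  time points (excluding the first 3 h), rank-ordered, the two highest slopes
  dropped, and the next five averaged;
* lag time ``lag_h`` [h] — the intercept of the horizontal line at the
  log-transformed initial population density with the line of slope ``mu``
  extrapolated from the maximum-growth windows;
* growth efficiency ``efficiency_od`` [OD600] — mean of the six highest raw OD
  readings minus the mean of the two lowest (OD_Max - OD_Min).

The module follows the statsmodels convention of a model object built from data
whose :meth:`GrowthCurveModel.fit` returns a results object carrying the
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MU_TOLERANCE = 1e-3  # [1/h] below this the lag intercept is undefined


@dataclass
class GrowthCurve:
    """A single OD600 trajectory.

    times are hours (strictly increasing, >= 10 points); od values are raw
    absorbance readings; an optional plate blank is subtracted before the log
    transform.
    """

    times: np.ndarray
    od: np.ndarray
    condition: str = ""
    replicate: str = ""
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if self.times.size < 10:
            raise ValueError("a growth curve needs at least 10 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("od values must be finite")
        if self.blank < 0:
            raise ValueError("blank must be non-negative")


@dataclass
class GrowthConfig:
    """Tunable extraction settings with the defaults used throughout."""

    window: int = 3
    exclude_first_h: float = 3.0
    log_floor: float = 1e-4
    n_drop: int = 2
    n_avg: int = 5
    n_low: int = 2
    n_high: int = 6
    mu_tolerance: float = MU_TOLERANCE


def _log_od(curve: GrowthCurve, log_floor: float) -> np.ndarray:
    od = curve.od - curve.blank
    return np.log(np.maximum(od, log_floor))


def window_slopes(
    curve: GrowthCurve,
    window: int = 3,
    exclude_first_h: float = 3.0,
    log_floor: float = 1e-4,
    return_windows: bool = False,
):
    """OLS slopes of ln(OD) over every run of ``window`` consecutive points.

    Points earlier than ``exclude_first_h`` are discarded before windowing
    (t == exclude_first_h is kept).  Returns one slope per window ordered by
    window start time; with ``return_windows=True`` also returns, per window,
    the centroid (mean time, mean ln OD) used downstream as the lag anchor.
    """
    keep = curve.times >= exclude_first_h
    t = curve.times[keep]
    y = _log_od(curve, log_floor)[keep]
    n = t.size
    if n < window:
        raise ValueError(
            f"need at least {window} points after excluding the first "
            f"{exclude_first_h} h; got {n}"
        )
    n_win = n - window + 1
    slopes = np.empty(n_win)
    centroids = np.empty((n_win, 2))
    for i in range(n_win):
        ti, yi = t[i : i + window], y[i : i + window]
        tm, ym = ti.mean(), yi.mean()
        denom = np.sum((ti - tm) ** 2)
        slopes[i] = np.sum((ti - tm) * (yi - ym)) / denom
        centroids[i] = (tm, ym)
    if return_windows:
        return slopes, centroids
    return slopes


def specific_growth_rate(slopes, n_drop: int = 2, n_avg: int = 5) -> float:
    """Average of the ``n_avg`` highest window slopes after dropping the top
    ``n_drop`` (defaults: ranks 3-7 of the descending list)."""
    s = np.asarray(slopes, dtype=float)
    if s.size < n_drop + n_avg:
        raise ValueError(
            f"need at least {n_drop + n_avg} slopes, got {s.size}"
        )
    ranked = np.sort(s)[::-1]
    return float(ranked[n_drop : n_drop + n_avg].mean())


def growth_efficiency(curve: GrowthCurve, n_low: int = 2, n_high: int = 6) -> float:
    """OD_Max - OD_Min: mean of the ``n_high`` largest raw readings minus the
    mean of the ``n_low`` smallest, treating readings as a multiset."""
    od = np.asarray(curve.od, dtype=float)
    if od.size < n_low + n_high:
        raise ValueError(f"need at least {n_low + n_high} readings, got {od.size}")
    srt = np.sort(od)
    return max(float(srt[-n_high:].mean() - srt[:n_low].mean()), 0.0)


def lag_time(
    mu: float,
    anchor_t: float,
    anchor_ln_od: float,
    initial_od: float,
    t_end: float,
    mu_tolerance: float = MU_TOLERANCE,
) -> tuple[float, bool]:
    """Intersect the max-growth line with the log initial density.

    The line ``y = anchor_ln_od + mu*(t - anchor_t)`` is intersected with the
    horizontal ``y = ln(initial_od)``; the crossing time, clamped to
    ``[0, t_end]``, is the lag-phase endpoint.  Returns ``(lag_h, defined)``;
    with ``mu`` at or below tolerance the lag is undefined (NaN, False), which
    is a phenotype flag, not an error.
    """
    if initial_od <= 0:
        raise ValueError("initial_od must be positive")
    if mu <= mu_tolerance:
        return float("nan"), False
    t_cross = anchor_t + (math.log(initial_od) - anchor_ln_od) / mu
    return float(min(max(t_cross, 0.0), t_end)), True


@dataclass
class GrowthResults:
    """Extracted growth parameters plus fit diagnostics."""

    lag_h: float
    mu_per_h: float
    efficiency_od: float
    lag_defined: bool
    condition: str = ""
    replicate: str = ""
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["lag_h", "mu_per_h", "efficiency_od"],
                "value": [self.lag_h, self.mu_per_h, self.efficiency_od],
                "unit": ["h", "1/h", "OD600"],
            }
        )


class GrowthCurveModel:
    """Kinetic parameter extraction for one OD600 curve.

    Parameters
    ----------
    curve : GrowthCurve
    config : GrowthConfig, optional
    """

    def __init__(self, curve: GrowthCurve, config: GrowthConfig | None = None):
        self.curve = curve
        self.config = config or GrowthConfig()

    def fit(self) -> GrowthResults:
        cfg = self.config
        slopes, centroids = window_slopes(
            self.curve,
            window=cfg.window,
            exclude_first_h=cfg.exclude_first_h,
            log_floor=cfg.log_floor,
            return_windows=True,
        )
        mu = specific_growth_rate(slopes, n_drop=cfg.n_drop, n_avg=cfg.n_avg)
        eff = growth_efficiency(self.curve, n_low=cfg.n_low, n_high=cfg.n_high)

        # anchor = centroid of the windows whose slopes were averaged into mu
        order = np.argsort(slopes)[::-1]
        used = order[cfg.n_drop : cfg.n_drop + cfg.n_avg]
        anchor_t = float(centroids[used, 0].mean())
        anchor_y = float(centroids[used, 1].mean())

        # initial population density: mean of the n_low lowest raw readings
        # (the OD_Min convention), floored for the log
        srt = np.sort(self.curve.od - self.curve.blank)
        initial_od = max(float(srt[: cfg.n_low].mean()), cfg.log_floor)

        lag, defined = lag_time(
            mu,
            anchor_t,
            anchor_y,
            initial_od,
            t_end=float(self.curve.times[-1]),
            mu_tolerance=cfg.mu_tolerance,
        )
        return GrowthResults(
            lag_h=lag,
            mu_per_h=mu,
            efficiency_od=eff,
            lag_defined=defined,
            condition=self.curve.condition,
            replicate=self.curve.replicate,
            diagnostics={
                "n_windows": int(slopes.size),
                "anchor_t": anchor_t,
                "anchor_ln_od": anchor_y,
                "initial_od": initial_od,
                "used_window_indices": used.tolist(),
                "slopes_used": slopes[used].tolist(),
            },
        )


def fit_growth_parameters(
    curve: GrowthCurve, config: GrowthConfig | None = None
) -> GrowthResults:
    """Functional wrapper around :class:`GrowthCurveModel`."""
    return GrowthCurveModel(curve, config).fit()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_growth_long(path: str | Path, sep: str = "\t") -> list[GrowthCurve]:
    """Read a long-format table with columns time_h, od600, condition, replicate."""
    df = pd.read_csv(path, sep=sep)
    required = {"time_h", "od600", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"long growth table needs columns {sorted(required)}")
    curves = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy(),
                condition=str(cond),
                replicate=str(rep),
            )
        )
    return curves


def read_growth_plate(
    plate_path: str | Path, layout_path: str | Path, sep: str = "\t"
) -> list[GrowthCurve]:
    """Read a wide plate table (rows = time_h, columns = wells) plus a layout
    table with columns well, condition, replicate."""
    plate = pd.read_csv(plate_path, sep=sep)
    layout = pd.read_csv(layout_path, sep=sep)
    if "time_h" not in plate.columns:
        raise ValueError("plate table needs a time_h column")
    if not {"well", "condition", "replicate"}.issubset(layout.columns):
        raise ValueError("layout table needs columns well, condition, replicate")
    t = plate["time_h"].to_numpy()
    curves = []
    for _, row in layout.iterrows():
        well = str(row["well"])
        if well not in plate.columns:
            raise ValueError(f"well {well!r} not present in the plate table")
        curves.append(
            GrowthCurve(
                times=t,
                od=plate[well].to_numpy(dtype=float),
                condition=str(row["condition"]),
                replicate=str(row["replicate"]),
            )
        )
    return curves


def write_growth_results(results: list[GrowthResults], path: str | Path) -> None:
    """One row per curve: condition, replicate, lag, mu, efficiency, flags."""
    rows = [
        {
            "condition": r.condition,
            "replicate": r.replicate,
            "lag_h": r.lag_h,
            "mu_per_h": r.mu_per_h,
            "efficiency_od": r.efficiency_od,
            "lag_defined": r.lag_defined,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
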