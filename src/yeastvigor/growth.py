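"""Maximum growth rate (MGR) estimation from microplate OD time series.

The estimator works in three stages, applied per test environment:

1. background-correct each culture's raw OD readings;
2. choose a single OD window (lower and upper corrected-OD bound) shared by
   *all* cultures of the environment, picked to maximize the mean Pearson
   correlation of log OD versus time over the readings falling inside the
   window — this isolates the exponential phase while excluding lag and
   saturation in a way that is comparable across strains;
3. within that window, fit ordinary least squares of natural-log OD on time
   for each culture.  The slope is the MGR (per hour); the Pearson r of the
   same points is the quality score, with a QC threshold (default 0.99).

Window candidates are quantiles of the pooled corrected OD values of the
environment (``grid_size`` quantiles, default 25), and every (lower, upper)
pair that leaves at least ``min_points`` readings in every culture is scored;
the search is exhaustive over that grid, so a brute-force check over the same
candidates must agree exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WellSeries",
    "ODWindow",
    "MGREstimate",
    "NoFeasibleWindowError",
    "correct_background",
    "select_window",
    "fit_mgr",
    "estimate_environment",
    "GrowthRateModel",
    "GrowthRateResults",
]

#: objective values closer than this are considered tied during window search
_TIE_TOL = 1e-12


class NoFeasibleWindowError(RuntimeError):
    """No candidate OD window keeps the required points in every culture."""


@dataclass
class WellSeries:
    """One culture's OD trajectory (a strain x environment x replicate)."""

    strain_id: str
    environment_id: str
    replicate: int
    times: np.ndarray
    od_raw: np.ndarray
    od_corrected: np.ndarray | None = None
    correction_method: str | None = None
    usable: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        if self.times.shape != self.od_raw.shape:
            raise ValueError("times and od_raw must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"times must be strictly increasing for "
                f"({self.strain_id}, {self.environment_id}, {self.replicate})"
            )
        if self.od_corrected is not None:
            self.od_corrected = np.asarray(self.od_corrected, dtype=float)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ODWindow:
    """Inclusive corrected-OD bounds delimiting the exponential phase."""

    od_lower: float
    od_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.od_lower < self.od_upper):
            raise ValueError("require 0 < od_lower < od_upper")

    def mask(self, od: np.ndarray) -> np.ndarray:
        return (od >= self.od_lower) & (od <= self.od_upper)


@dataclass
class MGREstimate:
    strain_id: str
    environment_id: str
    replicate: int
    mgr: float          # per hour; NaN when fewer than 2 in-window points
    pearson_r: float    # NaN when undefined (zero variance)
    n_points: int
    window: ODWindow
    qc_pass: bool

    def to_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "environment": self.environment_id,
            "replicate": self.replicate,
            "mgr_per_h": self.mgr,
            "pearson_r": self.pearson_r,
            "n_points": self.n_points,
            "od_lower": self.window.od_lower,
            "od_upper": self.window.od_upper,
            "qc_pass": self.qc_pass,
        }


def correct_background(
    series: WellSeries,
    method: str = "min_minus_eps",
    blank: float | np.ndarray | None = None,
    epsilon: float = 0.005,
) -> WellSeries:
    """Subtract a background estimate from raw OD, clipping at ``epsilon``.

    method:
        ``blank_well``    — subtract the median of ``blank`` readings;
        ``first_read``    — subtract the first reading of the series;
        ``min_minus_eps`` — subtract ``min(od_raw) - epsilon`` so the smallest
        corrected value is exactly ``epsilon`` (log stays defined).
    """
    od = series.od_raw
    flags = list(series.flags)
    if method == "blank_well":
        if blank is None:
            raise ValueError("blank readings required for method='blank_well'")
        b = float(np.median(np.asarray(blank, dtype=float)))
    elif method == "first_read":
        b = float(od[0])
    elif method == "min_minus_eps":
        if od.size and np.all(od == od[0]):
            warnings.warn(
                f"all-equal OD readings in ({series.strain_id}, "
                f"{series.environment_id}, {series.replicate}); "
                "background is ill-defined",
                stacklevel=2,
            )
            flags.append("constant_od")
        b = float(np.min(od)) - epsilon
    else:
        raise ValueError(f"unknown background method {method!r}")
    corrected = np.clip(od - b, epsilon, None)
    return replace(
        series,
        od_corrected=corrected,
        correction_method=method,
        flags=flags,
    )


def _pad(cultures: list[WellSeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack ragged series into padded (t, log od, valid) arrays."""
    tmax = max(len(c) for c in cultures)
    t = np.zeros((len(cultures), tmax))
    od = np.full((len(cultures), tmax), np.nan)
    for i, c in enumerate(cultures):
        if c.od_corrected is None:
            raise ValueError("cultures must be background-corrected first")
        t[i, : len(c)] = c.times
        od[i, : len(c)] = c.od_corrected
    valid = ~np.isnan(od)
    return t, od, valid


def _masked_mean_r(
    t: np.ndarray, logod: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-culture Pearson r(log OD, t) over masked points.

    Returns (mean r, per-culture point counts); mean is NaN if any culture
    has an undefined correlation (zero variance) on its retained points.
    """
    n = mask.sum(axis=1)
    if np.any(n < 2):
        return np.nan, n
    tm = np.where(mask, t, 0.0)
    ym = np.where(mask, logod, 0.0)
    sx = tm.sum(axis=1)
    sy = ym.sum(axis=1)
    sxx = (tm * tm).sum(axis=1)
    syy = (ym * ym).sum(axis=1)
    sxy = (tm * ym).sum(axis=1)
    vart = sxx - sx * sx / n
    vary = syy - sy * sy / n
    cov = sxy - sx * sy / n
    denom = vart * vary
    if np.any(denom <= 0):
        return np.nan, n
    r = cov / np.sqrt(denom)
    return float(r.mean()), n


def _window_candidates(
    cultures: list[WellSeries], grid_size: int, exhaustive: bool
) -> np.ndarray:
    pooled = np.concatenate([c.od_corrected for c in cultures])
    if exhaustive:
        return np.unique(pooled)
    qs = np.quantile(pooled, np.linspace(0.0, 1.0, grid_size))
    return np.unique(qs)


def select_window(
    cultures: list[WellSeries],
    grid_size: int = 25,
    min_points: int = 5,
    exhaustive: bool = False,
) -> ODWindow:
    """Pick the OD window maximizing mean Pearson r(log OD, time).

    Candidate bounds are pooled-OD quantiles (or every observed value when
    ``exhaustive``).  A pair (lo, hi), lo < hi, is feasible iff every culture
    keeps at least ``min_points`` readings with lo <= OD <= hi and its
    retained points have a defined correlation.  Ties on the objective are
    broken by the wider window, then the smaller lower bound.
    """
    if not cultures:
        raise ValueError("select_window requires at least one culture")
    cand = _window_candidates(cultures, grid_size, exhaustive)
    t, od, valid = _pad(cultures)
    with np.errstate(invalid="ignore"):
        logod = np.where(valid & (od > 0), np.log(np.where(od > 0, od, 1.0)), np.nan)

    best: tuple[float, float, float] | None = None  # (obj, width, -lo)
    best_win: ODWindow | None = None
    for i in range(len(cand)):
        lo = cand[i]
        if lo <= 0:
            continue
        for j in range(i + 1, len(cand)):
            hi = cand[j]
            mask = valid & (od >= lo) & (od <= hi)
            n = mask.sum(axis=1)
            if np.any(n < min_points):
                continue
            obj, _ = _masked_mean_r(t, logod, mask)
            if math.isnan(obj):
                continue
            key = (obj, hi - lo, -lo)
            if best is None or _key_better(key, best):
                best = key
                best_win = ODWindow(float(lo), float(hi))
    if best_win is None:
        raise NoFeasibleWindowError(
            "no OD window keeps >= "
            f"{min_points} points in every culture; lower min_points or "
            "inspect the trajectories for non-overlapping OD ranges"
        )
    return best_win


def _key_better(key: tuple, best: tuple) -> bool:
    if key[0] > best[0] + _TIE_TOL:
        return True
    if key[0] < best[0] - _TIE_TOL:
        return False
    if key[1] > best[1] + _TIE_TOL:
        return True
    if key[1] < best[1] - _TIE_TOL:
        return False
    return key[2] > best[2] + _TIE_TOL


def fit_mgr(
    series: WellSeries,
    window: ODWindow,
    min_points: int = 5,
    qc_r_threshold: float = 0.99,
) -> MGREstimate:
    """OLS of ln(corrected OD) on time over the in-window readings."""
    if series.od_corrected is None:
        raise ValueError("series must be background-corrected first")
    mask = window.mask(series.od_corrected)
    t = series.times[mask]
    y = series.od_corrected[mask]
    n = int(mask.sum())
    if n < 2:
        return MGREstimate(
            series.strain_id, series.environment_id, series.replicate,
            math.nan, math.nan, n, window, False,
        )
    ly = np.log(y)
    tc = t - t.mean()
    yc = ly - ly.mean()
    vart = float(tc @ tc)
    vary = float(yc @ yc)
    cov = float(tc @ yc)
    if vary == 0.0:
        # flat series: zero slope, correlation undefined
        return MGREstimate(
            series.strain_id, series.environment_id, series.replicate,
            0.0, math.nan, n, window, False,
        )
    slope = cov / vart
    r = cov / math.sqrt(vart * vary)
    qc = (n >= min_points) and (r >= qc_r_threshold)
    return MGREstimate(
        series.strain_id, series.environment_id, series.replicate,
        slope, r, n, window, qc,
    )


def estimate_environment(
    cultures: list[WellSeries],
    grid_size: int = 25,
    min_points: int = 5,
    qc_r_threshold: float = 0.99,
    background: str = "min_minus_eps",
    epsilon: float = 0.005,
    blank: float | np.ndarray | None = None,
    exhaustive: bool = False,
) -> tuple[list[MGREstimate], ODWindow]:
    """Correct, select one shared window, and fit every culture of one environment."""
    envs = {c.environment_id for c in cultures}
    if len(envs) != 1:
        raise ValueError(f"cultures span several environments: {sorted(envs)}")
    corrected = [
        correct_background(c, method=background, blank=blank, epsilon=epsilon)
        for c in cultures
        if c.usable
    ]
    if not corrected:
        raise ValueError("no usable cultures in environment")
    window = select_window(
        corrected, grid_size=grid_size, min_points=min_points, exhaustive=exhaustive
    )
    estimates = [
        fit_mgr(c, window, min_points=min_points, qc_r_threshold=qc_r_threshold)
        for c in corrected
    ]
    return estimates, window


class GrowthRateModel:
    """Per-environment exponential-window MGR estimation over a plate dataset.

    Parameters
    ----------
    wells
        Background-uncorrected :class:`WellSeries` covering one or more
        environments.
    grid_size, min_points, qc_r_threshold, background, epsilon, blank,
    exhaustive
        Passed through to the per-environment pipeline; see module docstring.
    """

    def __init__(
        self,
        wells: list[WellSeries],
        grid_size: int = 25,
        min_points: int = 5,
        qc_r_threshold: float = 0.99,
        background: str = "min_minus_eps",
        epsilon: float = 0.005,
        blank: float | np.ndarray | None = None,
        exhaustive: bool = False,
    ):
        self.wells = list(wells)
        self.grid_size = grid_size
        self.min_points = min_points
        self.qc_r_threshold = qc_r_threshold
        self.background = background
        self.epsilon = epsilon
        self.blank = blank
        self.exhaustive = exhaustive

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GrowthRateModel":
        """Build from a long table with columns strain, environment, replicate, time_h, od."""
        from .io import wells_from_frame

        return cls(wells_from_frame(df), **kwargs)

    def fit(self) -> "GrowthRateResults":
        by_env: dict[str, list[WellSeries]] = {}
        for w in self.wells:
            by_env.setdefault(w.environment_id, []).append(w)
        estimates: list[MGREstimate] = []
        windows: dict[str, ODWindow] = {}
        n_skipped = sum(1 for w in self.wells if not w.usable)
        for env in sorted(by_env):
            est, win = estimate_environment(
                by_env[env],
                grid_size=self.grid_size,
                min_points=self.min_points,
                qc_r_threshold=self.qc_r_threshold,
                background=self.background,
                epsilon=self.epsilon,
                blank=self.blank,
                exhaustive=self.exhaustive,
            )
            estimates.extend(est)
            windows[env] = win
        return GrowthRateResults(self, estimates, windows, n_skipped)


class GrowthRateResults:
    """MGR estimates, per-environment windows and QC bookkeeping."""

    def __init__(
        self,
        model: GrowthRateModel,
        estimates: list[MGREstimate],
        windows: dict[str, ODWindow],
        n_unusable: int = 0,
    ):
        self.model = model
        self.estimates = estimates
        self.windows = windows
        self.n_unusable = n_unusable

    @property
    def frame(self) -> pd.DataFrame:
        """Replicate-level MGR table (one row per culture)."""
        return pd.DataFrame([e.to_dict() for e in self.estimates])

    def fitness_matrix(self, qc_only: bool = True) -> pd.DataFrame:
        """Mean MGR per strain x environment over (QC-passing) replicates."""
        df = self.frame
        if qc_only:
            df = df[df["qc_pass"]]
        return (
            df.groupby(["strain", "environment"], as_index=False)["mgr_per_h"]
            .mean()
            .rename(columns={"mgr_per_h": "mgr"})
        )

    def summary(self) -> str:
        df = self.frame
        lines = ["Maximum growth rate estimation", "=" * 34]
        lines.append(f"cultures fitted: {len(df)}   unusable series: {self.n_unusable}")
        lines.append(f"QC failures (r < {self.model.qc_r_threshold} or too few points): "
                     f"{int((~df['qc_pass']).sum())}")
        lines.append("")
        lines.append("environment   od_lower  od_upper  mean_r   mean_mgr")
        for env in sorted(self.windows):
            sub = df[df["environment"] == env]
            win = self.windows[env]
            lines.append(
                f"{env:<13} {win.od_lower:8.4f}  {win.od_upper:8.4f}  "
                f"{sub['pearson_r'].mean():.4f}   {sub['mgr_per_h'].mean():.4f}"
            )
        return "\n".join(lines)
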