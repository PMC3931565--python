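"""Agar-patch stress assays: intensity calibration, growth rates, survival.

Patch photographs yield reflectance intensities before and after incubation.
A linear calibration (cell count vs intensity, fitted on counted patches)
converts intensities to cell numbers; the patch growth rate is then

    rate = ln(cells_final / cells_initial) / incubation_h        [per hour]
    doublings = log2(cells_final / cells_initial)

Because inocula are pregrown under benign conditions, a little residual
growth can reflect carry-over rather than true growth under stress:
conditions whose mean doublings over trials stay at or below a threshold
(default 3) are classified nongrowing and their fitness set to zero; a
strain counts as a grower in a condition iff at least one of its trials
retains a positive fitness after that zeroing.

Survival curves report the proportion of growers along each stress
gradient.  For the cross-stress independence question, fitness at the most
extreme dose of each agent is normalized by the stress-specific median of
growers, each strain's empirical mean over the three stresses is compared
with a resampling null (draw one value per stress at random, average;
default 10,000 draws) using the two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heterosis import StatTestResult

__all__ = [
    "Calibration",
    "calibrate_intensity",
    "patch_growth_rate",
    "classify_grower",
    "survival_curve",
    "normalize_fitness",
    "resample_null",
    "ks_two_sample",
    "StressAssayModel",
    "StressAssayResults",
]

PATCH_COLUMNS = [
    "strain", "agent", "dose", "trial",
    "intensity_initial", "intensity_final", "incubation_h",
]


@dataclass
class Calibration:
    """Linear map from patch intensity to cell count."""

    slope: float       # cells per intensity unit
    intercept: float   # cells
    pearson_r: float

    def cells(self, intensity: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(intensity, dtype=float) + self.intercept


def calibrate_intensity(pairs: pd.DataFrame) -> Calibration:
    """OLS of cell count on intensity over counted patches (>= 3 pairs)."""
    if len(pairs) < 3:
        raise ValueError("calibration needs at least 3 (intensity, cells) pairs")
    x = pairs["intensity"].to_numpy(dtype=float)
    y = pairs["cells"].to_numpy(dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("calibration intensities and counts must be positive")
    res = stats.linregress(x, y)
    calib = Calibration(float(res.slope), float(res.intercept), float(res.rvalue))
    fitted = calib.cells(np.array([x.min(), x.max()]))
    if np.any(fitted <= 0):
        warnings.warn(
            "calibration line predicts nonpositive cell counts over the "
            "observed intensity range",
            stacklevel=2,
        )
    return calib


def patch_growth_rate(
    cells_initial: float, cells_final: float, incubation_h: float
) -> tuple[float, float]:
    """(per-hour growth rate, cell doublings) from initial/final cell counts."""
    if cells_initial <= 0 or cells_final <= 0 or incubation_h <= 0:
        raise ValueError("cell counts and incubation time must be positive")
    ratio = cells_final / cells_initial
    return math.log(ratio) / incubation_h, math.log2(ratio)


def classify_grower(
    rates: np.ndarray,
    doublings: np.ndarray,
    doubling_threshold: float = 3.0,
    order: str = "zero_then_test",
) -> tuple[bool, np.ndarray]:
    """Apply the nongrower rules to one strain x condition's trials.

    Default order zeroes first (mean doublings <= threshold -> all trial
    fitness set to 0), then asks whether any trial remains positive.  The
    alternative order ('test_then_zero') decides grower status on the raw
    rates before zeroing, for sensitivity analysis.
    """
    rates = np.asarray(rates, dtype=float)
    doublings = np.asarray(doublings, dtype=float)
    if rates.size == 0 or rates.size != doublings.size:
        raise ValueError("need 1-3 matching trial rates and doublings")
    nongrowing = doublings.mean() <= doubling_threshold
    if order == "zero_then_test":
        out = np.zeros_like(rates) if nongrowing else rates.copy()
        return bool(np.any(out > 0)), out
    if order == "test_then_zero":
        is_grower = bool(np.any(rates > 0))
        out = np.zeros_like(rates) if nongrowing else rates.copy()
        return is_grower, out
    raise ValueError(f"unknown rule order {order!r}")


def survival_curve(
    fitness: pd.DataFrame, group_cols: list[str] | None = None
) -> pd.DataFrame:
    """Proportion of grower strains per agent x dose (x optional groups)."""
    keys = ["agent", "dose"] + (group_cols or [])
    per_strain = (
        fitness.groupby(keys + ["strain"], as_index=False)["is_grower"].first()
    )
    out = (
        per_strain.groupby(keys)
        .agg(n_strains=("strain", "nunique"), proportion_growers=("is_grower", "mean"))
        .reset_index()
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return out


def normalize_fitness(values: pd.Series | np.ndarray) -> np.ndarray:
    """Divide by the median over growers (positive values); zeros stay zero."""
    v = np.asarray(values, dtype=float)
    growers = v[v > 0]
    if growers.size == 0:
        raise ValueError("no growers in this stress; normalization undefined")
    return v / np.median(growers)


def resample_null(
    per_stress_values: dict[str, np.ndarray],
    n_draws: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of 3-stress mean fitness under independence.

    Each draw picks one value uniformly with replacement from every stress's
    full value set (zeros of nongrowers included) and records the average.
    """
    if seed is None:
        raise ValueError("resampling requires an explicit seed")
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(v, dtype=float) for v in per_stress_values.values()]
    if not arrays or any(a.size == 0 for a in arrays):
        raise ValueError("every stress needs at least one value")
    draws = np.stack(
        [a[rng.integers(0, a.size, size=n_draws)] for a in arrays]
    )
    return draws.mean(axis=0)


def ks_two_sample(sample_a: np.ndarray, sample_b: np.ndarray) -> StatTestResult:
    """Two-sample Kolmogorov–Smirnov D with the asymptotic p-value.

    D = sup |ECDF_a - ECDF_b| over the pooled points; p uses the Kolmogorov
    distribution at effective n = n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    n_eff = a.size * b.size / (a.size + b.size)
    return StatTestResult(
        float(res.statistic), float(n_eff), float(min(1.0, res.pvalue)),
        "two-sample K-S", a.size + b.size,
    )


class StressAssayModel:
    """Agar stress pipeline over a patch table and a calibration table.

    Parameters
    ----------
    patches
        Columns strain, agent, dose, trial, intensity_initial,
        intensity_final, incubation_h.
    calibration_pairs
        Columns intensity, cells (counted patches).
    strain_classes
        Optional columns strain, ploidy (homozygote/heterozygote) and
        origin_class, used for survival-curve grouping.
    """

    def __init__(
        self,
        patches: pd.DataFrame,
        calibration_pairs: pd.DataFrame,
        strain_classes: pd.DataFrame | None = None,
        doubling_threshold: float = 3.0,
        rule_order: str = "zero_then_test",
    ):
        missing = [c for c in PATCH_COLUMNS if c not in patches.columns]
        if missing:
            raise ValueError(f"patch table missing column(s) {missing}")
        if (patches[["intensity_initial", "intensity_final"]] <= 0).any().any():
            raise ValueError("patch intensities must be positive")
        if (patches["incubation_h"] <= 0).any():
            raise ValueError("incubation times must be positive")
        self.patches = patches.copy()
        self.calibration_pairs = calibration_pairs
        self.strain_classes = strain_classes
        self.doubling_threshold = doubling_threshold
        self.rule_order = rule_order

    def fit(self) -> "StressAssayResults":
        calib = calibrate_intensity(self.calibration_pairs)
        df = self.patches.copy()
        ci = np.maximum(calib.cells(df["intensity_initial"].to_numpy()), 1.0)
        cf = np.maximum(calib.cells(df["intensity_final"].to_numpy()), 1.0)
        inc = df["incubation_h"].to_numpy(dtype=float)
        ratio = cf / ci
        df["growth_rate"] = np.log(ratio) / inc
        df["doublings"] = np.log2(ratio)
        # vectorized form of classify_grower over all strain x condition cells
        key = ["strain", "agent", "dose"]
        grouped = df.groupby(key)
        nongrowing = grouped["doublings"].transform("mean") <= self.doubling_threshold
        raw_positive = df["growth_rate"] > 0
        df.loc[nongrowing, "growth_rate"] = 0.0
        if self.rule_order == "zero_then_test":
            df["is_grower"] = (df["growth_rate"] > 0).groupby(
                [df[k] for k in key]
            ).transform("any")
        elif self.rule_order == "test_then_zero":
            df["is_grower"] = raw_positive.groupby(
                [df[k] for k in key]
            ).transform("any")
        else:
            raise ValueError(f"unknown rule order {self.rule_order!r}")
        df["nongrowing"] = nongrowing
        return StressAssayResults(self, calib, df)


class StressAssayResults:
    """Per-trial agar fitness with grower flags, plus derived analyses."""

    def __init__(
        self,
        model: StressAssayModel,
        calibration: Calibration,
        fitness: pd.DataFrame,
    ):
        self.model = model
        self.calibration = calibration
        self.fitness = fitness

    def survival_curves(self) -> pd.DataFrame:
        df = self.fitness
        group_cols: list[str] = []
        if self.model.strain_classes is not None:
            df = df.merge(self.model.strain_classes, on="strain", how="left")
            group_cols = [
                c for c in ("ploidy", "origin_class")
                if c in self.model.strain_classes.columns
            ]
        return survival_curve(df, group_cols or None)

    def extreme_conditions(self) -> dict[str, float]:
        """Highest dose per agent (the most extreme stress of each gradient)."""
        return self.fitness.groupby("agent")["dose"].max().to_dict()

    def normalized_fitness(self) -> pd.DataFrame:
        """Strain x agent fitness at the extreme dose, median-normalized.

        Per strain and agent the trial mean of the (zeroed) growth rate is
        taken; growers' stress-specific median maps to 1, nongrowers to 0.
        """
        extremes = self.extreme_conditions()
        frames = []
        for agent, dose in extremes.items():
            sub = self.fitness[
                (self.fitness["agent"] == agent) & (self.fitness["dose"] == dose)
            ]
            strain_means = sub.groupby("strain")["growth_rate"].mean()
            norm = normalize_fitness(strain_means.to_numpy())
            frames.append(
                pd.DataFrame(
                    {"strain": strain_means.index, "agent": agent,
                     "normalized_fitness": norm}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def empirical_means(self) -> pd.Series:
        """Per-strain mean normalized fitness over the extreme stresses.

        Restricted to strains assayed under every agent's extreme condition.
        """
        norm = self.normalized_fitness()
        wide = norm.pivot(index="strain", columns="agent",
                          values="normalized_fitness").dropna()
        return wide.mean(axis=1)

    def resampled_null(self, n_draws: int = 10_000, seed: int | None = None) -> np.ndarray:
        norm = self.normalized_fitness()
        per_stress = {
            agent: grp["normalized_fitness"].to_numpy()
            for agent, grp in norm.groupby("agent")
        }
        return resample_null(per_stress, n_draws=n_draws, seed=seed)

    def ks_independence(
        self, n_draws: int = 10_000, seed: int | None = None
    ) -> StatTestResult:
        """K-S test of the empirical 3-stress means against the resampling null.

        A non-significant D says per-strain performance across the extreme
        stresses looks no more concordant than independent draws.
        """
        emp = self.empirical_means().to_numpy()
        null = self.resampled_null(n_draws=n_draws, seed=seed)
        return ks_two_sample(emp, null)

    def summary(self, seed: int | None = None) -> str:
        lines = ["Agar stress assays", "=" * 30]
        lines.append(
            f"calibration: cells = {self.calibration.slope:.1f} x intensity "
            f"+ {self.calibration.intercept:.1f} (r = {self.calibration.pearson_r:.3f})"
        )
        curves = self.survival_curves()
        for agent, grp in curves.groupby("agent"):
            overall = grp.groupby("dose")["proportion_growers"].mean()
            path = "  ".join(f"{d:g}:{p:.2f}" for d, p in overall.items())
            lines.append(f"{agent}: grower proportion by dose  {path}")
        if seed is not None:
            ks = self.ks_independence(seed=seed)
            lines.append(
                f"K-S empirical vs independence null: D = {ks.statistic:.4f}, "
                f"P = {ks.p_value:.3f}"
            )
        return "\n".join(lines)
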