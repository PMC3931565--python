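"""Mid-parent and best-parent heterosis, cross classes, and divergence tests.

A hybrid shows mid-parent heterosis (MPH) when its fitness exceeds the mean
of its two homozygous parents, and best-parent heterosis (BPH) when it
exceeds even the fitter parent:

    MPH = F_hybrid - (F_p1 + F_p2) / 2
    BPH = F_hybrid - max(F_p1, F_p2)

so MPH >= BPH always, with equality iff the parents are equally fit.  Both
are in MGR units (per hour).  Positive BPH means the hybrid beats its best
parent — the conventional sign, under which heterosis is positive.

Crosses are stratified by parental origin: DxD (both domesticated), WxW
(both wild) and mixed.  Under the complementation model, recessive
deleterious alleles private to one parent are masked in the hybrid, so MPH
should grow with the number of private mutations and hence with the
sequence divergence between the parents; :func:`divergence_correlation`
tests exactly that with a Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DivergenceMatrix

__all__ = [
    "CROSS_CLASSES",
    "StatTestResult",
    "midparent_heterosis",
    "bestparent_heterosis",
    "classify_cross",
    "heterosis_scores",
    "heterosis_summary",
    "oneway_anova_F",
    "welch_t",
    "significance_stars",
    "divergence_correlation",
    "HeterosisModel",
    "HeterosisResults",
]

CROSS_CLASSES = ("DxD", "mixed", "WxW")


@dataclass
class StatTestResult:
    """Outcome of a classical test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    test_name: str
    n: int | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Star coding for significance: * 0.05, ** 0.01, *** 0.001."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def midparent_heterosis(f_hybrid: float, f_p1: float, f_p2: float) -> float:
    """Hybrid fitness minus the arithmetic mean of its parents' fitness."""
    return f_hybrid - (f_p1 + f_p2) / 2.0


def bestparent_heterosis(f_hybrid: float, f_p1: float, f_p2: float) -> float:
    """Hybrid fitness minus the fitter parent's fitness (positive = exceeds it)."""
    return f_hybrid - max(f_p1, f_p2)


def classify_cross(origin1: str, origin2: str) -> str:
    """DxD / mixed / WxW from the two parental origins (symmetric)."""
    for o in (origin1, origin2):
        if o not in ("wild", "domesticated"):
            raise ValueError(f"unknown origin label {o!r}")
    if origin1 == origin2 == "domesticated":
        return "DxD"
    if origin1 == origin2 == "wild":
        return "WxW"
    return "mixed"


def heterosis_scores(
    fitness: pd.DataFrame,
    crosses: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Per hybrid x environment MPH/BPH table.

    ``fitness`` has columns strain, environment, mgr (strain x environment
    means).  Hybrids lacking either parent's value in an environment are
    excluded from that environment.
    """
    origin = dict(zip(metadata["strain"], metadata["origin"]))
    fit = {(r.strain, r.environment): r.mgr for r in fitness.itertuples()}
    envs = sorted(fitness["environment"].unique())
    rows = []
    for cr in crosses.itertuples():
        cls = classify_cross(origin[cr.parent1], origin[cr.parent2])
        for env in envs:
            fh = fit.get((cr.hybrid, env))
            f1 = fit.get((cr.parent1, env))
            f2 = fit.get((cr.parent2, env))
            if fh is None or f1 is None or f2 is None:
                continue
            rows.append(
                (
                    cr.hybrid,
                    env,
                    midparent_heterosis(fh, f1, f2),
                    bestparent_heterosis(fh, f1, f2),
                    cls,
                )
            )
    return pd.DataFrame(
        rows, columns=["hybrid", "environment", "mph", "bph", "cross_class"]
    )


def heterosis_summary(
    scores: pd.DataFrame, per_environment: bool = False
) -> pd.DataFrame:
    """Class-level means and positive proportions of MPH/BPH.

    Proportions use strict > 0; exact zeros are counted as non-positive and
    reported in their own columns.
    """
    keys = ["cross_class"] + (["environment"] if per_environment else [])
    out = []
    for key, grp in scores.groupby(keys):
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        out.append(
            dict(
                zip(keys, key),
                n=n,
                mean_mph=grp["mph"].mean(),
                mean_bph=grp["bph"].mean(),
                prop_mph_positive=(grp["mph"] > 0).mean(),
                prop_bph_positive=(grp["bph"] > 0).mean(),
                prop_mph_zero=(grp["mph"] == 0).mean(),
                prop_bph_zero=(grp["bph"] == 0).mean(),
            )
        )
    df = pd.DataFrame(out)
    order = {c: i for i, c in enumerate(CROSS_CLASSES)}
    return df.sort_values(
        keys, key=lambda s: s.map(order) if s.name == "cross_class" else s
    ).reset_index(drop=True)


def oneway_anova_F(*groups: np.ndarray) -> StatTestResult:
    """Classic one-way ANOVA F = MS_between / MS_within with (k-1, N-k) df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df1, df2 = k - 1, n_total - k
    if df2 < 1:
        raise ValueError("not enough total observations for a within-group df")
    f_stat, p = stats.f_oneway(*arrays)
    return StatTestResult(float(f_stat), (df1, df2), float(p), "one-way ANOVA", n_total)


def welch_t(sample1: np.ndarray, sample2: np.ndarray) -> StatTestResult:
    """Welch's unequal-variance t with Welch–Satterthwaite df (two-sided)."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # degenerate: identical constants; no evidence of a difference
            return StatTestResult(0.0, float(a.size + b.size - 2), 1.0,
                                  "Welch t", a.size + b.size)
        return StatTestResult(math.inf, float(a.size + b.size - 2), 0.0,
                              "Welch t", a.size + b.size)
    res = stats.ttest_ind(a, b, equal_var=False)
    return StatTestResult(float(res.statistic), float(res.df), float(res.pvalue),
                          "Welch t", a.size + b.size)


def divergence_correlation(
    values: pd.DataFrame,
    divergence: DivergenceMatrix,
    value_col: str = "mph",
) -> StatTestResult:
    """Pearson correlation between a hybrid metric and parental divergence.

    ``values`` has columns parent1, parent2 and ``value_col``, one row per
    hybrid (already restricted to one environment and one cross-class
    subset).  p is two-sided from t = r * sqrt((n-2) / (1-r^2)).
    """
    if len(values) < 3:
        raise ValueError("need at least 3 hybrid pairs for a correlation")
    d = np.array(
        [divergence.distance(p1, p2)
         for p1, p2 in zip(values["parent1"], values["parent2"])]
    )
    y = values[value_col].to_numpy(dtype=float)
    n = len(y)
    if np.ptp(d) == 0 or np.ptp(y) == 0:
        return StatTestResult(math.nan, float(n - 2), math.nan,
                              "Pearson r (degenerate)", n)
    r, p = stats.pearsonr(d, y)
    return StatTestResult(float(r), float(n - 2), float(p), "Pearson r", n)


class HeterosisModel:
    """Heterosis analysis over a fitness matrix, cross design and metadata.

    Parameters
    ----------
    fitness
        Replicate-level MGR table with columns strain, environment, mgr
        (optionally replicate and qc_pass; QC failures are dropped).
    metadata
        Columns strain, origin (wild / domesticated) for the parental
        homozygotes.
    crosses
        Columns hybrid, parent1, parent2.
    divergence
        Optional pairwise distance matrix over the parental strains.
    """

    def __init__(
        self,
        fitness: pd.DataFrame,
        metadata: pd.DataFrame,
        crosses: pd.DataFrame,
        divergence: DivergenceMatrix | None = None,
    ):
        fitness = fitness.copy()
        if "mgr" not in fitness.columns and "mgr_per_h" in fitness.columns:
            fitness = fitness.rename(columns={"mgr_per_h": "mgr"})
        if "qc_pass" in fitness.columns:
            fitness = fitness[fitness["qc_pass"].astype(bool)]
        self.fitness = fitness
        self.metadata = metadata
        self.crosses = crosses
        self.divergence = divergence
        missing = set(crosses["parent1"]) | set(crosses["parent2"])
        missing -= set(metadata["strain"])
        if missing:
            raise ValueError(f"parents missing from metadata: {sorted(missing)}")

    def fit(self) -> "HeterosisResults":
        means = (
            self.fitness.groupby(["strain", "environment"], as_index=False)["mgr"]
            .mean()
        )
        scores = heterosis_scores(means, self.crosses, self.metadata)
        return HeterosisResults(self, means, scores)


class HeterosisResults:
    """Heterosis scores plus the derived group comparisons."""

    def __init__(
        self,
        model: HeterosisModel,
        strain_env_means: pd.DataFrame,
        scores: pd.DataFrame,
    ):
        self.model = model
        self.strain_env_means = strain_env_means
        self.scores = scores

    # -- class summaries ----------------------------------------------------

    def class_summary(
        self, per_environment: bool = False, unit: str = "cells"
    ) -> pd.DataFrame:
        """Class means and positive proportions.

        ``unit='cells'`` summarizes hybrid x environment scores;
        ``unit='hybrids'`` first averages each hybrid over environments (the
        two readings of "proportion of hybrids better than expected").
        """
        if unit == "cells":
            return heterosis_summary(self.scores, per_environment=per_environment)
        if unit == "hybrids":
            if per_environment:
                raise ValueError("per-hybrid averages pool environments")
            return heterosis_summary(self.per_hybrid_scores())
        raise ValueError(f"unknown unit {unit!r}")

    def per_hybrid_scores(self) -> pd.DataFrame:
        """Environment-averaged MPH/BPH, one row per hybrid."""
        return (
            self.scores.groupby(["hybrid", "cross_class"], as_index=False)[
                ["mph", "bph"]
            ].mean()
        )

    # -- heterozygote vs homozygote ANOVA -----------------------------------

    def _strain_level_means(self) -> pd.DataFrame:
        """One mean MGR per strain, averaged over environments and replicates."""
        return (
            self.strain_env_means.groupby("strain", as_index=False)["mgr"].mean()
        )

    def heterozygote_vs_homozygote(self, subset: str = "all") -> StatTestResult:
        """One-way F comparing hybrid vs homozygote strain-level mean MGR.

        ``subset``: 'all' (every hybrid vs every homozygote), 'domesticated'
        (DxD hybrids vs domesticated homozygotes) or 'wild' (WxW vs wild).
        """
        md = self.model.metadata
        origin = dict(zip(md["strain"], md["origin"]))
        cls = {
            r.hybrid: classify_cross(origin[r.parent1], origin[r.parent2])
            for r in self.model.crosses.itertuples()
        }
        means = self._strain_level_means()
        if subset == "all":
            homs = set(md["strain"])
            hets = set(cls)
        elif subset == "domesticated":
            homs = {s for s, o in origin.items() if o == "domesticated"}
            hets = {h for h, c in cls.items() if c == "DxD"}
        elif subset == "wild":
            homs = {s for s, o in origin.items() if o == "wild"}
            hets = {h for h, c in cls.items() if c == "WxW"}
        else:
            raise ValueError(f"unknown subset {subset!r}")
        het_vals = means.loc[means["strain"].isin(hets), "mgr"].to_numpy()
        hom_vals = means.loc[means["strain"].isin(homs), "mgr"].to_numpy()
        return oneway_anova_F(het_vals, hom_vals)

    def origin_comparison(self) -> StatTestResult:
        """Welch t of replicate-level homozygote MGR: wild vs domesticated."""
        md = self.model.metadata
        origin = dict(zip(md["strain"], md["origin"]))
        fit = self.model.fitness
        hom = fit[fit["strain"].isin(origin)]
        wild = hom.loc[hom["strain"].map(origin) == "wild", "mgr"].to_numpy()
        dom = hom.loc[hom["strain"].map(origin) == "domesticated", "mgr"].to_numpy()
        return welch_t(wild, dom)

    # -- divergence correlations --------------------------------------------

    def divergence_correlations(
        self,
        metrics: tuple[str, ...] = ("mgr", "mph", "bph"),
        subsets: tuple[str, ...] = ("all", "DxD", "WxW"),
        per_environment: bool = True,
        adjust: str | None = None,
    ) -> pd.DataFrame:
        """Grid of Pearson r of a hybrid metric vs parental divergence.

        metric 'mgr' is the hybrid's absolute MGR; 'mph'/'bph' the heterosis
        scores.  Subsets restrict to one cross class ('all' keeps every
        hybrid).  With ``per_environment=False`` the metric is averaged over
        environments first.  Raw p-values are reported with star coding;
        ``adjust='bh'`` appends a Benjamini-Hochberg column over the whole
        grid.
        """
        if self.model.divergence is None:
            raise ValueError("model was built without a divergence matrix")
        parents = self.model.crosses.set_index("hybrid")[["parent1", "parent2"]]
        base = self.scores.merge(parents, left_on="hybrid", right_index=True)
        hyb_mgr = self.strain_env_means.rename(
            columns={"strain": "hybrid", "mgr": "hybrid_mgr"}
        )
        base = base.merge(hyb_mgr, on=["hybrid", "environment"], how="left")
        base = base.rename(columns={"hybrid_mgr": "mgr"})
        envs = (
            sorted(base["environment"].unique()) if per_environment else [None]
        )
        rows = []
        for metric in metrics:
            for subset in subsets:
                sub = base if subset == "all" else base[base["cross_class"] == subset]
                for env in envs:
                    if env is None:
                        data = (
                            sub.groupby(["hybrid", "parent1", "parent2"],
                                        as_index=False)[metric].mean()
                        )
                    else:
                        data = sub[sub["environment"] == env]
                    if len(data) < 3:
                        continue
                    res = divergence_correlation(
                        data, self.model.divergence, value_col=metric
                    )
                    rows.append(
                        {
                            "metric": metric,
                            "subset": subset,
                            "environment": env if env is not None else "mean",
                            "n": res.n,
                            "r": res.statistic,
                            "p": res.p_value,
                            "stars": res.stars,
                        }
                    )
        grid = pd.DataFrame(rows)
        if adjust is not None:
            if adjust != "bh":
                raise ValueError(f"unknown adjustment {adjust!r}")
            ok = grid["p"].notna()
            grid["p_bh"] = math.nan
            grid.loc[ok, "p_bh"] = stats.false_discovery_control(
                grid.loc[ok, "p"], method="bh"
            )
        return grid

    # -- summary -------------------------------------------------------------

    def summary(self) -> str:
        cs = self.class_summary()
        lines = ["Heterosis analysis", "=" * 30]
        lines.append(
            f"hybrids: {self.scores['hybrid'].nunique()}   "
            f"environments: {self.scores['environment'].nunique()}"
        )
        lines.append("")
        lines.append("class   n(cells)  mean MPH  mean BPH  P(MPH>0)  P(BPH>0)")
        for r in cs.itertuples():
            lines.append(
                f"{r.cross_class:<7} {r.n:8d}  {r.mean_mph:8.4f}  {r.mean_bph:8.4f}"
                f"  {r.prop_mph_positive:8.3f}  {r.prop_bph_positive:8.3f}"
            )
        for subset in ("all", "domesticated", "wild"):
            try:
                t = self.heterozygote_vs_homozygote(subset)
            except ValueError:
                continue
            df1, df2 = t.df
            lines.append(
                f"het vs hom ({subset}): F = {t.statistic:.3f}; "
                f"df = {df1} and {df2}; P = {t.p_value:.4g} {t.stars}"
            )
        return "\n".join(lines)
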