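"""Variance components of replicate-level MGR and intraclass correlation.

For a balanced two-way random-effects layout (g genotypes x e environments
x n replicates) the method-of-moments estimators follow from the expected
mean squares of the standard ANOVA table:

    sigma2_error    = MS_within
    sigma2_gxe      = (MS_GxE - MS_within) / n
    sigma2_genotype = (MS_G   - MS_GxE) / (e * n)
    sigma2_env      = (MS_E   - MS_GxE) / (g * n)

Raw estimates can be negative by sampling noise; both the raw values and
their absolute ("reported") magnitudes are kept.  On balanced data these
moment estimators coincide with REML for this model.

The one-way intraclass correlation ICC(1) measures replicate repeatability
within one environment:

    ICC = (MS_between - MS_within) / (MS_between + (k0 - 1) * MS_within)

with k0 the (Searle-adjusted) replicate count per strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "varcomp_from_array",
    "varcomp_two_way",
    "icc_oneway",
    "icc_average",
    "VarianceComponentsModel",
    "VarianceComponentsResults",
]

COMPONENTS = ("environment", "genotype", "gxe", "error")


@dataclass
class VarianceComponents:
    """Raw (possibly negative) EMS estimates plus absolute reported values."""

    sigma2_env: float
    sigma2_genotype: float
    sigma2_gxe: float
    sigma2_error: float
    n_genotypes: int
    n_environments: int
    n_replicates: int

    @property
    def raw(self) -> dict[str, float]:
        return {
            "environment": self.sigma2_env,
            "genotype": self.sigma2_genotype,
            "gxe": self.sigma2_gxe,
            "error": self.sigma2_error,
        }

    @property
    def reported(self) -> dict[str, float]:
        """Absolute values, as variance-component magnitudes are displayed."""
        return {k: abs(v) for k, v in self.raw.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": list(COMPONENTS),
                "raw": [self.raw[c] for c in COMPONENTS],
                "reported": [self.reported[c] for c in COMPONENTS],
            }
        )


@dataclass
class ICCResult:
    """One-way ICC: reported value truncated at 0, raw value retained."""

    value: float
    raw: float
    k0: float
    n_groups: int
    flagged: bool = False


def varcomp_from_array(y: np.ndarray) -> VarianceComponents:
    """EMS variance components from a balanced (g, e, n) array."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a (genotype, environment, replicate) array")
    g, e, n = y.shape
    if g < 2 or e < 2 or n < 2:
        raise ValueError(
            "need >= 2 genotypes, >= 2 environments and >= 2 replicates "
            "to separate interaction from error"
        )
    grand = y.mean()
    cell = y.mean(axis=2)                       # (g, e)
    gm = y.mean(axis=(1, 2))                    # (g,)
    em = y.mean(axis=(0, 2))                    # (e,)
    ss_g = e * n * float(((gm - grand) ** 2).sum())
    ss_e = g * n * float(((em - grand) ** 2).sum())
    inter = cell - gm[:, None] - em[None, :] + grand
    ss_ge = n * float((inter ** 2).sum())
    ss_err = float(((y - cell[:, :, None]) ** 2).sum())
    ms_g = ss_g / (g - 1)
    ms_e = ss_e / (e - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_err = ss_err / (g * e * (n - 1))
    return VarianceComponents(
        sigma2_env=(ms_e - ms_ge) / (g * n),
        sigma2_genotype=(ms_g - ms_ge) / (e * n),
        sigma2_gxe=(ms_ge - ms_err) / n,
        sigma2_error=ms_err,
        n_genotypes=g,
        n_environments=e,
        n_replicates=n,
    )


def varcomp_two_way(
    df: pd.DataFrame,
    genotype: str = "strain",
    environment: str = "environment",
    value: str = "mgr",
    balance: str = "error",
    seed: int | None = None,
) -> VarianceComponents:
    """EMS variance components from a long replicate-level table.

    The design must be balanced.  ``balance='subsample'`` randomly thins
    every genotype x environment cell to the minimum replicate count
    (seeded); the default ``'error'`` refuses unbalanced input.
    """
    counts = df.groupby([genotype, environment])[value].count()
    full = df[genotype].nunique() * df[environment].nunique()
    if len(counts) != full or counts.min() == 0:
        raise ValueError("design has empty genotype x environment cells")
    n_min, n_max = int(counts.min()), int(counts.max())
    if n_min != n_max:
        if balance == "error":
            raise ValueError(
                f"unbalanced design (replicates {n_min}..{n_max}); pass "
                "balance='subsample' with a seed to thin to the minimum count"
            )
        if balance != "subsample":
            raise ValueError(f"unknown balance mode {balance!r}")
        if seed is None:
            raise ValueError("balance='subsample' requires a seed")
        rng = np.random.default_rng(seed)
        df = (
            df.groupby([genotype, environment], group_keys=False)[df.columns]
            .apply(lambda grp: grp.iloc[rng.permutation(len(grp))[:n_min]])
        )
    gl = sorted(df[genotype].unique())
    el = sorted(df[environment].unique())
    y = np.empty((len(gl), len(el), n_min))
    gi = {k: i for i, k in enumerate(gl)}
    ei = {k: i for i, k in enumerate(el)}
    filled = np.zeros((len(gl), len(el)), dtype=int)
    for row in df.itertuples():
        a = gi[getattr(row, genotype)]
        b = ei[getattr(row, environment)]
        y[a, b, filled[a, b]] = getattr(row, value)
        filled[a, b] += 1
    return varcomp_from_array(y)


def icc_oneway(
    df: pd.DataFrame, group: str = "strain", value: str = "mgr"
) -> ICCResult:
    """One-way random-effects ICC(1) of replicate measurements within strains.

    Unbalanced groups use Searle's adjusted replicate count
    k0 = (N - sum(k_i^2) / N) / (s - 1).  All-identical values give ICC = 1
    by convention (flagged: both variance components are zero).
    """
    sizes = df.groupby(group)[value].count()
    s = len(sizes)
    if s < 2:
        raise ValueError("need at least two strains")
    if (sizes < 2).any():
        raise ValueError("every strain needs at least two replicates")
    n_total = int(sizes.sum())
    vals = df[value].to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        return ICCResult(1.0, 1.0, float(sizes.mean()), s, flagged=True)
    k0 = (n_total - float((sizes ** 2).sum()) / n_total) / (s - 1)
    grand = vals.mean()
    means = df.groupby(group)[value].mean()
    ss_b = float((sizes * (means - grand) ** 2).sum())
    ss_w = float(
        ((df[value] - df[group].map(means)) ** 2).sum()
    )
    ms_b = ss_b / (s - 1)
    ms_w = ss_w / (n_total - s)
    if ms_w == 0:
        return ICCResult(1.0, 1.0, k0, s)
    raw = (ms_b - ms_w) / (ms_b + (k0 - 1) * ms_w)
    return ICCResult(max(0.0, raw), raw, k0, s)


def icc_average(iccs: list[float]) -> float:
    """Arithmetic mean of per-environment ICC values."""
    if not iccs:
        raise ValueError("need at least one environment ICC")
    return float(np.mean(iccs))


class VarianceComponentsModel:
    """Variance decomposition of a replicate-level MGR table.

    With ``metadata``/``crosses`` supplied, components are estimated
    separately for the six panels all/domesticated/wild x
    homozygote/heterozygote; otherwise for the whole table.
    """

    def __init__(
        self,
        fitness: pd.DataFrame,
        metadata: pd.DataFrame | None = None,
        crosses: pd.DataFrame | None = None,
        balance: str = "error",
        seed: int | None = None,
    ):
        fitness = fitness.copy()
        if "mgr" not in fitness.columns and "mgr_per_h" in fitness.columns:
            fitness = fitness.rename(columns={"mgr_per_h": "mgr"})
        if "qc_pass" in fitness.columns:
            fitness = fitness[fitness["qc_pass"].astype(bool)]
        self.fitness = fitness
        self.metadata = metadata
        self.crosses = crosses
        self.balance = balance
        self.seed = seed

    def _panels(self) -> dict[str, pd.DataFrame]:
        if self.metadata is None or self.crosses is None:
            return {"all": self.fitness}
        from .heterosis import classify_cross

        origin = dict(zip(self.metadata["strain"], self.metadata["origin"]))
        cls = {
            r.hybrid: classify_cross(origin[r.parent1], origin[r.parent2])
            for r in self.crosses.itertuples()
        }
        f = self.fitness
        is_hom = f["strain"].isin(origin)
        panels = {
            "all_homozygote": f[is_hom],
            "all_heterozygote": f[f["strain"].isin(cls)],
            "domesticated_homozygote": f[
                is_hom & (f["strain"].map(origin) == "domesticated")
            ],
            "domesticated_heterozygote": f[
                f["strain"].map(cls) == "DxD"
            ],
            "wild_homozygote": f[is_hom & (f["strain"].map(origin) == "wild")],
            "wild_heterozygote": f[f["strain"].map(cls) == "WxW"],
        }
        return {k: v for k, v in panels.items() if v["strain"].nunique() >= 2}

    def fit(self) -> "VarianceComponentsResults":
        components = {
            name: varcomp_two_way(
                panel, balance=self.balance, seed=self.seed
            )
            for name, panel in self._panels().items()
        }
        iccs = {}
        for env, grp in self.fitness.groupby("environment"):
            counts = grp.groupby("strain")["mgr"].count()
            if len(counts) >= 2 and (counts >= 2).all():
                iccs[env] = icc_oneway(grp)
        return VarianceComponentsResults(self, components, iccs)


class VarianceComponentsResults:
    def __init__(
        self,
        model: VarianceComponentsModel,
        components: dict[str, VarianceComponents],
        iccs: dict[str, ICCResult],
    ):
        self.model = model
        self.components = components
        self.iccs = iccs

    @property
    def icc_mean(self) -> float:
        """ICC averaged over environments (the repeatability headline)."""
        return icc_average([icc.value for icc in self.iccs.values()])

    def components_frame(self) -> pd.DataFrame:
        frames = []
        for name, vc in self.components.items():
            f = vc.to_frame()
            f.insert(0, "group", name)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def icc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "environment": list(self.iccs),
                "icc": [v.value for v in self.iccs.values()],
                "icc_raw": [v.raw for v in self.iccs.values()],
            }
        )

    def summary(self) -> str:
        lines = ["Variance decomposition", "=" * 30]
        if self.iccs:
            lines.append(
                f"ICC averaged over {len(self.iccs)} environments: "
                f"{self.icc_mean:.3f}"
            )
        lines.append("")
        lines.append("group                        env      genotype  gxe      error")
        for name, vc in self.components.items():
            rep = vc.reported
            lines.append(
                f"{name:<28} {rep['environment']:.5f}  {rep['genotype']:.5f}"
                f"  {rep['gxe']:.5f}  {rep['error']:.5f}"
            )
        return "\n".join(lines)
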