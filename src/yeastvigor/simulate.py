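"""Synthetic data with the statistical structure the analysis assumes.

The generating model: strains sit on a two-clade ultrametric phylogeny
(domesticated and wild).  Recessive deleterious mutations accumulate along
branches as a Poisson process with a clade-specific rate per unit branch
length (default: only the domesticated clade accumulates load-relevant
mutations), each mutation drawing a homozygous selection coefficient s from
an exponential distribution.  A strain inherits every mutation on its
root-to-tip path, so shared ancestry means shared mutations.

Fitness is multiplicative across loci.  A homozygote expresses every
mutation in full; in a hybrid, mutations carried by both parents stay
homozygous (factor 1 - s) while mutations private to one parent become
heterozygous (factor 1 - h*s; h = 0 means full complementation).  Observed
MGR adds a strain-x-environment interaction and replicate noise on the log
scale:

    MGR = env_mean * prod_i(1 - h_i * s_i) * exp(g + eps)

Liquid cultures are emulated as logistic OD trajectories with additive
background and read noise; agar assays as a load-threshold survival model
with per-agent robustness draws that are independent across agents by
default, so cross-stress performance is uncorrelated.

Pairwise sequence divergence is Poisson-sampled from patristic distance via
a background substitution rate shared by both clades, so the distance
matrix is informative about ancestry even where the wild clade carries no
fitness load.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DivergenceMatrix, write_divergence_matrix, write_plate_timeseries

__all__ = [
    "SimulationParams",
    "StrainTree",
    "simulate_tree",
    "assign_mutations",
    "homozygote_factor",
    "hybrid_factor",
    "homozygote_fitness",
    "hybrid_fitness",
    "simulate_fitness_table",
    "generate_od_curves",
    "generate_agar_assays",
    "SyntheticDataset",
    "generate_dataset",
]


def _default_agents() -> dict:
    # dose gradients and incubation times mirror typical salt / zinc /
    # salicylate stress ramps (doses in %, mg/ml, %; incubation in hours)
    return {
        "NaCl": {"doses": [2.0, 8.0, 9.0, 10.0], "incubation_h": [48, 72, 96, 120]},
        "salicylate": {"doses": [2.5, 3.5, 4.0, 5.0], "incubation_h": [24, 24, 48, 72]},
        "ZnSO4": {"doses": [0.5, 2.0, 2.5, 2.75], "incubation_h": [24, 48, 72, 120]},
    }


@dataclass
class SimulationParams:
    """Stated world of the generator; defaults are the study-scale design."""

    # design
    n_dom: int = 13
    n_wild: int = 9
    n_env: int = 11
    n_rep_hom: int = 6
    n_rep_het: int = 4
    # phylogeny (branch lengths in arbitrary time units)
    clade_height: float = 8.0
    stem_length: float = 0.25
    height_power: float = 0.25   # < 1 pushes coalescences toward the clade
                                 # root (radiation-like rapid diversification)
    subst_rate: float = 1500.0   # substitutions per unit branch length
    # mutation accumulation
    lambda_dom: float = 0.8      # load mutations per unit branch length
    lambda_wild: float = 0.0
    s_mean: float = 0.03         # mean homozygous selection coefficient
    h: float = 0.0               # dominance coefficient (0 = fully recessive)
    # environment and noise (log scale)
    env_means: tuple[float, ...] | None = None   # default linspace(0.20, 0.65)
    sigma_gxe: float = 0.035
    sigma_rep: float = 0.02
    # liquid OD trajectories
    od0: float = 0.005
    K: float = 2.0               # carrying capacity (corrected OD)
    background_od: float = 0.08
    sigma_od: float = 0.0002
    dt_h: float = 0.5
    t_max_h: float = 16.0
    # agar stress assays
    agents: dict = field(default_factory=_default_agents)
    robustness_sd: float = 0.2
    cross_stress_correlation: float = 0.0
    threshold_start: float = 0.6
    threshold_end: float = -0.05
    n_trials: int = 3
    cells_inoculum: float = 3e5
    calib_slope: float = 2000.0  # cells per intensity unit
    calib_intercept: float = 0.0
    calib_noise_rel: float = 0.03
    n_calib: int = 40

    def __post_init__(self) -> None:
        if self.n_dom + self.n_wild < 3:
            raise ValueError("need at least 3 strains in total")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError("dominance coefficient h must lie in [0, 1]")
        for name in ("lambda_dom", "lambda_wild", "s_mean", "sigma_gxe",
                     "sigma_rep", "sigma_od", "robustness_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.env_means is None:
            self.env_means = tuple(np.linspace(0.20, 0.65, self.n_env))
        if len(self.env_means) != self.n_env:
            raise ValueError("env_means length must equal n_env")

    @property
    def environment_ids(self) -> list[str]:
        return [f"E{i + 1:02d}" for i in range(self.n_env)]

    @property
    def strain_ids(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_dom)] + [
            f"W{i + 1:02d}" for i in range(self.n_wild)
        ]

    @property
    def origins(self) -> dict[str, str]:
        return {
            s: ("domesticated" if s.startswith("D") else "wild")
            for s in self.strain_ids
        }


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

@dataclass
class StrainTree:
    """Rooted binary tree; ``clade[v]`` labels the branch above node v."""

    labels: list[str]          # tip labels, index = node id
    parent: np.ndarray         # parent node id, -1 at the root
    length: np.ndarray         # branch length above each node
    clade: np.ndarray          # 0 domesticated, 1 wild, -1 root

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    def path_to_root(self, tip: int) -> list[int]:
        """Node ids whose branches lie on the root-to-tip path."""
        path = []
        v = tip
        while self.parent[v] != -1:
            path.append(v)
            v = self.parent[v]
        return path

    def tip_depth(self, tip: int) -> float:
        return float(sum(self.length[v] for v in self.path_to_root(tip)))

    def patristic_matrix(self) -> np.ndarray:
        n = self.n_tips
        paths = [self.path_to_root(i) for i in range(n)]
        sets = [set(p) for p in paths]
        lens = [dict(zip(p, self.length[p])) for p in paths]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                sym = sets[i] ^ sets[j]
                dist = sum(
                    lens[i].get(v, 0.0) + lens[j].get(v, 0.0) for v in sym
                )
                d[i, j] = d[j, i] = dist
        return d


def _coalescent_clade(
    tips: list[int], rng: np.random.Generator, height: float, power: float,
    next_id: itertools.count,
) -> tuple[dict[int, int], dict[int, float], int]:
    """Kingman coalescent over given tips, rescaled to the target height.

    Node heights are then transformed by h -> height * (h / height)**power;
    a power < 1 pushes coalescences toward the clade root, emulating a
    rapid early radiation (star-like clades).
    """
    heights = {t: 0.0 for t in tips}
    parent: dict[int, int] = {}
    active = list(tips)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        new = next(next_id)
        heights[new] = t
        parent[a] = parent[b] = new
        active = [x for x in active if x not in (a, b)] + [new]
    root = active[0]
    if len(tips) > 1:
        scale = height / heights[root]
        heights = {
            v: height * (h * scale / height) ** power if h > 0 else 0.0
            for v, h in heights.items()
        }
    else:
        heights[root] = 0.0
    return parent, heights, root


def simulate_tree(
    params: SimulationParams, seed: int | np.random.Generator
) -> tuple[StrainTree, DivergenceMatrix]:
    """Two-clade coalescent tree plus a Poisson-sampled divergence matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_dom + params.n_wild
    labels = params.strain_ids
    counter = itertools.count(n)
    dom_tips = list(range(params.n_dom))
    wild_tips = list(range(params.n_dom, n))
    p1, h1, r1 = _coalescent_clade(
        dom_tips, rng, params.clade_height, params.height_power, counter
    )
    p2, h2, r2 = _coalescent_clade(
        wild_tips, rng, params.clade_height, params.height_power, counter
    )
    root = next(counter)
    n_nodes = root + 1
    parent = np.full(n_nodes, -1, dtype=int)
    length = np.zeros(n_nodes)
    clade = np.full(n_nodes, -1, dtype=int)
    heights = np.zeros(n_nodes)
    for p, h, r, cl in ((p1, h1, r1, 0), (p2, h2, r2, 1)):
        for v, hh in h.items():
            heights[v] = hh
            clade[v] = cl
        for v, pa in p.items():
            parent[v] = pa
        parent[r] = root
    root_height = params.clade_height + params.stem_length
    heights[root] = root_height
    for v in range(n_nodes - 1):
        length[v] = heights[parent[v]] - heights[v]
    tree = StrainTree(labels, parent, length, clade)
    pat = tree.patristic_matrix()
    counts = np.zeros_like(pat)
    iu = np.triu_indices(n, k=1)
    counts[iu] = rng.poisson(params.subst_rate * pat[iu])
    counts = counts + counts.T
    return tree, DivergenceMatrix(labels, counts)


# ---------------------------------------------------------------------------
# mutation accumulation and fitness
# ---------------------------------------------------------------------------

def assign_mutations(
    tree: StrainTree,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> dict[str, dict[int, float]]:
    """Poisson mutation placement on branches; tips inherit their path.

    Returns one {mutation_id: s} map per strain label; ids are shared
    between strains exactly when the mutation arose on a shared branch.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = {0: params.lambda_dom, 1: params.lambda_wild}
    branch_muts: dict[int, dict[int, float]] = {}
    mut_id = itertools.count()
    for v in range(len(tree.parent)):
        if tree.parent[v] == -1:
            continue
        lam = rates[int(tree.clade[v])] * tree.length[v]
        k = rng.poisson(lam) if lam > 0 else 0
        muts = {}
        for _ in range(k):
            s = rng.exponential(params.s_mean)
            while s >= 1.0:
                s = rng.exponential(params.s_mean)
            muts[next(mut_id)] = s
        branch_muts[v] = muts
    out: dict[str, dict[int, float]] = {}
    for tip in range(tree.n_tips):
        acc: dict[int, float] = {}
        for v in tree.path_to_root(tip):
            acc.update(branch_muts.get(v, {}))
        out[tree.labels[tip]] = acc
    return out


def homozygote_factor(mutations: dict[int, float]) -> float:
    """Multiplicative fitness factor of a fully homozygous strain."""
    return float(np.prod([1.0 - s for s in mutations.values()])) if mutations else 1.0


def hybrid_factor(
    muts1: dict[int, float], muts2: dict[int, float], h: float
) -> float:
    """Fitness factor of the F1: shared loci homozygous, private masked by h."""
    shared = muts1.keys() & muts2.keys()
    f = 1.0
    for m, s in muts1.items():
        f *= (1.0 - s) if m in shared else (1.0 - h * s)
    for m, s in muts2.items():
        if m not in shared:
            f *= 1.0 - h * s
    return f


def _draw_mgr(
    factor: float,
    env_mean: float,
    sigma_gxe: float,
    sigma_rep: float,
    rng: np.random.Generator | None,
    n_rep: int,
) -> np.ndarray:
    if rng is None:
        if sigma_gxe > 0 or sigma_rep > 0:
            raise ValueError("noise draws require an rng")
        return np.full(n_rep, env_mean * factor)
    g = rng.normal(0.0, sigma_gxe)
    eps = rng.normal(0.0, sigma_rep, size=n_rep)
    return env_mean * factor * np.exp(g + eps)


def homozygote_fitness(
    mutations: dict[int, float],
    env_mean: float,
    sigma_gxe: float = 0.0,
    sigma_rep: float = 0.0,
    rng: np.random.Generator | None = None,
    n_rep: int = 1,
) -> np.ndarray:
    """Replicate MGR draws for a homozygote in one environment."""
    return _draw_mgr(
        homozygote_factor(mutations), env_mean, sigma_gxe, sigma_rep, rng, n_rep
    )


def hybrid_fitness(
    muts1: dict[int, float],
    muts2: dict[int, float],
    env_mean: float,
    h: float = 0.0,
    sigma_gxe: float = 0.0,
    sigma_rep: float = 0.0,
    rng: np.random.Generator | None = None,
    n_rep: int = 1,
) -> np.ndarray:
    """Replicate MGR draws for the F1 of two parents in one environment."""
    return _draw_mgr(
        hybrid_factor(muts1, muts2, h), env_mean, sigma_gxe, sigma_rep, rng, n_rep
    )


def _hybrid_id(p1: str, p2: str) -> str:
    a, b = sorted((p1, p2))
    return f"{a}x{b}"


def simulate_fitness_table(
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> dict:
    """Replicate-level true MGR for every homozygote and hybrid.

    Returns a dict with keys tree, divergence, mutations, metadata, crosses,
    fitness (strain, environment, replicate, mgr), truth_strains (per-strain
    deterministic factor, mutation count, load = sum of s).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree, divergence = simulate_tree(params, rng)
    mutations = assign_mutations(tree, params, rng)

    origins = params.origins
    homs = params.strain_ids
    pairs = list(itertools.combinations(homs, 2))
    crosses = pd.DataFrame(
        [(_hybrid_id(a, b), a, b) for a, b in pairs],
        columns=["hybrid", "parent1", "parent2"],
    )
    metadata = pd.DataFrame(
        {"strain": homs, "origin": [origins[s] for s in homs]}
    )

    factors: dict[str, float] = {s: homozygote_factor(mutations[s]) for s in homs}
    loads: dict[str, float] = {
        s: float(sum(mutations[s].values())) for s in homs
    }
    n_muts: dict[str, int] = {s: len(mutations[s]) for s in homs}
    ploidy: dict[str, str] = {s: "homozygote" for s in homs}
    for a, b in pairs:
        hid = _hybrid_id(a, b)
        factors[hid] = hybrid_factor(mutations[a], mutations[b], params.h)
        shared = mutations[a].keys() & mutations[b].keys()
        loads[hid] = float(
            sum(s for m, s in mutations[a].items() if m in shared)
            + params.h * sum(s for m, s in mutations[a].items() if m not in shared)
            + params.h * sum(s for m, s in mutations[b].items() if m not in shared)
        )
        n_muts[hid] = len(mutations[a].keys() | mutations[b].keys())
        ploidy[hid] = "heterozygote"

    strains = list(factors)
    n_strain = len(strains)
    env_ids = params.environment_ids
    env_means = np.asarray(params.env_means)
    reps = np.array(
        [params.n_rep_hom if ploidy[s] == "homozygote" else params.n_rep_het
         for s in strains]
    )
    g = rng.normal(0.0, params.sigma_gxe, size=(n_strain, params.n_env))
    rows_strain, rows_env, rows_rep, rows_mgr = [], [], [], []
    fvec = np.array([factors[s] for s in strains])
    for i, s in enumerate(strains):
        eps = rng.normal(0.0, params.sigma_rep, size=(params.n_env, reps[i]))
        mgr = env_means[:, None] * fvec[i] * np.exp(g[i][:, None] + eps)
        for e in range(params.n_env):
            rows_strain.extend([s] * reps[i])
            rows_env.extend([env_ids[e]] * reps[i])
            rows_rep.extend(range(1, reps[i] + 1))
            rows_mgr.extend(mgr[e])
    fitness = pd.DataFrame(
        {
            "strain": rows_strain,
            "environment": rows_env,
            "replicate": rows_rep,
            "mgr": rows_mgr,
        }
    )
    truth_strains = pd.DataFrame(
        {
            "strain": strains,
            "ploidy": [ploidy[s] for s in strains],
            "fitness_factor": [factors[s] for s in strains],
            "n_mutations": [n_muts[s] for s in strains],
            "load": [loads[s] for s in strains],
        }
    )
    return {
        "tree": tree,
        "divergence": divergence,
        "mutations": mutations,
        "metadata": metadata,
        "crosses": crosses,
        "fitness": fitness,
        "truth_strains": truth_strains,
    }


# ---------------------------------------------------------------------------
# liquid OD trajectories
# ---------------------------------------------------------------------------

def generate_od_curves(
    fitness: pd.DataFrame,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Logistic OD trajectories (plus background and read noise) per culture.

    ``fitness`` is the replicate-level true-MGR table; each row becomes one
    well sampled every ``dt_h`` hours up to ``t_max_h``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, params.t_max_h + 1e-9, params.dt_h)
    r = fitness["mgr"].to_numpy(dtype=float)
    if np.any(r <= 0):
        raise ValueError("true MGR values must be positive to grow a culture")
    ert = np.exp(np.outer(r, t))
    od = params.K * params.od0 * ert / (params.K + params.od0 * (ert - 1.0))
    od = od + params.background_od
    if params.sigma_od > 0:
        od = od + rng.normal(0.0, params.sigma_od, size=od.shape)
    od = np.maximum(od, 1e-4)
    n_cult, n_t = od.shape
    return pd.DataFrame(
        {
            "strain": np.repeat(fitness["strain"].to_numpy(), n_t),
            "environment": np.repeat(fitness["environment"].to_numpy(), n_t),
            "replicate": np.repeat(fitness["replicate"].to_numpy(), n_t),
            "time_h": np.tile(t, n_cult),
            "od": od.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# agar stress assays
# ---------------------------------------------------------------------------

def generate_agar_assays(
    truth_strains: pd.DataFrame,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patch assay table, calibration pairs and per-condition ground truth.

    Survival follows a load-threshold rule: a strain grows at a dose iff
    load + z_agent < threshold(dose), with z_agent a per-strain robustness
    draw independent across agents (unless ``cross_stress_correlation`` > 0
    mixes in a shared component).  Growing patches make 4-6 doublings
    scaled by the threshold margin; nongrowing patches show only carry-over
    growth (< 3 doublings).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains = truth_strains["strain"].to_numpy()
    load = truth_strains["load"].to_numpy(dtype=float)
    n = len(strains)
    rho = params.cross_stress_correlation
    common = rng.normal(0.0, params.robustness_sd, size=n)
    frames = []
    truth_frames = []
    for agent, spec_a in params.agents.items():
        doses = np.asarray(spec_a["doses"], dtype=float)
        incub = np.asarray(spec_a["incubation_h"], dtype=float)
        thresholds = np.linspace(
            params.threshold_start, params.threshold_end, len(doses)
        )
        indep = rng.normal(0.0, params.robustness_sd, size=n)
        z = rho * common + np.sqrt(max(0.0, 1.0 - rho**2)) * indep
        for d_idx, dose in enumerate(doses):
            margin = thresholds[d_idx] - (load + z)
            grows = margin > 0
            truth_frames.append(
                pd.DataFrame(
                    {"strain": strains, "agent": agent, "dose": dose,
                     "grows_true": grows}
                )
            )
            nt = params.n_trials
            db_grow = (
                4.0
                + 2.0 * np.minimum(1.0, margin / 0.5)[None, :]
                + rng.normal(0.0, 0.4, size=(nt, n))
            )
            db_grow = np.maximum(db_grow, 3.3)
            db_non = rng.uniform(0.5, 2.5, size=(nt, n))
            doublings = np.where(grows[None, :], db_grow, db_non)
            cells_init = params.cells_inoculum * np.exp(
                rng.normal(0.0, 0.1, size=(nt, n))
            )
            cells_final = cells_init * np.exp2(doublings)
            int_init = (cells_init - params.calib_intercept) / params.calib_slope
            int_final = (cells_final - params.calib_intercept) / params.calib_slope
            int_init = int_init * (1.0 + rng.normal(0.0, 0.02, size=(nt, n)))
            int_final = int_final * (1.0 + rng.normal(0.0, 0.02, size=(nt, n)))
            frames.append(
                pd.DataFrame(
                    {
                        "strain": np.tile(strains, nt),
                        "agent": agent,
                        "dose": dose,
                        "trial": np.repeat(np.arange(1, nt + 1), n),
                        "intensity_initial": np.maximum(0.5, int_init).ravel(),
                        "intensity_final": np.maximum(0.5, int_final).ravel(),
                        "incubation_h": incub[d_idx],
                    }
                )
            )
    patches = pd.DataFrame(
        pd.concat(frames, ignore_index=True),
        columns=[
            "strain", "agent", "dose", "trial",
            "intensity_initial", "intensity_final", "incubation_h",
        ],
    )
    # counted-patch calibration sample spanning the observed intensity range
    intensity = np.exp(rng.uniform(np.log(50.0), np.log(20000.0), size=params.n_calib))
    cells = (params.calib_slope * intensity + params.calib_intercept) * (
        1.0 + rng.normal(0.0, params.calib_noise_rel, size=params.n_calib)
    )
    calibration = pd.DataFrame({"intensity": intensity, "cells": cells})
    truth = pd.concat(truth_frames, ignore_index=True)
    return patches, calibration, truth


# ---------------------------------------------------------------------------
# full dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """All generated tables, matching the pipeline's input schemas."""

    params: SimulationParams
    seed: int
    metadata: pd.DataFrame
    crosses: pd.DataFrame
    divergence: DivergenceMatrix
    fitness_true: pd.DataFrame
    truth_strains: pd.DataFrame
    plate: pd.DataFrame | None = None
    patches: pd.DataFrame | None = None
    calibration: pd.DataFrame | None = None
    agar_truth: pd.DataFrame | None = None

    def strain_classes(self) -> pd.DataFrame:
        """Strain, ploidy and origin class (for stress-survival grouping)."""
        origin = dict(zip(self.metadata["strain"], self.metadata["origin"]))
        from .heterosis import classify_cross

        rows = []
        for r in self.truth_strains.itertuples():
            if r.ploidy == "homozygote":
                oc = origin[r.strain]
            else:
                p1, p2 = r.strain.split("x")
                oc = {"DxD": "domesticated", "WxW": "wild", "mixed": "mixed"}[
                    classify_cross(origin[p1], origin[p2])
                ]
            rows.append((r.strain, r.ploidy, oc))
        return pd.DataFrame(rows, columns=["strain", "ploidy", "origin_class"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _save(name: str, df: pd.DataFrame) -> None:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p

        _save("strains", self.metadata)
        _save("crosses", self.crosses)
        write_divergence_matrix(self.divergence, outdir / "divergence.csv")
        paths["divergence"] = outdir / "divergence.csv"
        _save("fitness_true", self.fitness_true)
        _save("truth_strains", self.truth_strains)
        _save("strain_classes", self.strain_classes())
        if self.plate is not None:
            write_plate_timeseries(self.plate, outdir / "plate.csv")
            paths["plate"] = outdir / "plate.csv"
        if self.patches is not None:
            _save("patches", self.patches)
        if self.calibration is not None:
            _save("calibration", self.calibration)
        if self.agar_truth is not None:
            _save("agar_truth", self.agar_truth)
        return paths


def generate_dataset(
    params: SimulationParams | None = None,
    seed: int = 0,
    include_od: bool = True,
    include_agar: bool = True,
) -> SyntheticDataset:
    """One fully synthetic study: design, true fitness, OD plates, agar assays."""
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    sim = simulate_fitness_table(params, rng)
    plate = (
        generate_od_curves(sim["fitness"], params, rng) if include_od else None
    )
    patches = calibration = agar_truth = None
    if include_agar:
        patches, calibration, agar_truth = generate_agar_assays(
            sim["truth_strains"], params, rng
        )
    return SyntheticDataset(
        params=params,
        seed=seed,
        metadata=sim["metadata"],
        crosses=sim["crosses"],
        divergence=sim["divergence"],
        fitness_true=sim["fitness"],
        truth_strains=sim["truth_strains"],
        plate=plate,
        patches=patches,
        calibration=calibration,
        agar_truth=agar_truth,
    )
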