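"""Recurrent genomic selection simulator for ordinal traits.

The engine reproduces an idealised breeding loop: a founder population of
diploid lines segregating at independent biallelic loci (allele frequency
0.5, followed by discrete generations of random mating), a multitrait
genetic architecture with marker effects drawn from a multivariate normal
whose correlation matrix induces the desired genetic correlations,
quantitative phenotypes discretised into ordered categories at fixed
tercile cutpoints, and selection cycles in which an ordinal probit model is
trained on 70% of the lines, the remaining 30% are scored by expected
divergence loss against a target pmf, the best 30% of candidates become
parents, and the next generation is produced as doubled-haploid (DH) lines
from random crosses.

Six standard scenarios E1..E6 combine three genetic correlation structures
(S1 positive, S2 antagonistic, S3 mixed) with two heritabilities (0.3,
0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .divergence import TargetSpec
from .ordinal import McmcSettings, OrdinalRidgeModel, PosteriorDraws
from .selection import multitrait_selection

__all__ = [
    "CORRELATION_STRUCTURES",
    "SCENARIOS",
    "Population",
    "TraitArchitecture",
    "ScenarioConfig",
    "CycleSummary",
    "simulate_founders",
    "build_architecture",
    "phenotype_and_discretize",
    "run_cycle",
    "run_scenario",
    "summaries_to_frame",
]

CORRELATION_STRUCTURES = {
    "S1": np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.2], [0.3, 0.2, 1.0]]),
    "S2": np.array([[1.0, -0.3, -0.2], [-0.3, 1.0, -0.35], [-0.2, -0.35, 1.0]]),
    "S3": np.array([[1.0, 0.5, -0.4], [0.5, 1.0, 0.3], [-0.4, 0.3, 1.0]]),
}

# scenario id -> (correlation structure, heritability)
SCENARIOS = {
    "E1": ("S1", 0.3),
    "E2": ("S1", 0.6),
    "E3": ("S2", 0.3),
    "E4": ("S2", 0.6),
    "E5": ("S3", 0.3),
    "E6": ("S3", 0.6),
}


@dataclass
class Population:
    """Diploid line population over independently segregating loci.

    ``genotypes`` holds dosages in {0, 1, 2}; DH populations contain only
    {0, 2} (fully homozygous).
    """

    genotypes: np.ndarray
    generation: int = 0
    lineage: Optional[np.ndarray] = None

    def __post_init__(self):
        G = np.asarray(self.genotypes)
        if G.ndim != 2:
            raise ValueError("genotypes must be an n x k matrix")
        if not np.isin(G, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        self.genotypes = G.astype(np.int8)
        if self.lineage is None:
            self.lineage = np.arange(G.shape[0])

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_dh(self) -> bool:
        return not np.any(self.genotypes == 1)

    def allele_frequencies(self) -> np.ndarray:
        return self.genotypes.mean(axis=0) / 2.0


@dataclass
class TraitArchitecture:
    """True genetic architecture of the simulated ordinal traits.

    ``effects`` (k x t) are allele-substitution effects; ``cutpoints``
    (t x (C-1)) are the phenotype-scale thresholds frozen at their founder
    (F0) values so category proportions stay comparable across cycles.
    ``env_sd`` is calibrated so the realised F0 heritability equals ``h2``
    exactly.
    """

    effects: np.ndarray
    h2: np.ndarray
    S_corr: np.ndarray
    env_sd: np.ndarray
    cutpoints: np.ndarray
    dosage_center: np.ndarray  # F0 mean dosage per locus; genetic values use centred dosages
    f0_phenotypes: Optional[np.ndarray] = None
    f0_categories: Optional[np.ndarray] = None

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]

    def genetic_values(self, pop: Population) -> np.ndarray:
        return (pop.genotypes - self.dosage_center) @ self.effects


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one recurrent-selection scenario."""

    scenario: str = "E2"
    n_loci: int = 5000
    founder_freq: float = 0.5
    burn_in_generations: int = 200
    pop_size: int = 2000
    n_traits: int = 3
    n_categories: int = 3
    n_cycles: int = 10
    train_fraction: float = 0.7
    selection_fraction: float = 0.3
    target: tuple = ((0.1, 0.2, 0.7),) * 3
    n_replicates: int = 20
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(50_000, 20_000, 5))
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {sorted(SCENARIOS)}")
        if not 0 < self.founder_freq < 1:
            raise ValueError("founder_freq must be in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0, 1]")
        if min(self.n_loci, self.pop_size, self.n_traits, self.n_cycles, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if len(self.target) != self.n_traits:
            raise ValueError("one target pmf per trait is required")
        ts = TargetSpec(tuple(np.asarray(t, float) for t in self.target))  # validates
        if any(c != self.n_categories for c in ts.n_categories):
            raise ValueError(
                f"target pmfs must have n_categories={self.n_categories} entries"
            )

    @property
    def structure(self) -> np.ndarray:
        return CORRELATION_STRUCTURES[SCENARIOS[self.scenario][0]]

    @property
    def h2(self) -> float:
        return SCENARIOS[self.scenario][1]

    @property
    def target_spec(self) -> TargetSpec:
        return TargetSpec(tuple(np.asarray(t, float) for t in self.target))

    @classmethod
    def full_scale(cls, scenario: str = "E2", seed: int = 0) -> "ScenarioConfig":
        """Full-scale configuration: 5,000 loci, 2,000 lines, 20 replicates."""
        return cls(scenario=scenario, seed=seed)

    @classmethod
    def reduced_scale(cls, scenario: str = "E2", seed: int = 0, **kw) -> "ScenarioConfig":
        """Desk-scale configuration: 500 loci, 400 lines/cycle, 3 replicates,
        4,000/1,500/5 chains.  Same scientific structure, minutes not days."""
        base = dict(
            scenario=scenario,
            n_loci=500,
            pop_size=400,
            burn_in_generations=100,
            n_replicates=3,
            mcmc=McmcSettings(4000, 1500, 5),
            seed=seed,
        )
        base.update(kw)
        return cls(**base)


@dataclass
class CycleSummary:
    """Realised category proportions of one population in one cycle."""

    cycle: int
    proportions: np.ndarray  # (t, C), rows sum to 1
    mean_loss_selected: float = np.nan
    replicate: int = 0
    method: str = "kl"
    scenario: str = ""

    def __post_init__(self):
        P = np.atleast_2d(np.asarray(self.proportions, dtype=float))
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("per-trait category proportions must sum to 1")
        self.proportions = P


# ----------------------------------------------------------------------
# founder genome


def _gametes(genotypes: np.ndarray, parent_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per requested parent; independent-locus meiosis.

    Each gamete allele is Bernoulli(dosage/2) per locus: homozygotes
    transmit their allele deterministically, heterozygotes a fair coin.
    """
    dos = genotypes[parent_idx]
    return (rng.random(dos.shape) < dos / 2.0).astype(np.int8)


def _distinct_pairs(n_parents: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """(n_pairs, 2) uniformly random pairs of distinct parent indices."""
    a = rng.integers(0, n_parents, size=n_pairs)
    b = rng.integers(0, n_parents - 1, size=n_pairs)
    b[b >= a] += 1  # uniform over the remaining n_parents - 1 indices
    return np.column_stack([a, b])


def random_mating_generation(pop: Population, rng: np.random.Generator,
                             n_offspring: Optional[int] = None) -> Population:
    """One discrete, non-overlapping generation of random mating."""
    n = n_offspring if n_offspring is not None else pop.n_lines
    pairs = _distinct_pairs(pop.n_lines, n, rng)
    child = _gametes(pop.genotypes, pairs[:, 0], rng) + _gametes(pop.genotypes, pairs[:, 1], rng)
    return Population(child, generation=pop.generation + 1)


def simulate_founders(cfg: ScenarioConfig, seed=None) -> Population:
    """Founder population: binomial(2, founder_freq) dosages followed by
    ``burn_in_generations`` of random mating."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = rng.binomial(2, cfg.founder_freq, size=(cfg.pop_size, cfg.n_loci)).astype(np.int8)
    pop = Population(G, generation=0)
    for _ in range(cfg.burn_in_generations):
        pop = random_mating_generation(pop, rng)
    return Population(pop.genotypes, generation=0)


# ----------------------------------------------------------------------
# genetic architecture


def build_architecture(cfg: ScenarioConfig, pop: Population, seed=None) -> TraitArchitecture:
    """Draw marker effects, calibrate environmental noise to the scenario
    heritability, and fix tercile cutpoints from realised F0 phenotypes.

    Effects are i.i.d. per locus from ``N_t(0, S_corr)`` (unit per-locus
    variance; only correlations and h2 matter after calibration).  The
    environmental standard deviation solves
    ``var(g) / (var(g) + env_sd^2) = h2`` in the realised F0 genetic
    values, and cutpoints sit at the empirical 1/C..(C-1)/C quantiles of
    the F0 phenotypes so each founder category holds ~1/C of the lines.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    S = np.asarray(cfg.structure, dtype=float)
    t = cfg.n_traits
    if S.shape != (t, t):
        raise ValueError("correlation structure does not match the trait count")
    if not np.allclose(S, S.T) or np.any(np.linalg.eigvalsh(S) <= 0):
        raise ValueError("S_corr must be symmetric positive-definite")
    L = np.linalg.cholesky(S)
    effects = rng.standard_normal((cfg.n_loci, t)) @ L.T

    center = pop.genotypes.mean(axis=0)
    g = (pop.genotypes - center) @ effects
    var_g = g.var(axis=0)
    h2 = float(cfg.h2)
    env_sd = np.sqrt(var_g * (1.0 - h2) / h2)

    pheno = g + rng.standard_normal(g.shape) * env_sd
    C = cfg.n_categories
    qs = np.arange(1, C) / C
    cutpoints = np.quantile(pheno, qs, axis=0).T  # (t, C-1)
    cats = _discretize(pheno, cutpoints)
    return TraitArchitecture(
        effects=effects,
        h2=np.full(t, h2),
        S_corr=S,
        env_sd=env_sd,
        cutpoints=cutpoints,
        dosage_center=center,
        f0_phenotypes=pheno,
        f0_categories=cats,
    )


def _discretize(pheno: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    """Half-open binning: category 1 iff p <= cut_1, c iff cut_{c-1} < p <= cut_c."""
    n, t = pheno.shape
    cats = np.empty((n, t), dtype=np.int64)
    for j in range(t):
        cats[:, j] = np.searchsorted(cutpoints[j], pheno[:, j], side="left") + 1
    return cats


def phenotype_and_discretize(pop: Population, arch: TraitArchitecture, seed=None,
                             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Fresh environmental noise on top of genetic values, then fixed-cutpoint
    binning.  Returns the n x t ordinal category matrix (codes 1..C)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    g = arch.genetic_values(pop)
    pheno = g + rng.standard_normal(g.shape) * arch.env_sd
    return _discretize(pheno, arch.cutpoints)


def category_proportions(cats: np.ndarray, n_categories: int) -> np.ndarray:
    """(t, C) matrix of category proportions from an n x t category matrix."""
    n, t = cats.shape
    out = np.empty((t, n_categories))
    for j in range(t):
        out[j] = np.bincount(cats[:, j], minlength=n_categories + 1)[1:] / n
    return out


# ----------------------------------------------------------------------
# cycle loop


def _fit_trait_draws(y: np.ndarray, X: np.ndarray, C: int, settings: McmcSettings) -> PosteriorDraws:
    """Fit one trait, tolerating categories absent from the training split.

    Unobserved categories get zero predictive mass: codes are compressed to
    the observed set, the model is fitted on the compressed scale, and the
    cutpoint draws are mapped back by inserting degenerate intervals
    (epsilon-width) at the missing categories so downstream pmfs keep
    length C with (numerically) zero probability there.
    """
    present = np.unique(y.astype(int))
    if present.size < 2:
        raise ValueError("training split has fewer than 2 observed categories")
    if present.size == C and present[0] == 1:
        return OrdinalRidgeModel(y, X, n_categories=C).fit(settings).draws

    remap = {c: i + 1 for i, c in enumerate(present)}
    y_c = np.array([remap[int(v)] for v in y])
    draws = OrdinalRidgeModel(y_c, X, n_categories=present.size).fit(settings).draws
    S = draws.n_draws
    thr_full = np.empty((S, C - 1))
    # map compressed cutpoints back to the full scale: a category never seen
    # in training gets a degenerate (epsilon-width) liability interval, i.e.
    # numerically zero predictive mass
    span = float(np.ptp(draws.thresholds)) + 1.0
    lo_pad = draws.thresholds[:, 0] - 10.0 * span
    hi_pad = draws.thresholds[:, -1] + 10.0 * span
    for c in range(1, C):  # gamma_c separates full-scale categories c and c+1
        n_below = int(np.searchsorted(present, c, side="right"))
        if n_below == 0:
            thr_full[:, c - 1] = lo_pad
        elif n_below == present.size:
            thr_full[:, c - 1] = hi_pad
        else:
            thr_full[:, c - 1] = draws.thresholds[:, n_below - 1]
    eps = 1e-8
    thr_full = np.maximum.accumulate(thr_full, axis=1) + eps * np.arange(C - 1)
    return PosteriorDraws(B=draws.B, thresholds=thr_full, x_mean=draws.x_mean)


RankerFn = Callable[[np.ndarray, np.ndarray, np.ndarray, "ScenarioConfig"], np.ndarray]


def run_cycle(
    pop: Population,
    arch: TraitArchitecture,
    cfg: ScenarioConfig,
    loss_method: str = "kl",
    seed=None,
    ranker: Optional[RankerFn] = None,
    replicate: int = 0,
) -> tuple:
    """One selection cycle; returns (next population, summary of ``pop``).

    Steps: phenotype and discretise; random 70/30 train/candidate split;
    per-trait ordinal probit fit on training rows; expected-loss ranking of
    candidates against the scenario target; top ``selection_fraction`` of
    candidates become parents; the next generation consists of
    ``pop_size`` DH lines, each from a single doubled gamete of an F1 of
    two distinct random parents.

    ``ranker`` (mainly for tests and controls) bypasses the Bayesian model:
    called as ``ranker(y_train, X_train, X_cand, cfg)`` it must return a
    loss-like score per candidate, low = good.
    """
    entropy = cfg.seed if seed is None else seed
    ss = entropy if isinstance(entropy, np.random.SeedSequence) else np.random.SeedSequence(entropy)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_pheno, rng_split, rng_fit, rng_mate = rngs

    cats = phenotype_and_discretize(pop, arch, rng=rng_pheno)
    n = pop.n_lines
    perm = rng_split.permutation(n)
    n_train = int(round(cfg.train_fraction * n))
    train_idx, cand_idx = perm[:n_train], perm[n_train:]
    if cand_idx.size < 2:
        raise ValueError("candidate pool too small; decrease train_fraction")
    X = pop.genotypes.astype(float)
    Xtr, Xcand = X[train_idx], X[cand_idx]

    mean_loss = np.nan
    if ranker is not None:
        score = np.asarray(ranker(cats[train_idx], Xtr, Xcand, cfg), dtype=float)
        order = np.argsort(score, kind="stable")
    else:
        fit_seeds = rng_fit.integers(0, 2**31 - 1, size=cfg.n_traits)
        draws = []
        for j in range(cfg.n_traits):
            settings = replace(cfg.mcmc, seed=int(fit_seeds[j]))
            try:
                draws.append(_fit_trait_draws(cats[train_idx, j], Xtr, cfg.n_categories, settings))
            except Exception as exc:
                raise RuntimeError(
                    f"model fit failed for trait {j + 1} in cycle {pop.generation} "
                    f"(replicate {replicate})"
                ) from exc
        result = multitrait_selection(
            Xcand, draws, target=cfg.target_spec, method=loss_method
        )
        order = np.argsort(result.ranking, kind="stable")

    n_sel = max(2, int(round(cfg.selection_fraction * cand_idx.size)))
    sel_local = order[:n_sel]
    if ranker is None:
        mean_loss = float(result.loss[sel_local].mean())
    parents = pop.genotypes[cand_idx[sel_local]]

    pairs = _distinct_pairs(parents.shape[0], cfg.pop_size, rng_mate)
    f1 = _gametes(parents, pairs[:, 0], rng_mate) + _gametes(parents, pairs[:, 1], rng_mate)
    dh = 2 * _gametes(f1, np.arange(cfg.pop_size), rng_mate)
    next_pop = Population(dh, generation=pop.generation + 1)

    summary = CycleSummary(
        cycle=pop.generation,
        proportions=category_proportions(cats, cfg.n_categories),
        mean_loss_selected=mean_loss,
        replicate=replicate,
        method=str(loss_method).lower(),
        scenario=cfg.scenario,
    )
    return next_pop, summary


def summarize_population(pop: Population, arch: TraitArchitecture, cfg: ScenarioConfig,
                         seed=None, replicate: int = 0, method: str = "kl") -> CycleSummary:
    """Phenotype, discretise and tabulate a population without selecting."""
    cats = phenotype_and_discretize(pop, arch, seed=seed)
    return CycleSummary(
        cycle=pop.generation,
        proportions=category_proportions(cats, cfg.n_categories),
        replicate=replicate,
        method=str(method).lower(),
        scenario=cfg.scenario,
    )


def run_scenario(
    cfg: ScenarioConfig,
    loss_method: str = "kl",
    ranker: Optional[RankerFn] = None,
    progress: bool = False,
    callback: Optional[Callable[[CycleSummary], None]] = None,
) -> list:
    """Full scenario: ``n_replicates`` independent runs of ``n_cycles`` cycles.

    Each replicate regenerates founders and architecture from its own seed
    stream (spawned from the master seed).  Returns the flat list of
    :class:`CycleSummary` (cycles 0..n_cycles per replicate; cycle c
    describes the population after c rounds of selection).  ``callback``
    receives each summary as soon as it exists, for incremental writing.
    """
    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.n_replicates)
    summaries: list = []

    def emit(s: CycleSummary):
        summaries.append(s)
        if callback is not None:
            callback(s)

    for rep, rep_ss in enumerate(rep_seeds):
        founder_ss, arch_ss, *cycle_ss = rep_ss.spawn(2 + cfg.n_cycles + 1)
        pop = simulate_founders(cfg, seed=founder_ss)
        arch = build_architecture(cfg, pop, seed=arch_ss)
        for c in range(cfg.n_cycles):
            pop, summ = run_cycle(
                pop, arch, cfg, loss_method=loss_method, seed=cycle_ss[c],
                ranker=ranker, replicate=rep,
            )
            emit(summ)
            if progress:
                p3 = summ.proportions[:, -1]
                print(
                    f"[{cfg.scenario} rep {rep}] cycle {summ.cycle}: "
                    f"top-category proportions {np.round(p3, 3)}"
                )
        emit(summarize_population(pop, arch, cfg, seed=cycle_ss[-1], replicate=rep,
                                  method=loss_method))
    return summaries


def summaries_to_frame(summaries: Sequence[CycleSummary]) -> pd.DataFrame:
    """Long-format table: scenario, replicate, cycle, method, trait, category,
    proportion, mean_loss_selected."""
    rows = []
    for s in summaries:
        t, C = s.proportions.shape
        for j in range(t):
            for c in range(C):
                rows.append(
                    {
                        "scenario": s.scenario,
                        "replicate": s.replicate,
                        "cycle": s.cycle,
                        "method": s.method,
                        "trait": j + 1,
                        "category": c + 1,
                        "proportion": s.proportions[j, c],
                        "mean_loss_selected": s.mean_loss_selected,
                    }
                )
    return pd.DataFrame(rows)


def mean_trajectory(df: pd.DataFrame, category: Optional[int] = None) -> pd.DataFrame:
    """Replicate-mean proportion per (cycle, trait, category)."""
    g = df.groupby(["cycle", "trait", "category"], as_index=False)["proportion"].mean()
    if category is not None:
        g = g[g["category"] == category].reset_index(drop=True)
    return g


def plot_trajectories(df: pd.DataFrame, target: Optional[Sequence[float]] = None, ax=None):
    """Replicate-mean category-proportion trajectories, one panel per trait."""
    import matplotlib.pyplot as plt

    traits = sorted(df["trait"].unique())
    cats = sorted(df["category"].unique())
    if ax is None:
        fig, axes = plt.subplots(1, len(traits), figsize=(4 * len(traits), 3), sharey=True)
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
        fig = axes[0].figure
    m = mean_trajectory(df)
    for a, tr in zip(axes, traits):
        sub = m[m["trait"] == tr]
        for c in cats:
            cc = sub[sub["category"] == c]
            a.plot(cc["cycle"], cc["proportion"], marker="o", ms=3, label=f"level {c}")
        if target is not None:
            for c, q in enumerate(target, start=1):
                a.axhline(q, ls="--", lw=0.8, color="red", alpha=0.5)
        a.set_xlabel("cycle")
        a.set_title(f"trait {tr}")
    axes[0].set_ylabel("population proportion")
    axes[-1].legend(fontsize=8)
    fig.tight_layout()
    return fig
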