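"""Random-sampling validation of divergence-based selection.

The harness mirrors a standard masking protocol for real breeding data: in
each replicate a random fraction of lines is treated as unphenotyped
candidates, per-trait ordinal probit models are trained on the remainder,
candidates are ranked by expected divergence loss against the breeder's
targets, and the TRUE (held-out) categories of the selected lines are
tabulated.  A same-size uniformly random selection provides the baseline.
Frequencies are aggregated as mean +/- sd across replicates.

A fixture generator emulates the shape of a wheat disease-resistance panel
(a few hundred lines, dosage markers, 4-5 category severity scores with
strongly skewed marginals) so the harness can run without any external
dataset; real (X, Y) matrices drop in unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .divergence import TargetSpec
from .ordinal import McmcSettings
from .selection import multitrait_selection, rank_candidates
from .simulate import _fit_trait_draws

__all__ = [
    "ValidationConfig",
    "FrequencyReport",
    "TraitFixtureSpec",
    "WHEAT_TRAIT_SPECS",
    "WHEAT_TARGETS",
    "random_sampling_validation",
    "make_wheat_like_fixture",
]

# Marginal category distributions typical of a multi-disease wheat panel
# (one 4-category trait, two 5-category traits with rare top scores),
# plus the matching skewed selection targets.


@dataclass(frozen=True)
class TraitFixtureSpec:
    """Marginal category proportions and heritability for one fixture trait."""

    marginals: tuple
    h2: float = 0.5

    def __post_init__(self):
        m = np.asarray(self.marginals, dtype=float)
        # tolerate rounded percentages that miss 1 by a little; renormalise
        if m.ndim != 1 or m.size < 2 or np.any(m < 0) or abs(m.sum() - 1) > 0.02:
            raise ValueError("marginals must be a pmf over >= 2 categories")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        object.__setattr__(self, "marginals", tuple(m / m.sum()))

    @property
    def n_categories(self) -> int:
        return len(self.marginals)


WHEAT_TRAIT_SPECS = (
    TraitFixtureSpec((0.5971, 0.1942, 0.1845, 0.0243), h2=0.5),
    TraitFixtureSpec((0.3738, 0.3859, 0.2184, 0.0194, 0.0024), h2=0.5),
    TraitFixtureSpec((0.4474, 0.4254, 0.1051, 0.0171, 0.0049), h2=0.5),
)

WHEAT_TARGETS = TargetSpec(
    (
        np.array([0.8, 0.1, 0.05, 0.05]),
        np.array([0.8, 0.1, 0.05, 0.025, 0.025]),
        np.array([0.8, 0.1, 0.05, 0.025, 0.025]),
    )
)


@dataclass(frozen=True)
class ValidationConfig:
    """Mask-train-select-compare protocol parameters."""

    targets: TargetSpec
    mask_fraction: float = 0.3
    n_select: int = 30
    n_replicates: int = 30
    methods: tuple = ("kl", "bhattacharyya", "hellinger")
    mcmc: McmcSettings = field(default_factory=lambda: McmcSettings(50_000, 20_000, 5))
    seed: int = 0
    max_redraws: int = 10

    def __post_init__(self):
        if not 0 < self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in (0, 1)")
        if self.n_select < 1 or self.n_replicates < 1:
            raise ValueError("n_select and n_replicates must be positive")
        if not isinstance(self.targets, TargetSpec):
            object.__setattr__(
                self, "targets", TargetSpec(tuple(np.asarray(t, float) for t in self.targets))
            )


@dataclass
class FrequencyReport:
    """Mean +/- sd selected-set category frequencies per method and trait.

    ``frame`` columns: method, trait, category, mean_freq, sd_freq,
    n_replicates.  ``predicted_frame`` repeats the tabulation on the
    model-predicted (rather than true held-out) categories, as a secondary
    diagnostic; it is None for the baseline-only case.
    """

    frame: pd.DataFrame
    predicted_frame: Optional[pd.DataFrame] = None
    per_replicate: Optional[pd.DataFrame] = None

    def mean_frequency(self, method: str, trait: int, category: int) -> float:
        f = self.frame
        row = f[(f["method"] == method) & (f["trait"] == trait) & (f["category"] == category)]
        if row.empty:
            raise KeyError(f"no entry for ({method}, trait {trait}, category {category})")
        return float(row["mean_freq"].iloc[0])

    def save(self, path: Union[str, Path], sep: str = "\t") -> None:
        self.frame.to_csv(path, sep=sep, index=False)

    def plot(self, trait: int = 1, ax=None):
        """Bar chart of mean category frequencies with sd error bars."""
        import matplotlib.pyplot as plt

        sub = self.frame[self.frame["trait"] == trait]
        methods = list(dict.fromkeys(sub["method"]))
        cats = sorted(sub["category"].unique())
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        w = 0.8 / len(methods)
        for i, m in enumerate(methods):
            mm = sub[sub["method"] == m].set_index("category")
            x = np.array(cats) + (i - (len(methods) - 1) / 2) * w
            ax.bar(x, mm.loc[cats, "mean_freq"], width=w,
                   yerr=mm.loc[cats, "sd_freq"], capsize=2, label=m)
        ax.set_xlabel("category")
        ax.set_ylabel("selected-set frequency")
        ax.set_title(f"trait {trait}")
        ax.legend(fontsize=8)
        return ax


def _tabulate(cats: np.ndarray, n_categories: Sequence[int]) -> np.ndarray:
    """Per-trait category frequencies of the selected lines, ragged -> list."""
    freqs = []
    for j, C in enumerate(n_categories):
        freqs.append(np.bincount(cats[:, j].astype(int), minlength=C + 1)[1:] / cats.shape[0])
    return freqs


RankerFn = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def random_sampling_validation(
    X, Y, cfg: ValidationConfig, ranker: Optional[RankerFn] = None, progress: bool = False,
) -> FrequencyReport:
    """Run the mask-train-select-compare protocol.

    Parameters
    ----------
    X
        n x k complete marker dosage matrix.
    Y
        n x t ordinal phenotype matrix, codes 1..C_j per trait.
    cfg
        Protocol parameters; ``cfg.targets`` must match Y's traits.
    ranker
        Optional stand-in for the Bayesian pipeline (tests/controls):
        ``ranker(Y_train, X_train, X_cand, Y_cand_true) -> score`` per
        candidate (low = good).  When given, it is used for every method
        label in ``cfg.methods``.

    Replicates whose training split lacks a category for some trait are
    re-drawn with a fresh seed (warned, up to ``cfg.max_redraws`` times
    each).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y))
    n, t = Y.shape
    if X.shape[0] != n:
        raise ValueError("X and Y must have the same number of lines")
    if cfg.targets.n_traits != t:
        raise ValueError(f"targets specify {cfg.targets.n_traits} traits, Y has {t}")
    n_cat = list(cfg.targets.n_categories)
    n_mask = int(round(cfg.mask_fraction * n))
    if cfg.n_select > n_mask:
        raise ValueError(f"n_select ({cfg.n_select}) exceeds masked count ({n_mask})")

    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = list(master.spawn(cfg.n_replicates))
    rows, pred_rows = [], []

    for rep, ss in enumerate(rep_seeds):
        freqs = None
        for attempt in range(cfg.max_redraws + 1):
            sub = ss.spawn(3)
            rng_mask = np.random.default_rng(sub[0])
            cand_idx = rng_mask.choice(n, size=n_mask, replace=False)
            train_mask = np.ones(n, dtype=bool)
            train_mask[cand_idx] = False
            ok = all(
                np.unique(Y[train_mask, j]).size >= 2 for j in range(t)
            )
            if ok:
                break
            warnings.warn(
                f"replicate {rep}: training split lacks categories, re-drawing "
                f"(attempt {attempt + 1})"
            )
            ss = ss.spawn(1)[0]
        else:
            raise RuntimeError(f"replicate {rep}: could not draw a valid training split")

        Xtr, Xcand = X[train_mask], X[cand_idx]
        Ytr, Ycand = Y[train_mask], Y[cand_idx]
        rng_base = np.random.default_rng(sub[1])

        if ranker is None:
            fit_seeds = np.random.default_rng(sub[2]).integers(0, 2**31 - 1, size=t)
            draws = []
            for j in range(t):
                settings = McmcSettings(
                    n_iter=cfg.mcmc.n_iter, burn_in=cfg.mcmc.burn_in, thin=cfg.mcmc.thin,
                    seed=int(fit_seeds[j]), prior_df=cfg.mcmc.prior_df,
                    prior_scale=cfg.mcmc.prior_scale, r2=cfg.mcmc.r2,
                )
                draws.append(_fit_trait_draws(Ytr[:, j].astype(float), Xtr, n_cat[j], settings))

        for method in cfg.methods:
            if ranker is None:
                res = multitrait_selection(Xcand, draws, target=cfg.targets, method=method)
                order = np.argsort(res.ranking, kind="stable")
                pred_sel = res.predicted_level[order[: cfg.n_select]]
            else:
                score = np.asarray(ranker(Ytr, Xtr, Xcand, Ycand), dtype=float)
                order = np.argsort(rank_candidates(score), kind="stable")
                pred_sel = None
            sel = order[: cfg.n_select]
            for j, fr in enumerate(_tabulate(Ycand[sel], n_cat)):
                for c, v in enumerate(fr):
                    rows.append(
                        {"method": method, "replicate": rep, "trait": j + 1,
                         "category": c + 1, "freq": v}
                    )
            if pred_sel is not None:
                for j, fr in enumerate(_tabulate(pred_sel, n_cat)):
                    for c, v in enumerate(fr):
                        pred_rows.append(
                            {"method": method, "replicate": rep, "trait": j + 1,
                             "category": c + 1, "freq": v}
                        )

        base_sel = rng_base.choice(n_mask, size=cfg.n_select, replace=False)
        for j, fr in enumerate(_tabulate(Ycand[base_sel], n_cat)):
            for c, v in enumerate(fr):
                rows.append(
                    {"method": "baseline", "replicate": rep, "trait": j + 1,
                     "category": c + 1, "freq": v}
                )
        if progress:
            print(f"validation replicate {rep + 1}/{cfg.n_replicates} done")

    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby(["method", "trait", "category"], as_index=False)["freq"]
        .agg(mean_freq="mean", sd_freq=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
    )
    agg["n_replicates"] = cfg.n_replicates
    pred_frame = None
    if pred_rows:
        pred_frame = (
            pd.DataFrame(pred_rows)
            .groupby(["method", "trait", "category"], as_index=False)["freq"]
            .agg(mean_freq="mean", sd_freq=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        )
    return FrequencyReport(frame=agg, predicted_frame=pred_frame, per_replicate=per_rep)


def make_wheat_like_fixture(
    n_lines: int = 403,
    n_markers: int = 500,
    trait_specs: Sequence[TraitFixtureSpec] = WHEAT_TRAIT_SPECS,
    seed: int = 0,
) -> tuple:
    """Synthetic marker/phenotype panel shaped like a wheat disease study.

    Markers are biallelic dosages with allele frequencies U(0.1, 0.5); each
    trait's liability is a genomic value (random marker effects) scaled to
    heritability ``h2`` plus unit-free environmental noise, and cutpoints
    are placed at the empirical liability quantiles of the requested
    marginal proportions, so realised marginals match the specs up to
    quantile granularity.

    Returns
    -------
    (X, Y): float (n, k) dosages and int (n, t) category codes 1..C_j.
    """
    rng = np.random.default_rng(seed)
    specs = [s if isinstance(s, TraitFixtureSpec) else TraitFixtureSpec(**s) for s in trait_specs]
    maf = rng.uniform(0.1, 0.5, size=n_markers)
    X = rng.binomial(2, maf, size=(n_lines, n_markers)).astype(float)
    Z = X - X.mean(axis=0)
    Y = np.empty((n_lines, len(specs)), dtype=int)
    for j, spec in enumerate(specs):
        if spec.h2 > 0:
            u = rng.standard_normal(n_markers)
            g = Z @ u
            sd = g.std()
            g = g / sd * np.sqrt(spec.h2) if sd > 0 else np.zeros(n_lines)
        else:
            g = np.zeros(n_lines)
        liab = g + rng.standard_normal(n_lines) * np.sqrt(1.0 - spec.h2)
        cum = np.cumsum(spec.marginals)[:-1]
        cuts = np.quantile(liab, cum)
        Y[:, j] = np.searchsorted(cuts, liab, side="left") + 1
        # guarantee every category appears at least once (rare categories in
        # small panels): move the closest lines across the empty boundary
        for c in range(1, spec.n_categories + 1):
            if not np.any(Y[:, j] == c):
                donor = np.argsort(np.abs(liab - np.quantile(liab, min(cum[min(c - 1, len(cum) - 1)], 1.0))))
                Y[donor[0], j] = c
    return X, Y
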