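"""Bayesian ordinal probit (threshold) regression with a Gaussian ridge prior.

The observed ordinal score ``y_i`` in ``{1..C}`` is modelled as the
categorised version of a latent liability ``l_i = x_i' beta + e_i`` with
``e_i ~ N(0, 1)``: ``y_i = c`` iff ``gamma_{c-1} < l_i <= gamma_c`` with
ordered cutpoints ``gamma_1 < ... < gamma_{C-1}`` (``gamma_0 = -inf``,
``gamma_C = +inf``).  Marker effects get a ridge prior
``beta_j ~ N(0, sigma_b^2)`` with a scaled-inverse-chi-square hyperprior on
``sigma_b^2``.  The residual (liability) variance is fixed at 1 and there is
no intercept; the thresholds absorb location.

Fitting is by Gibbs sampling with latent-variable augmentation:

* liabilities from truncated normals on their category interval
  (unconstrained for rows with missing response);
* ``beta`` from its Gaussian full conditional, drawn exactly via a thin SVD
  of the (centred) marker matrix so the per-iteration cost is O(nk);
* ``sigma_b^2`` from its scaled-inverse-chi-square full conditional;
* each cutpoint uniform between the largest liability in its lower category
  and the smallest liability in its upper category.

The model class follows the statsmodels convention: build
``OrdinalRidgeModel(y, X)`` then ``fit()`` to obtain an
``OrdinalRidgeResults`` carrying the MCMC draws, posterior summaries and
posterior-predictive machinery.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .divergence import CategoricalPMF

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "OrdinalRidgeModel",
    "OrdinalRidgeResults",
    "fit_ordinal_brr",
    "category_probabilities",
    "posterior_predictive",
    "prediction_metrics",
]

_U_EPS = 1e-14  # clip for uniform draws fed to the inverse normal CDF


@dataclass(frozen=True)
class McmcSettings:
    """Gibbs chain configuration.

    Defaults mirror common practice for whole-genome ordinal regression
    (50,000 iterations, 20,000 burn-in, thinning 5).  ``prior_df`` and
    ``prior_scale`` parameterise the scaled-inverse-chi-square hyperprior on
    the ridge variance; when ``prior_scale`` is None it is set from the data
    so that the prior mode of the implied genomic variance equals ``r2``
    of the liability variance.
    """

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_scale: Optional[float] = None
    r2: float = 0.5

    def __post_init__(self):
        if self.n_iter <= 0 or self.thin < 1 or self.burn_in < 0:
            raise ValueError("n_iter must be positive, thin >= 1, burn_in >= 0")
        if self.burn_in >= self.n_iter:
            raise ValueError(f"burn_in ({self.burn_in}) must be < n_iter ({self.n_iter})")
        if self.n_retained < 1:
            raise ValueError("settings retain no draws; decrease burn_in or thin")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must be in (0, 1)")

    @property
    def n_retained(self) -> int:
        """Number of retained draws: iterations > burn_in at thin spacing."""
        return self.n_iter // self.thin - self.burn_in // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of marker effects and cutpoints for one trait.

    ``B`` is S x k (draw s, marker j); ``thresholds`` is S x (C-1) with each
    row strictly increasing.  ``x_mean`` records the column centring applied
    to the training markers; prediction re-applies it.
    """

    B: np.ndarray
    thresholds: np.ndarray
    x_mean: Optional[np.ndarray] = None
    sigma2_b: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if self.B.shape[0] != self.thresholds.shape[0]:
            raise ValueError("B and thresholds must have the same number of draws")
        if self.B.shape[0] < 1:
            raise ValueError("need at least one retained draw")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("every thresholds row must be strictly increasing")

    @property
    def n_draws(self) -> int:
        return self.B.shape[0]

    @property
    def n_markers(self) -> int:
        return self.B.shape[1]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    # -- persistence ---------------------------------------------------
    # effects: either delimited text or a flat little-endian float64 binary
    # with a 2-int64 header (n_draws, n_markers); thresholds: whitespace-
    # delimited text, one retained draw per row.

    def save(self, prefix: Union[str, Path], effects_format: str = "txt") -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        if effects_format == "txt":
            np.savetxt(f"{prefix}_effects.txt", self.B)
        elif effects_format == "bin":
            with open(f"{prefix}_effects.bin", "wb") as fh:
                np.asarray(self.B.shape, dtype="<i8").tofile(fh)
                self.B.astype("<f8").tofile(fh)
        else:
            raise ValueError("effects_format must be 'txt' or 'bin'")
        np.savetxt(f"{prefix}_thresholds.txt", self.thresholds)
        if self.x_mean is not None:
            np.savetxt(f"{prefix}_xmean.txt", self.x_mean)

    @classmethod
    def load(cls, prefix: Union[str, Path]) -> "PosteriorDraws":
        prefix = Path(prefix)
        txt, binf = Path(f"{prefix}_effects.txt"), Path(f"{prefix}_effects.bin")
        if txt.exists():
            B = np.atleast_2d(np.loadtxt(txt))
        elif binf.exists():
            with open(binf, "rb") as fh:
                shape = np.fromfile(fh, dtype="<i8", count=2)
                B = np.fromfile(fh, dtype="<f8").reshape(shape)
        else:
            raise FileNotFoundError(f"no effects file found for prefix {prefix}")
        thr = np.atleast_2d(np.loadtxt(f"{prefix}_thresholds.txt"))
        xmean_path = Path(f"{prefix}_xmean.txt")
        x_mean = np.atleast_1d(np.loadtxt(xmean_path)) if xmean_path.exists() else None
        return cls(B=B, thresholds=thr, x_mean=x_mean)


def category_probabilities(eta, gamma) -> np.ndarray:
    """Category pmf(s) of the probit threshold model.

    ``p_c = Phi(gamma_c - eta) - Phi(gamma_{c-1} - eta)`` with
    ``gamma_0 = -inf`` and ``gamma_C = +inf``; the entries telescope to 1.

    Parameters
    ----------
    eta
        Scalar linear predictor or array of predictors.
    gamma
        Strictly increasing cutpoints, length C-1.

    Returns
    -------
    pmf array with shape ``eta.shape + (C,)`` (a length-C vector for scalar
    ``eta``).
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if gamma.ndim != 1 or gamma.size < 1:
        raise ValueError("gamma must be a 1-D vector of at least one cutpoint")
    if np.any(np.diff(gamma) <= 0):
        raise ValueError("gamma must be strictly increasing")
    eta_arr = np.asarray(eta, dtype=float)
    cdf = ndtr(gamma - eta_arr[..., None])  # shape (..., C-1)
    ones = np.ones_like(eta_arr, dtype=float)[..., None]
    zeros = np.zeros_like(ones)
    cum = np.concatenate([zeros, cdf, ones], axis=-1)
    return np.diff(cum, axis=-1)


def posterior_predictive(Xcand, draws: PosteriorDraws) -> np.ndarray:
    """Posterior-predictive category pmfs for candidate genotypes.

    For each retained draw ``s`` and candidate ``i`` computes the pmf
    ``category_probabilities(x_i' beta_s, gamma_s)``.

    Returns an array of shape (S, n, C).
    """
    X = np.atleast_2d(np.asarray(Xcand, dtype=float))
    if X.shape[1] != draws.n_markers:
        raise ValueError(
            f"Xcand has {X.shape[1]} markers but draws were fitted with {draws.n_markers}"
        )
    if draws.x_mean is not None:
        X = X - draws.x_mean
    eta = X @ draws.B.T  # (n, S)
    S, n, C = draws.n_draws, X.shape[0], draws.n_categories
    out = np.empty((S, n, C))
    for s in range(S):  # per-draw cutpoints differ; loop over S only
        out[s] = category_probabilities(eta[:, s], draws.thresholds[s])
    return out


def prediction_metrics(pmfs, y_true) -> dict:
    """Probabilistic accuracy of per-individual category pmfs.

    Parameters
    ----------
    pmfs
        (n, C) array of posterior-mean pmfs.
    y_true
        Observed categories coded 1..C.

    Returns
    -------
    dict with

    * ``brier`` — mean over individuals of ``sum_c (p_c - 1[y=c])^2``;
    * ``ranked_probability_score`` — mean of
      ``sum_{c<C} (P_c - 1[y<=c])^2`` on the cumulative scale (penalises
      mass far from the observed category in the ordering);
    * ``proportion_correct`` — fraction with ``argmax p = y`` (ties to the
      lowest category index).
    """
    P = np.atleast_2d(np.asarray(pmfs, dtype=float))
    y = np.asarray(y_true)
    n, C = P.shape
    if y.shape != (n,):
        raise ValueError(f"y_true length {y.shape} does not match {n} pmfs")
    if np.any((y < 1) | (y > C)) or not np.issubdtype(y.dtype, np.integer):
        y = y.astype(int)
        if np.any((y < 1) | (y > C)):
            raise ValueError(f"y_true codes must be integers in 1..{C}")
    onehot = np.zeros((n, C))
    onehot[np.arange(n), y - 1] = 1.0
    brier = float(np.mean(np.sum((P - onehot) ** 2, axis=1)))
    cumP = np.cumsum(P, axis=1)[:, :-1]
    cumO = np.cumsum(onehot, axis=1)[:, :-1]
    rps = float(np.mean(np.sum((cumP - cumO) ** 2, axis=1)))
    pred = np.argmax(P, axis=1) + 1  # argmax takes the first (lowest) on ties
    prop = float(np.mean(pred == y))
    return {
        "brier": brier,
        "ranked_probability_score": rps,
        "proportion_correct": prop,
    }


class OrdinalRidgeModel:
    """Whole-genome ordinal probit regression model.

    Parameters
    ----------
    y
        Length-n vector of category codes in 1..C; NaN (or values in a
        masked array) marks candidates with missing phenotype, which
        contribute no likelihood.
    X
        n x k marker dosage matrix, no missing values.  Columns are centred
        internally; the centring is stored and re-applied at prediction.
    n_categories
        Category count C; inferred as ``max(observed y)`` when omitted.

    Notes
    -----
    Every category 1..C must be observed at least once among the non-missing
    responses: the uniform cutpoint update needs both neighbouring
    categories occupied.
    """

    def __init__(self, y, X, n_categories: Optional[int] = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("X must be n x k with n >= 2, k >= 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if y.shape[0] != X.shape[0]:
            raise ValueError(f"y length {y.shape[0]} does not match X rows {X.shape[0]}")
        obs = np.isfinite(y)
        if obs.sum() < 2:
            raise ValueError("need at least 2 observed responses")
        yobs = y[obs]
        if np.any(yobs != np.round(yobs)) or np.any(yobs < 1):
            raise ValueError("observed y must be integer category codes >= 1")
        C = int(n_categories) if n_categories is not None else int(yobs.max())
        observed_cats = np.unique(yobs.astype(int))
        if observed_cats.size < 2:
            raise ValueError("need at least 2 distinct observed categories")
        missing_cats = sorted(set(range(1, C + 1)) - set(observed_cats.tolist()))
        if missing_cats:
            raise ValueError(
                f"categories {missing_cats} have no observations; every category "
                f"1..{C} must appear among the non-missing responses"
            )
        self.endog = y
        self.n_categories = C
        self.observed = obs
        self.x_mean = X.mean(axis=0)
        self.exog = X - self.x_mean
        self.nobs, self.n_markers = X.shape

    # -- prior scale ---------------------------------------------------
    def _default_prior_scale(self, settings: McmcSettings) -> float:
        # mode of scaled-inv-chi2(df, S) is S*df/(df+2); pick S so the mode
        # of the implied genomic variance sum_j var(x_j) * sigma_b^2 equals
        # r2/(1-r2) (the genetic variance when the residual variance is 1)
        msx = float(np.sum(self.exog.var(axis=0)))
        if msx <= 0:
            msx = float(self.n_markers)
        df = settings.prior_df
        return settings.r2 / (1.0 - settings.r2) / msx * (df + 2.0) / df

    def fit(
        self,
        settings: Optional[McmcSettings] = None,
        *,
        n_iter: Optional[int] = None,
        burn_in: Optional[int] = None,
        thin: Optional[int] = None,
        seed: Optional[int] = None,
        verbose: bool = False,
    ) -> "OrdinalRidgeResults":
        """Run the Gibbs sampler and return results with retained draws."""
        if settings is None:
            settings = McmcSettings()
        overrides = {
            k: v
            for k, v in dict(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed).items()
            if v is not None
        }
        if overrides:
            settings = replace(settings, **overrides)
        S0 = settings.prior_scale
        if S0 is None:
            S0 = self._default_prior_scale(settings)

        rng = np.random.default_rng(settings.seed)
        X = self.exog
        n, k = X.shape
        C = self.n_categories
        obs = self.observed
        y_obs = self.endog[obs].astype(int)

        # thin SVD once; beta full-conditional draws become O(nk)
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        V = Vt.T
        sv2 = sv**2

        # initial cutpoints from observed cumulative proportions
        props = np.bincount(y_obs, minlength=C + 1)[1:].astype(float)
        cum = np.cumsum(props / props.sum())[:-1]
        gamma = ndtri(np.clip(cum, 1e-3, 1 - 1e-3))
        gamma = np.maximum.accumulate(gamma)
        for c in range(1, C - 1):  # enforce strict order at init
            if gamma[c] <= gamma[c - 1]:
                gamma[c] = gamma[c - 1] + 1e-6

        beta = np.zeros(k)
        sigma2_b = S0 * settings.prior_df / (settings.prior_df + 2.0)
        eta = np.zeros(n)
        df_post = settings.prior_df + k

        # category interval bounds per observed row
        lo_idx = y_obs - 1  # gamma index of lower bound; 0 -> -inf
        hi_idx = y_obs  # gamma index of upper bound; C -> +inf

        n_ret = settings.n_retained
        B_out = np.empty((n_ret, k))
        thr_out = np.empty((n_ret, C - 1))
        s2_out = np.empty(n_ret)
        ell = np.zeros(n)

        s = 0
        for it in range(1, settings.n_iter + 1):
            # 1. latent liabilities
            bounds = np.concatenate(([-np.inf], gamma, [np.inf]))
            lo = bounds[lo_idx] - eta[obs]
            hi = bounds[hi_idx] - eta[obs]
            plo = ndtr(lo)
            phi = ndtr(hi)
            u = plo + rng.random(lo.shape[0]) * (phi - plo)
            z = ndtri(np.clip(u, _U_EPS, 1.0 - _U_EPS))
            z = np.clip(z, lo, hi)  # guard against CDF saturation far in a tail
            ell[obs] = eta[obs] + z
            n_miss = n - obs.sum()
            if n_miss:
                ell[~obs] = eta[~obs] + rng.standard_normal(n_miss)

            # 2. marker effects: N(C^-1 X'l, C^-1), C = X'X + I/sigma2_b
            lam = 1.0 / sigma2_b
            d = 1.0 / (sv2 + lam)
            m = V @ (d * (sv * (U.T @ ell)))
            zk = rng.standard_normal(k)
            coef = np.sqrt(d) - np.sqrt(1.0 / lam)
            beta = m + np.sqrt(1.0 / lam) * zk + V @ (coef * (V.T @ zk))
            eta = X @ beta

            # 3. ridge variance
            sigma2_b = (settings.prior_df * S0 + beta @ beta) / rng.chisquare(df_post)

            # 4. cutpoints, uniform between adjacent category extrema
            ell_obs = ell[obs]
            for c in range(1, C):
                a = np.max(ell_obs[y_obs == c])
                b = np.min(ell_obs[y_obs == c + 1])
                gamma[c - 1] = a + rng.random() * (b - a)

            if verbose and it % 1000 == 0:
                print(f"iter {it}/{settings.n_iter}")
            if it > settings.burn_in and it % settings.thin == 0:
                B_out[s] = beta
                thr_out[s] = gamma
                s2_out[s] = sigma2_b
                s += 1

        draws = PosteriorDraws(
            B=B_out,
            thresholds=thr_out,
            x_mean=self.x_mean.copy(),
            sigma2_b=s2_out,
            meta={
                "n_iter": settings.n_iter,
                "burn_in": settings.burn_in,
                "thin": settings.thin,
                "seed": settings.seed,
                "prior_df": settings.prior_df,
                "prior_scale": S0,
            },
        )
        return OrdinalRidgeResults(self, draws, settings)


class OrdinalRidgeResults:
    """Posterior draws plus summaries for a fitted ordinal ridge model."""

    def __init__(self, model: OrdinalRidgeModel, draws: PosteriorDraws, settings: McmcSettings):
        self.model = model
        self.draws = draws
        self.settings = settings

    @property
    def effects_mean(self) -> np.ndarray:
        return self.draws.B.mean(axis=0)

    @property
    def thresholds_mean(self) -> np.ndarray:
        return self.draws.thresholds.mean(axis=0)

    def predict_liability(self, X=None) -> np.ndarray:
        """Posterior-mean linear predictor for rows of ``X`` (default: training)."""
        if X is None:
            Xc = self.model.exog
        else:
            Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.model.x_mean
        return Xc @ self.effects_mean

    def predict_probs(self, X=None, reduce: str = "mean") -> np.ndarray:
        """Posterior-predictive category pmfs.

        ``reduce="draws"`` returns the full (S, n, C) array;
        ``reduce="mean"`` averages over draws to (n, C).
        """
        if X is None:
            X = self.model.exog + self.model.x_mean
        pp = posterior_predictive(X, self.draws)
        if reduce == "draws":
            return pp
        if reduce == "mean":
            return pp.mean(axis=0)
        raise ValueError("reduce must be 'mean' or 'draws'")

    def prediction_metrics(self, X=None, y_true=None) -> dict:
        """Brier score, ranked probability score and proportion correct."""
        if y_true is None:
            obs = self.model.observed
            y_true = self.model.endog[obs].astype(int)
            X = (self.model.exog + self.model.x_mean)[obs]
        return prediction_metrics(self.predict_probs(X), y_true)

    def threshold_interval(self, alpha: float = 0.10) -> np.ndarray:
        """Equal-tailed (1-alpha) credible intervals for the cutpoints, (C-1, 2)."""
        lo = np.quantile(self.draws.thresholds, alpha / 2, axis=0)
        hi = np.quantile(self.draws.thresholds, 1 - alpha / 2, axis=0)
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        """Plain-text posterior summary of cutpoints and the ridge variance."""
        thr = self.draws.thresholds
        rows = []
        for c in range(thr.shape[1]):
            col = thr[:, c]
            rows.append(
                (f"gamma_{c + 1}", col.mean(), col.std(ddof=1),
                 np.quantile(col, 0.05), np.quantile(col, 0.95))
            )
        if self.draws.sigma2_b is not None:
            s2 = self.draws.sigma2_b
            rows.append(("sigma2_b", s2.mean(), s2.std(ddof=1),
                         np.quantile(s2, 0.05), np.quantile(s2, 0.95)))
        tab = pd.DataFrame(rows, columns=["param", "mean", "sd", "q05", "q95"])
        buf = _io.StringIO()
        buf.write("Ordinal probit regression (ridge prior), Gibbs sampler\n")
        buf.write(
            f"n_obs={int(self.model.observed.sum())}  markers={self.model.n_markers}  "
            f"categories={self.model.n_categories}  draws={self.draws.n_draws}\n"
        )
        buf.write(tab.to_string(index=False, float_format=lambda v: f"{v: .4f}"))
        return buf.getvalue()


def fit_ordinal_brr(
    y, X, settings: Optional[McmcSettings] = None, n_categories: Optional[int] = None,
    **kwargs,
) -> OrdinalRidgeResults:
    """Convenience wrapper: build an :class:`OrdinalRidgeModel` and fit it."""
    return OrdinalRidgeModel(y, X, n_categories=n_categories).fit(settings, **kwargs)


def mean_pmf(pp: np.ndarray) -> np.ndarray:
    """Average an (S, n, C) posterior-predictive array over draws."""
    return np.asarray(pp).mean(axis=0)


def pmf_row(pp: np.ndarray, s: int, i: int) -> CategoricalPMF:
    """The pmf of candidate ``i`` under draw ``s`` as a :class:`CategoricalPMF`."""
    return CategoricalPMF(pp[s, i])
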