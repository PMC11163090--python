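"""Bayesian disproportionality: gamma-Poisson shrinkage (EBGM) and the IC.

Model
-----
For each drug-event pair with observed count ``n`` and expected count ``e``
(the product of the pair's margins over the grand total), the report-rate
ratio lambda follows DuMouchel's two-component gamma mixture prior

    lambda ~ p * Gamma(alpha1, beta1) + (1 - p) * Gamma(alpha2, beta2)

(shape/rate parameterization) and ``n | lambda ~ Poisson(lambda * e)``. The
marginal of ``n`` is then a mixture of two negative binomials, whose summed
log-likelihood over the whole grid is maximized to fit the five
hyperparameters. The posterior of lambda is again a two-component gamma
mixture with components Gamma(alpha_k + n, beta_k + e) and updated weights,
giving closed forms for the empirical Bayes geometric mean

    EBGM = 2 ** E[log2 lambda | n, e]

and numerically solved posterior quantiles EB05/EB95.

The information component uses the closed form IC = log2((n+0.5)/(e+0.5))
with credibility bounds from the Gamma(n+0.5, e+0.5) posterior — the
standard VigiBase-style formulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "GammaMixturePrior",
    "BayesResult",
    "DUMOUCHEL_INIT",
    "expected_counts",
    "pair_grid_from_cohort",
    "GammaPoissonShrinkage",
    "fit_hyperparameters",
    "ebgm",
    "ebgm_quantile",
    "ic",
    "compute_bayes",
    "save_prior",
    "load_prior",
]

_LOGIT_CLIP = 1e-6  # keeps the mixture weight strictly inside (0, 1)


@dataclass(frozen=True)
class GammaMixturePrior:
    """Five DuMouchel hyperparameters plus fit diagnostics."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    loglik: float = float("nan")
    converged: bool | None = None

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not (0 < self.p < 1):
            raise ValueError("mixture weight p must lie strictly in (0, 1)")

    @property
    def mixture_mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2

    @property
    def geometric_mean(self) -> float:
        """Prior geometric mean of lambda, exp(E[ln lambda])."""
        g1 = special.digamma(self.alpha1) - math.log(self.beta1)
        g2 = special.digamma(self.alpha2) - math.log(self.beta2)
        return math.exp(self.p * g1 + (1 - self.p) * g2)


#: DuMouchel's published starting values for the hyperparameter search.
DUMOUCHEL_INIT = GammaMixturePrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, p=1 / 3)


@dataclass(frozen=True)
class BayesResult:
    ebgm: float
    eb05: float
    eb95: float
    ic: float
    ic025: float
    ic975: float


# ---------------------------------------------------------------------------
# expected counts

def expected_counts(
    pairs: pd.DataFrame,
    strata: list[str] | None = None,
) -> pd.DataFrame:
    """Attach independence-model expected counts to a long drug x event grid.

    ``pairs`` needs columns ``drug``, ``event``, ``n``. The expectation for a
    pair is (row total x column total) / grand total, so that the expected
    counts sum to the observed grand total. With ``strata`` (additional
    grouping columns present in ``pairs``), expectations are computed within
    each stratum and summed over strata per pair.
    """
    required = {"drug", "event", "n"}
    if not required.issubset(pairs.columns):
        raise ValueError("pairs frame needs columns drug, event, n")
    if pairs["n"].sum() <= 0:
        raise ValueError("grand total of the pair grid is zero")

    def _e(group: pd.DataFrame) -> pd.Series:
        total = group["n"].sum()
        row = group.groupby("drug")["n"].transform("sum")
        col = group.groupby("event")["n"].transform("sum")
        return row * col / total

    out = pairs.copy()
    if strata:
        parts = []
        for _, group in out.groupby(strata, dropna=False):
            g = group.copy()
            g["_e"] = _e(g)
            parts.append(g)
        out = pd.concat(parts)
        out = (
            out.groupby(["drug", "event"], as_index=False)
            .agg(n=("n", "sum"), e=("_e", "sum"))
        )
    else:
        out["e"] = _e(out)
    return out.reset_index(drop=True)


def pair_grid_from_cohort(cohort: pd.DataFrame, strata: list[str] | None = None) -> pd.DataFrame:
    """Long (drug, event, n) counts from a cohort's PS drugs x PTs.

    Each report contributes one count per (PS drug, PT) combination — the
    usual one-row-per-drug-event convention for disproportionality grids.
    """
    records = []
    cols = list(strata) if strata else []
    for row in cohort.itertuples(index=False):
        extra = tuple(getattr(row, c) for c in cols)
        for d in sorted(row.ps_drugs):
            for pt in row.pts:
                records.append((d, pt) + extra)
    grid = pd.DataFrame(records, columns=["drug", "event"] + cols)
    counts = (
        grid.groupby(["drug", "event"] + cols, dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )
    return expected_counts(counts, strata=cols or None)


# ---------------------------------------------------------------------------
# marginal likelihood and fitting

def _log_nb(n, alpha, beta, e):
    """log of the negative-binomial marginal P(n | alpha, beta, e)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    return (
        special.gammaln(alpha + n)
        - special.gammaln(alpha)
        - special.gammaln(n + 1.0)
        + alpha * (np.log(beta) - np.log(beta + e))
        + n * (np.log(e) - np.log(beta + e))
    )


def _log_marginal(n, e, prior: GammaMixturePrior, weights=None):
    l1 = np.log(prior.p) + _log_nb(n, prior.alpha1, prior.beta1, e)
    l2 = np.log1p(-prior.p) + _log_nb(n, prior.alpha2, prior.beta2, e)
    ll = np.logaddexp(l1, l2)
    if weights is not None:
        ll = ll * np.asarray(weights, dtype=float)
    return ll


def _unpack(x) -> GammaMixturePrior:
    logit = float(np.clip(x[4], special.logit(_LOGIT_CLIP), special.logit(1 - _LOGIT_CLIP)))
    return GammaMixturePrior(
        alpha1=float(np.exp(x[0])),
        beta1=float(np.exp(x[1])),
        alpha2=float(np.exp(x[2])),
        beta2=float(np.exp(x[3])),
        p=float(special.expit(logit)),
    )


def _squash(n, e, bins: int):
    """Exact-weight aggregation of identical (n, e-bin) pairs.

    Pairs sharing a count and an expected-count bin contribute identical
    likelihood terms, so the objective can weight one representative instead
    of evaluating millions of duplicates. The e within a bin is replaced by
    the bin's weighted mean, which is exact in the limit of narrow bins.
    """
    df = pd.DataFrame({"n": np.asarray(n), "e": np.asarray(e, dtype=float)})
    df["bin"] = pd.cut(np.log(df["e"]), bins=bins, labels=False)
    g = df.groupby(["n", "bin"], as_index=False).agg(e=("e", "mean"), w=("e", "size"))
    return g["n"].to_numpy(float), g["e"].to_numpy(float), g["w"].to_numpy(float)


class GammaPoissonShrinkage:
    """Empirical-Bayes gamma-Poisson shrinker over a drug x event grid.

    sklearn-style estimator: construct with hyperparameter starting values,
    call :meth:`fit` with observed and expected counts, then read the fitted
    prior from the trailing-underscore attributes and score new pairs with
    :meth:`transform`.

    Parameters
    ----------
    alpha1, beta1, alpha2, beta2, p : float
        Starting values for the optimizer (DuMouchel's published defaults).
    tol : float
        Convergence tolerance on the successive max-abs change of the
        transformed parameter vector.
    max_iter : int
        Optimizer iteration cap; non-convergence warns and sets
        ``converged_ = False``, never fails silently.
    squash_bins : int or None
        When set, aggregate identical (n, e-bin) pairs with exact weights
        before optimizing — a performance trick for huge grids, off by
        default at desk scale.
    """

    def __init__(
        self,
        alpha1: float = DUMOUCHEL_INIT.alpha1,
        beta1: float = DUMOUCHEL_INIT.beta1,
        alpha2: float = DUMOUCHEL_INIT.alpha2,
        beta2: float = DUMOUCHEL_INIT.beta2,
        p: float = DUMOUCHEL_INIT.p,
        tol: float = 1e-6,
        max_iter: int = 500,
        squash_bins: int | None = None,
    ):
        self.alpha1 = alpha1
        self.beta1 = beta1
        self.alpha2 = alpha2
        self.beta2 = beta2
        self.p = p
        self.tol = tol
        self.max_iter = max_iter
        self.squash_bins = squash_bins

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha1": self.alpha1, "beta1": self.beta1,
            "alpha2": self.alpha2, "beta2": self.beta2, "p": self.p,
            "tol": self.tol, "max_iter": self.max_iter,
            "squash_bins": self.squash_bins,
        }

    def set_params(self, **params) -> "GammaPoissonShrinkage":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, n, e, sample_weight=None) -> "GammaPoissonShrinkage":
        """Maximize the summed negative-binomial-mixture log-likelihood.

        ``n`` and ``e`` are the observed and expected counts over the grid
        (at least two pairs with n > 0). Shapes/rates are optimized on the
        log scale and the weight on the logit scale; the weight is clipped
        strictly inside (0, 1) so degenerate boundary starts cannot crash.
        """
        n = np.asarray(n, dtype=float)
        e = np.asarray(e, dtype=float)
        if n.shape != e.shape:
            raise ValueError("n and e must have the same shape")
        if np.any(e <= 0):
            raise ValueError("expected counts must be positive")
        if int((n > 0).sum()) < 2:
            raise ValueError("need at least two pairs with n > 0 to fit")
        w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)
        if self.squash_bins and w is None:
            n, e, w = _squash(n, e, self.squash_bins)

        p0 = float(np.clip(self.p, _LOGIT_CLIP, 1 - _LOGIT_CLIP))
        x0 = np.array([
            np.log(self.alpha1), np.log(self.beta1),
            np.log(self.alpha2), np.log(self.beta2),
            special.logit(p0),
        ])

        def objective(x):
            prior = _unpack(x)
            return -float(np.sum(_log_marginal(n, e, prior, w)))

        bounds = [(-15.0, 15.0)] * 4 + [
            (special.logit(_LOGIT_CLIP), special.logit(1 - _LOGIT_CLIP))
        ]
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": self.tol},
        )
        prior = _unpack(res.x)
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"hyperparameter fit did not converge in {self.max_iter} "
                f"iterations: {res.message}",
                stacklevel=2,
            )
        self.prior_ = GammaMixturePrior(
            **{**asdict(prior), "loglik": -float(res.fun), "converged": converged}
        )
        self.alpha1_ = self.prior_.alpha1
        self.beta1_ = self.prior_.beta1
        self.alpha2_ = self.prior_.alpha2
        self.beta2_ = self.prior_.beta2
        self.p_ = self.prior_.p
        self.loglik_ = self.prior_.loglik
        self.converged_ = converged
        self.n_iter_ = int(res.nit)
        return self

    def transform(self, n, e, quantiles: bool = True) -> pd.DataFrame:
        """Per-pair EBGM (with EB05/EB95) and IC (with IC025/IC975)."""
        if not hasattr(self, "prior_"):
            raise AttributeError("estimator is not fitted; call fit() first")
        return score_pairs_bayes(n, e, self.prior_, quantiles=quantiles)

    def fit_transform(self, n, e, **kwargs) -> pd.DataFrame:
        return self.fit(n, e).transform(n, e, **kwargs)


def fit_hyperparameters(
    pairs: pd.DataFrame,
    init: GammaMixturePrior = DUMOUCHEL_INIT,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GammaMixturePrior:
    """Functional wrapper over :class:`GammaPoissonShrinkage` for a pair frame."""
    est = GammaPoissonShrinkage(
        alpha1=init.alpha1, beta1=init.beta1,
        alpha2=init.alpha2, beta2=init.beta2, p=init.p,
        tol=tol, max_iter=max_iter,
    )
    est.fit(pairs["n"].to_numpy(), pairs["e"].to_numpy())
    return est.prior_


# ---------------------------------------------------------------------------
# posterior summaries

def _posterior(n, e, prior: GammaMixturePrior):
    """Posterior mixture weight on component 1 and both gamma components."""
    l1 = np.log(prior.p) + _log_nb(n, prior.alpha1, prior.beta1, e)
    l2 = np.log1p(-prior.p) + _log_nb(n, prior.alpha2, prior.beta2, e)
    q1 = special.expit(l1 - l2)
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    return q1, (prior.alpha1 + n, prior.beta1 + e), (prior.alpha2 + n, prior.beta2 + e)


def ebgm(n, e, prior: GammaMixturePrior):
    """EBGM = 2**E[log2 lambda | n, e]; vectorized over n, e."""
    q1, (a1, b1), (a2, b2) = _posterior(n, e, prior)
    mean_ln = q1 * (special.digamma(a1) - np.log(b1)) + (1 - q1) * (
        special.digamma(a2) - np.log(b2)
    )
    return np.exp(mean_ln)


def ebgm_quantile(n, e, prior: GammaMixturePrior, q: float, tol: float = 1e-8):
    """Posterior quantile of lambda, solved to |delta lambda| < tol.

    The posterior CDF is the weighted sum of the two gamma component CDFs;
    the quantile is bracketed by the component quantiles and solved with
    Brent's method. Vectorized over n, e (scalar q).
    """
    q1, (a1, b1), (a2, b2) = _posterior(n, e, prior)
    q1 = np.atleast_1d(np.asarray(q1, dtype=float))
    a1, b1, a2, b2 = (np.atleast_1d(np.asarray(x, dtype=float)) for x in (a1, b1, a2, b2))
    out = np.empty(q1.shape)
    for i in np.ndindex(q1.shape):
        w = q1[i]
        lo1 = stats.gamma.ppf(q, a=a1[i], scale=1 / b1[i])
        lo2 = stats.gamma.ppf(q, a=a2[i], scale=1 / b2[i])
        # pad the component-quantile bracket so rounding at an endpoint that
        # coincides with the root cannot leave both ends on the same side
        lo = 0.999 * min(lo1, lo2)
        hi = 1.001 * max(lo1, lo2) + 1e-12

        def cdf(x):
            return (
                w * stats.gamma.cdf(x, a=a1[i], scale=1 / b1[i])
                + (1 - w) * stats.gamma.cdf(x, a=a2[i], scale=1 / b2[i])
                - q
            )

        # scale-aware absolute tolerance: roots can sit many orders of
        # magnitude below 1 (tiny lower quantiles at n = 0), where a fixed
        # xtol would stop before any digits are correct
        xtol = max(tol * min(lo1, lo2), 1e-300)
        if hi - lo < xtol:
            out[i] = 0.5 * (lo + hi)
        else:
            out[i] = optimize.brentq(cdf, lo, hi, xtol=xtol, rtol=1e-12)
    return out if out.size > 1 else float(out.ravel()[0])


def ic(n, e):
    """Information component with 95% credibility bounds.

    IC = log2((n + 0.5)/(e + 0.5)); IC025/IC975 are log2 of the 2.5th and
    97.5th percentiles of Gamma(shape = n + 0.5, rate = e + 0.5).
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    point = np.log2((n + 0.5) / (e + 0.5))
    shape = n + 0.5
    scale = 1.0 / (e + 0.5)
    lo = np.log2(stats.gamma.ppf(0.025, a=shape, scale=scale))
    hi = np.log2(stats.gamma.ppf(0.975, a=shape, scale=scale))
    return point, lo, hi


def score_pairs_bayes(n, e, prior: GammaMixturePrior, quantiles: bool = True) -> pd.DataFrame:
    """Frame with columns ebgm, eb05, eb95, ic, ic025, ic975 for each pair."""
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    e_arr = np.atleast_1d(np.asarray(e, dtype=float))
    g = np.atleast_1d(ebgm(n_arr, e_arr, prior))
    point, lo, hi = ic(n_arr, e_arr)
    out = pd.DataFrame({
        "ebgm": g,
        "ic": np.atleast_1d(point),
        "ic025": np.atleast_1d(lo),
        "ic975": np.atleast_1d(hi),
    })
    if quantiles:
        out["eb05"] = np.atleast_1d(ebgm_quantile(n_arr, e_arr, prior, 0.05))
        out["eb95"] = np.atleast_1d(ebgm_quantile(n_arr, e_arr, prior, 0.95))
    else:
        out["eb05"] = np.nan
        out["eb95"] = np.nan
    return out[["ebgm", "eb05", "eb95", "ic", "ic025", "ic975"]]


def compute_bayes(n: float, e: float, prior: GammaMixturePrior) -> BayesResult:
    """All Bayesian indices for a single pair."""
    row = score_pairs_bayes(n, e, prior, quantiles=True).iloc[0]
    return BayesResult(
        ebgm=float(row["ebgm"]), eb05=float(row["eb05"]), eb95=float(row["eb95"]),
        ic=float(row["ic"]), ic025=float(row["ic025"]), ic975=float(row["ic975"]),
    )


# ---------------------------------------------------------------------------
# serialization

def save_prior(prior: GammaMixturePrior, path) -> None:
    """Serialize a fitted prior as a flat key=value text file."""
    lines = [f"{k}={v!r}" for k, v in asdict(prior).items()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_prior(path) -> GammaMixturePrior:
    values: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            values[key.strip()] = raw.strip()
    kwargs = {
        k: float(values[k]) for k in ("alpha1", "beta1", "alpha2", "beta2", "p", "loglik")
        if k in values
    }
    if "converged" in values:
        kwargs["converged"] = values["converged"] in {"True", "true", "1"}
    return GammaMixturePrior(**kwargs)
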