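"""Phylogenetic comparative statistics for the calcaneal-lever dataset.

Implements, from first principles on top of the covariance machinery in
:mod:`footlever.phylo`:

* **PGLS with Pagel's lambda** — generalized least squares with
  covariance ``sigma^2 * C_lambda``; lambda is profiled by maximum
  likelihood (analytic GLS beta-hat and sigma-hat at each lambda,
  bounded scalar search on [0, 1]).  Used for the regression
  theta_obs = beta0 + beta1 * theta_est + beta2 * ln(body mass).
* **Simulation-based phylogenetic ANOVA** — the classical one-way F is
  referred to a null distribution of F statistics computed on traits
  simulated under Brownian motion on the tree (rate fitted to the data
  by ML); pairwise two-sample t statistics get simulation p-values the
  same way, Holm-adjusted.
* **Holm step-down adjustment** and **tie-corrected Spearman rank
  correlation** (midranks; p from the t approximation with n - 2 df, or
  exact permutation for very small n).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy import stats as sps

from .phylo import apply_lambda, shared_path_matrix

__all__ = [
    "RegressionCoefficients",
    "PGLSFit",
    "PhyANOVAResult",
    "pgls_fit",
    "apply_regression",
    "group_difference_summary",
    "phy_anova",
    "holm_adjust",
    "spearman_correlation",
]


@dataclass(frozen=True)
class RegressionCoefficients:
    """Coefficients of theta_obs = beta0 + beta1 * theta_est + beta2 * ln(body mass)."""

    beta0: float  # degrees
    beta1: float  # degrees per degree of theta_est
    beta2: float  # degrees per ln-gram

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.beta0, self.beta1, self.beta2))):
            raise ValueError("coefficients must be finite")


def apply_regression(
    coef: RegressionCoefficients, theta_est: float, ln_body_mass: float
) -> float:
    """Predicted observed angle (theta_r-obs) from theta_est and ln body mass."""
    return coef.beta0 + coef.beta1 * np.asarray(theta_est) + coef.beta2 * np.asarray(ln_body_mass)


@dataclass(frozen=True)
class PGLSFit:
    """A lambda-GLS regression fit."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_hat: float
    log_likelihood: float
    sigma2: float
    r_squared: float
    r_squared_adj: float
    model_f: float
    model_p: float
    n: int
    names: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "std_error": self.std_errors,
                "t_value": self.t_values,
                "p_value": self.p_values,
            },
            index=list(self.names),
        )


def _gls_profile(C: np.ndarray, y: np.ndarray, X: np.ndarray, lam: float):
    """GLS at fixed lambda: returns (beta, rss, logdet, Xw, resid_w, L)."""
    V = apply_lambda(C, lam)
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            f"phylogenetic covariance not positive definite at lambda={lam:.6g} "
            f"(condition number {np.linalg.cond(V):.3g})"
        ) from exc
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, Xw, resid, L


def _loglik(n: int, rss: float, logdet: float) -> float:
    sigma2 = rss / n
    return -0.5 * (n * math.log(2.0 * math.pi) + n * math.log(sigma2) + logdet + n)


def pgls_fit(
    y: Sequence[float],
    X: np.ndarray,
    tree: dendropy.Tree,
    taxa: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
    add_intercept: bool = True,
    lam: float | None = None,
) -> PGLSFit:
    """Fit a PGLS regression, estimating Pagel's lambda by profile ML.

    Parameters
    ----------
    y, X
        Response vector and predictor matrix, rows aligned with ``taxa``
        (or with the tree's tip order when ``taxa`` is None).
    tree
        Rooted ultrametric tree with branch lengths covering all taxa.
    names
        Coefficient labels for the summary table.
    add_intercept
        Prepend a column of ones (default).
    lam
        Fix lambda instead of estimating it (``lam=0`` reduces the fit
        to ordinary least squares).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        if names is not None:
            names = ["intercept", *names]
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have different numbers of rows")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("predictor matrix is rank deficient (singular design)")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    _, C = shared_path_matrix(tree, list(taxa) if taxa is not None else None)
    if C.shape[0] != n:
        raise ValueError(f"tree has {C.shape[0]} tips but data has {n} rows")

    if lam is None:

        def nll(l: float) -> float:
            _, rss_l, logdet_l, *_ = _gls_profile(C, y, X, l)
            return -_loglik(n, rss_l, logdet_l)

        res = optimize.minimize_scalar(
            nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
        )
        lam_hat = float(res.x)
        # the bounded optimizer never evaluates the exact endpoints; check them
        cand = [lam_hat, 0.0, 1.0]
        lls = []
        for l in cand:
            _, rss_l, logdet_l, *_ = _gls_profile(C, y, X, l)
            lls.append(_loglik(n, rss_l, logdet_l))
        lam_hat = cand[int(np.argmax(lls))]
    else:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        lam_hat = float(lam)

    beta, rss, logdet, Xw, _, L = _gls_profile(C, y, X, lam_hat)
    ll = _loglik(n, rss, logdet)
    sigma2 = rss / (n - p)  # unbiased, used for the Wald table
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=n - p)

    # R^2 against the GLS intercept-only model at the same lambda
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    mu = float(ones_w @ yw / (ones_w @ ones_w))
    rss0 = float(np.sum((yw - mu * ones_w) ** 2))
    r2 = 1.0 - rss / rss0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if p > 1:
        f = (rss0 - rss) / (p - 1) / (rss / (n - p))
        model_p = float(sps.f.sf(f, p - 1, n - p))
    else:
        f, model_p = float("nan"), float("nan")

    if names is None:
        names = [f"b{i}" for i in range(p)]
    return PGLSFit(
        coefficients=beta,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        lambda_hat=lam_hat,
        log_likelihood=ll,
        sigma2=sigma2,
        r_squared=r2,
        r_squared_adj=r2_adj,
        model_f=float(f),
        model_p=model_p,
        n=n,
        names=tuple(names),
    )


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA


@dataclass(frozen=True)
class PhyANOVAResult:
    f_statistic: float
    p_simulated: float
    n_simulations: int
    groups: tuple[str, ...]
    pairwise_adjusted_p: pd.DataFrame
    pairwise_t: pd.DataFrame


def _anova_f(T: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F for each column of T; groups given by row-index arrays."""
    n = T.shape[0]
    k = len(idx)
    grand = T.mean(axis=0)
    ssb = np.zeros(T.shape[1])
    ssw = np.zeros(T.shape[1])
    for ix in idx:
        g = T[ix]
        gm = g.mean(axis=0)
        ssb += len(ix) * (gm - grand) ** 2
        ssw += ((g - gm) ** 2).sum(axis=0)
    return (ssb / (k - 1)) / (ssw / (n - k))


def _pairwise_t(T: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """Pooled-variance two-sample t for each group pair (rows) and column of T."""
    k = len(idx)
    pairs = list(itertools.combinations(range(k), 2))
    out = np.empty((len(pairs), T.shape[1]))
    means = [T[ix].mean(axis=0) for ix in idx]
    sqs = [((T[ix] - T[ix].mean(axis=0)) ** 2).sum(axis=0) for ix in idx]
    for r, (a, b) in enumerate(pairs):
        na, nb = len(idx[a]), len(idx[b])
        sp2 = (sqs[a] + sqs[b]) / (na + nb - 2)
        out[r] = (means[a] - means[b]) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return out


def _bm_ml_estimates(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """ML root state and BM rate of a trait on covariance C."""
    L = linalg.cholesky(C, lower=True)
    xw = linalg.solve_triangular(L, x, lower=True)
    ones_w = linalg.solve_triangular(L, np.ones(len(x)), lower=True)
    mu = float(ones_w @ xw / (ones_w @ ones_w))
    sigma2 = float(np.sum((xw - mu * ones_w) ** 2)) / len(x)
    return mu, sigma2


def phy_anova(
    trait: Sequence[float],
    groups: Sequence[str],
    tree: dendropy.Tree,
    n_sim: int = 1000,
    seed: int | None = None,
    taxa: Sequence[str] | None = None,
    min_group_size: int = 1,
) -> PhyANOVAResult:
    """Phylogenetic ANOVA: F referred to a Brownian-motion simulation null.

    The BM rate is estimated from the observed trait by ML on the tree's
    shared-path covariance; ``n_sim`` trait sets are simulated under
    that model, the one-way F (and each pairwise pooled t) is recomputed
    on each, and p = (1 + #{|stat_sim| >= |stat_obs|}) / (1 + n_sim).
    Pairwise p-values are Holm-adjusted.  Groups smaller than
    ``min_group_size`` are dropped with a warning.
    """
    trait = np.asarray(trait, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if len(trait) != len(groups):
        raise ValueError("trait and groups must have the same length")
    taxa = list(taxa) if taxa is not None else None
    _, C = shared_path_matrix(tree, taxa)
    if C.shape[0] != len(trait):
        raise ValueError("trait length does not match number of tree tips")

    labels = [g for g in dict.fromkeys(groups)]  # preserve order
    keep = np.ones(len(trait), dtype=bool)
    kept_labels = []
    for g in labels:
        size = int((groups == g).sum())
        if size == 0:
            raise ValueError(f"group {g!r} has no tips")
        if size < min_group_size:
            warnings.warn(
                f"dropping group {g!r} with {size} tip(s) < min_group_size={min_group_size}",
                stacklevel=2,
            )
            keep &= groups != g
        else:
            kept_labels.append(g)
    if len(kept_labels) < 2:
        raise ValueError("need at least two groups after size filtering")
    trait = trait[keep]
    groups = groups[keep]
    C = C[np.ix_(keep, keep)]
    idx = [np.flatnonzero(groups == g) for g in kept_labels]

    f_obs = float(_anova_f(trait[:, None], idx)[0])
    t_obs = _pairwise_t(trait[:, None], idx)[:, 0]

    mu, sigma2 = _bm_ml_estimates(C, trait)
    rng = np.random.default_rng(seed)
    L = linalg.cholesky(C, lower=True)
    sims = mu + math.sqrt(sigma2) * (L @ rng.standard_normal((len(trait), n_sim)))
    f_sim = _anova_f(sims, idx)
    t_sim = _pairwise_t(sims, idx)

    p_sim = (1 + int((f_sim >= f_obs).sum())) / (1 + n_sim)
    pair_p = (1 + (np.abs(t_sim) >= np.abs(t_obs)[:, None]).sum(axis=1)) / (1 + n_sim)
    pair_adj = holm_adjust(pair_p)

    k = len(kept_labels)
    P = pd.DataFrame(np.full((k, k), np.nan), index=kept_labels, columns=kept_labels)
    T = P.copy()
    for (a, b), padj, t in zip(itertools.combinations(range(k), 2), pair_adj, t_obs):
        P.iloc[a, b] = P.iloc[b, a] = padj
        T.iloc[a, b] = T.iloc[b, a] = t
    return PhyANOVAResult(
        f_statistic=f_obs,
        p_simulated=float(p_sim),
        n_simulations=n_sim,
        groups=tuple(kept_labels),
        pairwise_adjusted_p=P,
        pairwise_t=T,
    )


# ---------------------------------------------------------------------------
# Generic test utilities


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with midrank tie handling.

    rho is the Pearson correlation of average ranks.  ``method='t'``
    (default) takes the two-sided p from t = rho * sqrt((n-2)/(1-rho^2))
    on n - 2 df; ``method='exact'`` enumerates all permutations of one
    rank vector (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        return rho, min(p, 1.0)
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        # only the cross term sum(rx_perm * ry) varies across permutations
        obs = float(rx @ ry)
        mx, sx = rx.mean(), rx.std()
        my, sy = ry.mean(), ry.std()
        denom = n * sx * sy
        count = 0
        total = 0
        for perm in itertools.permutations(rx):
            r = (float(np.dot(perm, ry)) - n * mx * my) / denom
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Table-6 style group summaries


def group_difference_summary(
    records: Sequence,
    theta_r_obs: Mapping[str, float] | Sequence[float],
    mass_cutoff: float = 10_000.0,
) -> pd.DataFrame:
    """Signed mean angle differences for species below vs at/above a mass cutoff.

    ``records`` are :class:`footlever.datasets.SpeciesRecord`-like objects
    (attributes species_id, theta_obs, theta_est, body_mass in grams);
    ``theta_r_obs`` gives the regression-predicted observed angle per
    species.  Returns one row per group ('below'/'above') with the group
    size and the means of (theta_obs - theta_est) and
    (theta_obs - theta_r_obs); an empty group yields NaN means.
    """
    if not (mass_cutoff > 0):
        raise ValueError("mass_cutoff must be positive")
    if not isinstance(theta_r_obs, Mapping):
        theta_r_obs = {r.species_id: v for r, v in zip(records, theta_r_obs)}
    rows = []
    for name, sel in (
        ("below", lambda r: r.body_mass < mass_cutoff),
        ("above", lambda r: r.body_mass >= mass_cutoff),
    ):
        grp = [r for r in records if sel(r)]
        if grp:
            d_est = float(np.mean([r.theta_obs - r.theta_est for r in grp]))
            d_robs = float(np.mean([r.theta_obs - theta_r_obs[r.species_id] for r in grp]))
        else:
            warnings.warn(f"mass group {name!r} is empty at cutoff {mass_cutoff} g", stacklevel=2)
            d_est = d_robs = float("nan")
        rows.append(
            {
                "group": name,
                "n": len(grp),
                "mean_theta_obs_minus_theta_est": d_est,
                "mean_theta_obs_minus_theta_r_obs": d_robs,
            }
        )
    return pd.DataFrame(rows).set_index("group")
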