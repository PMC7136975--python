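"""MLPE mixed models for pairwise distance data, with model selection.

The maximum-likelihood-population-effects (MLPE) model regresses a
pairwise response (genetic distance between sites i and j) on pairwise
predictors while absorbing the non-independence of pairs that share a
site:

    y_ij = X_ij beta + u_i + u_j + eps_ij,
    u_k ~ N(0, sigma_u^2),  eps_ij ~ N(0, sigma_e^2),

i.e. ``y = X beta + Z u + eps`` with Z the pairs-by-sites incidence matrix
carrying two unit loadings per row.  Estimation profiles the likelihood
over the variance ratio ``theta = sigma_u^2 / sigma_e^2``: the covariance
is ``sigma_e^2 (I + theta Z Z')``, ``Z Z'`` is eigendecomposed once per
pair universe, and for each theta the GLS beta and the closed-form
sigma_e^2 follow directly.  Both ML (for AIC-based selection) and REML
(for variance-component reporting) criteria are supported.

Also here: Box-Cox normalisation of the response, iterative VIF pruning,
exhaustive submodel dredging under a pairwise-correlation cap, Nakagawa
marginal/conditional R-squared, the model-implied shared-site dependency
rho, and a permutation Moran's I check for residual spatial
autocorrelation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sites import SiteSet, pair_index

__all__ = [
    "BoxCoxResult",
    "boxcox",
    "vif_prune",
    "MLPEFit",
    "fit_mlpe",
    "dredge",
    "r2_nakagawa",
    "dependency_rho",
    "residual_autocorrelation",
    "incidence_matrix",
    "scale_columns",
]


# ---------------------------------------------------------------- Box-Cox

@dataclass
class BoxCoxResult:
    """Box-Cox power transform of a response: lambda, shift, transformed values."""

    lam: float
    shift: float
    transformed: np.ndarray


def boxcox(y: np.ndarray, lam_grid: np.ndarray | None = None,
           eps: float = 1e-6) -> BoxCoxResult:
    """Grid-search Box-Cox transform maximizing the profile log-likelihood.

    A shift ``max(0, eps - min(y))`` makes the data strictly positive;
    lambda is searched on [-2, 2] in steps of 0.01.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(y) == 0.0:
        raise ValueError("constant response cannot be transformed")
    shift = max(0.0, eps - float(y.min()))
    ys = y + shift
    if lam_grid is None:
        lam_grid = np.round(np.arange(-2.0, 2.0 + 1e-12, 0.01), 10)
    llf = np.array([stats.boxcox_llf(l, ys) for l in lam_grid])
    lam = float(lam_grid[int(np.argmax(llf))])
    if lam == 0.0:
        z = np.log(ys)
    else:
        z = (ys ** lam - 1.0) / lam
    return BoxCoxResult(lam, shift, z)


# ---------------------------------------------------------------- VIF

def vif_prune(X: pd.DataFrame, threshold: float = 10.0
              ) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF column until all VIFs < threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the others (with
    intercept); perfect collinearity counts as infinite.  Ties drop the
    later column.  Returns the retained frame and a removal log of
    ``(column, vif_at_removal)``.
    """
    X = X.copy()
    if X.shape[1] < 2:
        return X, []
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than predictors for VIF")
    removed: list[tuple[str, float]] = []
    while X.shape[1] >= 2:
        vifs = _vifs(X.to_numpy(dtype=float))
        worst = int(np.max(np.nonzero(vifs == vifs.max())[0]))  # tie -> later col
        if vifs[worst] < threshold:
            break
        removed.append((X.columns[worst], float(vifs[worst])))
        X = X.drop(columns=X.columns[worst])
    return X, removed


def _vifs(A: np.ndarray) -> np.ndarray:
    n, p = A.shape
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = A[:, j]
        Xo = np.hstack([ones, np.delete(A, j, axis=1)])
        beta, res, rank, _ = np.linalg.lstsq(Xo, yj, rcond=None)
        fitted = Xo @ beta
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        ss_res = ((yj - fitted) ** 2).sum()
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def scale_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Standardize columns to zero mean, unit (sample) standard deviation."""
    Xs = X.astype(float).copy()
    for c in Xs.columns:
        sd = Xs[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"predictor {c!r} has zero or non-finite variance")
        Xs[c] = (Xs[c] - Xs[c].mean()) / sd
    return Xs


# ---------------------------------------------------------------- MLPE fit

def incidence_matrix(pairs: list[tuple[str, str]], sites: SiteSet) -> np.ndarray:
    """Pairs-by-sites incidence matrix Z with two unit entries per row."""
    idx = {s: k for k, s in enumerate(sites.site_ids)}
    Z = np.zeros((len(pairs), sites.n))
    for r, (a, b) in enumerate(pairs):
        Z[r, idx[a]] = 1.0
        Z[r, idx[b]] = 1.0
    return Z


@dataclass
class PairStructure:
    """Eigendecomposition of Z Z', reusable across fits on one pair universe."""

    Z: np.ndarray
    eigvals: np.ndarray
    Q: np.ndarray  # orthonormal eigenvectors, columns

    @classmethod
    def from_sites(cls, sites: SiteSet,
                   pairs: list[tuple[str, str]] | None = None) -> "PairStructure":
        if pairs is None:
            pairs = pair_index(sites)
        Z = incidence_matrix(pairs, sites)
        w, Q = np.linalg.eigh(Z @ Z.T)
        return cls(Z, np.maximum(w, 0.0), Q)


@dataclass
class MLPEFit:
    """A fitted MLPE model."""

    beta: np.ndarray
    beta_se: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    fit_method: str
    n_pairs: int
    n_sites: int
    predictors: list[str]
    residuals: np.ndarray = field(repr=False)
    fitted_fixed: np.ndarray = field(repr=False)

    @property
    def theta(self) -> float:
        return self.sigma_u2 / self.sigma_e2

    @property
    def k_params(self) -> int:
        return len(self.beta) + 2

    @property
    def aic(self) -> float:
        if self.fit_method != "ML":
            raise ValueError("AIC is defined from the ML log-likelihood")
        return -2.0 * self.loglik + 2.0 * self.k_params


def _profile_crit(theta: float, y: np.ndarray, X: np.ndarray,
                  struct: PairStructure, reml: bool):
    """Negative profiled criterion at a variance ratio theta (>= 0)."""
    w = 1.0 + theta * struct.eigvals          # eigenvalues of W = I + theta ZZ'
    Qty = struct.Q.T @ y
    QtX = struct.Q.T @ X
    inv_w = 1.0 / w
    XtWiX = QtX.T @ (QtX * inv_w[:, None])
    XtWiy = QtX.T @ (Qty * inv_w)
    beta = np.linalg.solve(XtWiX, XtWiy)
    r = Qty - QtX @ beta
    quad = float((r * r * inv_w).sum())
    n, p = len(y), X.shape[1]
    logdet_w = float(np.log(w).sum())
    if reml:
        dof = n - p
        sigma_e2 = quad / dof
        sign, logdet_xwx = np.linalg.slogdet(XtWiX)
        ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma_e2) + logdet_w
                     + logdet_xwx + dof)
    else:
        sigma_e2 = quad / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_e2) + logdet_w + n)
    return ll, beta, sigma_e2, XtWiX


def fit_mlpe(y: np.ndarray, X: np.ndarray | pd.DataFrame | None,
             sites: SiteSet, pairs: list[tuple[str, str]] | None = None,
             method: str = "ML",
             struct: PairStructure | None = None) -> MLPEFit:
    """Fit an MLPE model by profiled (RE)ML over the variance ratio.

    ``X`` holds predictor columns (an intercept is always added); pass
    ``None`` or an empty frame for the intercept-only model.  ``struct``
    may carry a precomputed :class:`PairStructure` to amortize the
    eigendecomposition across many fits on the same pair universe.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if struct is None:
        struct = PairStructure.from_sites(sites, pairs)
    y = np.asarray(y, dtype=float)
    n = struct.Z.shape[0]
    if len(y) != n:
        raise ValueError(f"response has {len(y)} rows, pair universe has {n}")
    names: list[str] = []
    if X is None:
        Xa = np.ones((n, 1))
    else:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i + 1}" for i in range(Xa.shape[1])]
        Xa = np.hstack([np.ones((n, 1)), Xa])
    if Xa.shape[0] != n:
        raise ValueError("X row count must equal the pair count")
    reml = method == "REML"

    def neg(log_theta: float) -> float:
        return -_profile_crit(np.exp(log_theta), y, Xa, struct, reml)[0]

    # profile over log theta; also consider the boundary theta = 0
    opt = optimize.minimize_scalar(neg, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    if not opt.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"profile optimisation failed: {opt}")
    ll_zero = _profile_crit(0.0, y, Xa, struct, reml)[0]
    theta = float(np.exp(opt.x))
    ll_opt = -float(opt.fun)
    if ll_zero >= ll_opt or theta < 1e-10:
        theta, ll = 0.0, ll_zero
    else:
        ll = ll_opt
    _, beta, sigma_e2, XtWiX = _profile_crit(theta, y, Xa, struct, reml)
    cov_beta = sigma_e2 * np.linalg.inv(XtWiX)
    fitted = Xa @ beta
    return MLPEFit(
        beta=beta,
        beta_se=np.sqrt(np.diag(cov_beta)),
        sigma_u2=theta * sigma_e2,
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        fit_method=method,
        n_pairs=n,
        n_sites=sites.n,
        predictors=names,
        residuals=y - fitted,
        fitted_fixed=fitted,
    )


# ---------------------------------------------------------------- dredge

def dredge(y: np.ndarray, X: pd.DataFrame, sites: SiteSet,
           pairs: list[tuple[str, str]] | None = None,
           r_max: float = 0.6) -> pd.DataFrame:
    """Exhaustively fit all predictor subsets under a collinearity cap.

    Subsets containing any predictor pair with ``|r| >= r_max`` are
    discarded; the intercept-only model is always a candidate.  Models are
    fitted by ML and ranked by AIC, with delta-AIC and Akaike weights over
    the retained candidate set.  Returns a ModelTable DataFrame sorted by
    AIC with columns ``formula, predictors, k, aic, delta_aic, weight,
    loglik``.
    """
    p = X.shape[1]
    if p > 12:
        raise ValueError("dredge enumerates 2^p subsets; at most 12 predictors")
    struct = PairStructure.from_sites(sites, pairs)
    corr = X.corr().abs().to_numpy() if p > 1 else np.ones((p, p))
    cols = list(X.columns)
    rows = []
    for size in range(p + 1):
        for subset in itertools.combinations(range(p), size):
            if any(corr[a, b] >= r_max for a, b in itertools.combinations(subset, 2)):
                continue
            sub_cols = [cols[k] for k in subset]
            try:
                fit = fit_mlpe(y, X[sub_cols] if sub_cols else None, sites,
                               pairs, method="ML", struct=struct)
            except Exception as exc:  # noqa: BLE001 - record and skip
                warnings.warn(f"fit failed for subset {sub_cols}: {exc}")
                continue
            formula = " + ".join(sub_cols) if sub_cols else "1"
            rows.append({"formula": formula, "predictors": tuple(sub_cols),
                         "k": fit.k_params, "aic": fit.aic, "loglik": fit.loglik})
    table = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    w = np.exp(-table["delta_aic"] / 2.0)
    table["weight"] = w / w.sum()
    return table[["formula", "predictors", "k", "aic", "delta_aic", "weight", "loglik"]]


# ---------------------------------------------------------------- summaries

def r2_nakagawa(fit: MLPEFit) -> tuple[float, float]:
    """Marginal and conditional R-squared of an MLPE fit (REML-based).

    The per-observation random-effect variance is ``2 sigma_u^2`` because
    each pair carries two unit site loadings:
    marginal = var(X beta) / (var(X beta) + 2 sigma_u^2 + sigma_e^2) and
    conditional adds the random-effect share to the numerator.
    """
    sigma_f2 = float(np.var(fit.fitted_fixed))
    denom = sigma_f2 + 2.0 * fit.sigma_u2 + fit.sigma_e2
    return sigma_f2 / denom, (sigma_f2 + 2.0 * fit.sigma_u2) / denom


def dependency_rho(fit: MLPEFit) -> float:
    """Model-implied correlation between two pairs sharing exactly one site."""
    return fit.sigma_u2 / (2.0 * fit.sigma_u2 + fit.sigma_e2)


def residual_autocorrelation(fit: MLPEFit, sites: SiteSet,
                             pairs: list[tuple[str, str]] | None = None,
                             n_perm: int = 999, seed: int = 0
                             ) -> tuple[float, float]:
    """Permutation Moran's I test on site-level mean residuals.

    Residuals of the fitted model are averaged per site; Moran's I uses
    row-standardized inverse-distance weights and a one-sided (positive
    autocorrelation) permutation p-value with ``n_perm`` shuffles.
    """
    if sites.n < 5:
        raise ValueError("need at least 5 sites for the autocorrelation check")
    if pairs is None:
        pairs = pair_index(sites)
    idx = {s: k for k, s in enumerate(sites.site_ids)}
    sums = np.zeros(sites.n)
    counts = np.zeros(sites.n)
    for r, (a, b) in enumerate(pairs):
        sums[idx[a]] += fit.residuals[r]
        sums[idx[b]] += fit.residuals[r]
        counts[idx[a]] += 1
        counts[idx[b]] += 1
    site_resid = sums / counts
    return moran_permutation_test(site_resid, sites, n_perm=n_perm, seed=seed)


def moran_permutation_test(values: np.ndarray, sites: SiteSet,
                           n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Moran's I with inverse-distance weights and a permutation p-value."""
    v = np.asarray(values, dtype=float)
    c = sites.coords()
    d = np.hypot(c[:, 0][:, None] - c[:, 0][None, :],
                 c[:, 1][:, None] - c[:, 1][None, :])
    with np.errstate(divide="ignore"):
        W = 1.0 / d
    np.fill_diagonal(W, 0.0)
    W = W / W.sum(axis=1, keepdims=True)

    def moran(x: np.ndarray) -> float:
        z = x - x.mean()
        return len(x) / W.sum() * float(z @ W @ z) / float(z @ z)

    obs = moran(v)
    rng = np.random.default_rng(seed)
    count = sum(moran(rng.permutation(v)) >= obs for _ in range(n_perm))
    p = (1.0 + count) / (1.0 + n_perm)
    return obs, p
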