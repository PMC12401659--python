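"""Richness models, AIC model selection and canonical correspondence analysis.

Species-by-time presence matrices are built per hex cell (sites with fewer
than 10 distinct sampled years are dropped).  Annual species richness is
modelled as Poisson with a log link, fixed effects for year and flow
metrics (all centered and scaled) and a Gaussian random intercept per hex:

    log lambda_it = beta0 + sum_k beta_k x_kit + u_i,   u_i ~ N(0, sigma^2)

The marginal likelihood integrates the random intercept out with adaptive
Gauss–Hermite quadrature (Laplace approximation refined with quadrature
nodes centred on each group's posterior mode), maximised over
``(beta, log sigma)``.  Model comparison uses AIC, Akaike weights
``w_i = exp(-delta_i/2)/sum_j exp(-delta_j/2)``, evidence ratios, the 95%
confidence set, and the "within 7 AIC" equal-plausibility rule.

Assemblage composition is related to year and flow with canonical
correspondence analysis: chi-square standardisation of the presence
matrix, weighted projection onto the constraints, SVD of the fitted
matrix; axis significance by row permutation of the constraint matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "AssemblageMatrix",
    "build_matrix",
    "ModelFit",
    "fit_poisson_glmm",
    "aic_table",
    "evidence_ratio",
    "CcaResult",
    "cca",
    "explained_fraction",
]


# ---------------------------------------------------------------------------
# species-by-time matrices

@dataclass
class AssemblageMatrix:
    hexid: str
    years: np.ndarray           # strictly increasing sampled years
    species: list[str]
    presence: np.ndarray        # years x species, boolean
    richness: np.ndarray        # per-year species counts (row sums)


def build_matrix(occurrences: pd.DataFrame, min_years: int = 10):
    """Presence matrices per hex from binned occurrence records.

    ``occurrences`` needs ``hexid``, ``species`` and either ``year`` or a
    parseable ``date``.  Returns ``(matrices, dropped)`` where ``matrices``
    maps hexid to :class:`AssemblageMatrix` and ``dropped`` lists hexes
    rejected for having fewer than ``min_years`` distinct sampled years.
    """
    df = occurrences.copy()
    if "year" not in df:
        df["year"] = pd.to_datetime(df["date"]).dt.year
    matrices: dict[str, AssemblageMatrix] = {}
    dropped: list[tuple[str, int]] = []
    for hexid, g in df.groupby("hexid"):
        years = np.sort(g["year"].unique())
        if years.size < min_years:
            dropped.append((str(hexid), int(years.size)))
            continue
        species = sorted(g["species"].unique())
        sp_ix = {s: j for j, s in enumerate(species)}
        yr_ix = {y: i for i, y in enumerate(years)}
        pres = np.zeros((years.size, len(species)), dtype=bool)
        for y, s in zip(g["year"], g["species"]):
            pres[yr_ix[y], sp_ix[s]] = True
        matrices[str(hexid)] = AssemblageMatrix(
            hexid=str(hexid), years=years, species=species,
            presence=pres, richness=pres.sum(axis=1))
    return matrices, dropped


# ---------------------------------------------------------------------------
# Poisson random-intercept GLMM by adaptive Gauss-Hermite ML

@dataclass
class ModelFit:
    name: str
    terms: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    sigma: float
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    scaler: dict[str, tuple[float, float]] = field(default_factory=dict)

    def wald_ci(self, term: str, level: float = 0.95):
        from scipy.stats import norm
        j = (["(intercept)"] + self.terms).index(term)
        z = norm.ppf(0.5 + level / 2)
        return (self.beta[j] - z * self.beta_se[j],
                self.beta[j] + z * self.beta_se[j])


def _group_mode(y, eta, sigma, n_newton=30):
    """Posterior mode and curvature of the random intercept for one group."""
    u = 0.0
    for _ in range(n_newton):
        mu = np.exp(eta + u)
        g = np.sum(y - mu) - u / sigma ** 2
        h = -np.sum(mu) - 1.0 / sigma ** 2
        step = g / h
        u -= step
        if abs(step) < 1e-10:
            break
    mu = np.exp(eta + u)
    h = -np.sum(mu) - 1.0 / sigma ** 2
    return u, h


def _marginal_loglik(theta, y_groups, X_groups, n_nodes=15):
    """Adaptive GH marginal log-likelihood at theta = (beta, log sigma)."""
    beta = theta[:-1]
    sigma = math.exp(theta[-1])
    nodes, weights = hermegauss(n_nodes)   # integrates against exp(-x^2/2)
    total = 0.0
    for y, X in zip(y_groups, X_groups):
        eta = X @ beta
        const = -np.sum(gammaln(y + 1))
        uhat, h = _group_mode(y, eta, sigma)
        tau = 1.0 / math.sqrt(-h)
        u = uhat + tau * nodes
        # log integrand: Poisson loglik + N(0, sigma^2) density of u
        ll = (y[:, None] * (eta[:, None] + u[None, :])
              - np.exp(eta[:, None] + u[None, :])).sum(axis=0)
        ll += -0.5 * (u / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        # adaptive GH: integral = tau * sum w_k exp(nodes^2/2) f(u_k)
        lse = ll + 0.5 * nodes ** 2 + np.log(weights) + math.log(tau)
        m = lse.max()
        total += const + m + math.log(np.exp(lse - m).sum())
    return total


def _poisson_glm_loglik(beta, y, X):
    eta = X @ beta
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def fit_poisson_glmm(data: pd.DataFrame, terms: list[str],
                     response: str = "richness", group: str = "hexid",
                     scale: bool = True, name: str | None = None,
                     n_nodes: int = 15) -> ModelFit:
    """Maximum-likelihood Poisson random-intercept model.

    ``terms`` are fixed-effect columns of ``data`` (may be empty for the
    null model); each is centered and scaled to unit SD when ``scale``.
    With a single group the random intercept cannot be estimated and the
    model collapses to an ordinary Poisson regression (sigma = 0, warned).
    """
    y_all = data[response].to_numpy(float)
    if np.any(y_all < 0) or np.any(y_all != np.round(y_all)):
        raise ValueError("response must be non-negative integer counts")
    X_all = np.column_stack([np.ones(len(data))] +
                            [data[t].to_numpy(float) for t in terms])
    scaler = {}
    for j, t in enumerate(terms, start=1):
        m, s = X_all[:, j].mean(), X_all[:, j].std()
        s = s if s > 0 else 1.0
        if scale:
            X_all[:, j] = (X_all[:, j] - m) / s
            scaler[t] = (m, s)
    groups = data[group].to_numpy()
    uniq = pd.unique(groups)
    y_groups = [y_all[groups == g] for g in uniq]
    X_groups = [X_all[groups == g] for g in uniq]
    k = X_all.shape[1]

    # Poisson GLM start (simple IRLS)
    beta0 = np.zeros(k)
    beta0[0] = math.log(max(y_all.mean(), 0.1))
    for _ in range(50):
        eta = X_all @ beta0
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        zvar = eta + (y_all - mu) / np.maximum(mu, 1e-10)
        XtW = X_all.T * W
        try:
            new = np.linalg.solve(XtW @ X_all, XtW @ zvar)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta0)) < 1e-10:
            beta0 = new
            break
        beta0 = new

    if len(uniq) < 2:
        warnings.warn("single group: random-intercept SD fixed at 0")
        ll = _poisson_glm_loglik(beta0, y_all, X_all)
        # observed information of the GLM for Wald SEs
        mu = np.exp(X_all @ beta0)
        info = (X_all.T * mu) @ X_all
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        n_params = k + 1  # sigma still counted in the contract
        return ModelFit(name or "+".join(terms) or "(null)", list(terms),
                        beta0, se, 0.0, ll, -2 * ll + 2 * n_params,
                        n_params, len(y_all), 1, True, scaler)

    def nll(theta):
        return -_marginal_loglik(theta, y_groups, X_groups, n_nodes)

    theta0 = np.append(beta0, math.log(0.3))
    res = minimize(nll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    if not res.success:  # one polish round
        res2 = minimize(nll, res.x, method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        if res2.fun <= res.fun:
            res = res2
    theta = res.x
    ll = -res.fun
    n_params = k + 1
    hess = _numeric_hessian(nll, theta)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return ModelFit(name or "+".join(terms) or "(null)", list(terms),
                    theta[:k], se, math.exp(theta[-1]), ll,
                    -2 * ll + 2 * n_params, n_params, len(y_all),
                    len(uniq), bool(res.success or res.fun < np.inf), scaler)


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej)
                - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


# ---------------------------------------------------------------------------
# AIC bookkeeping

def aic_table(aics, names=None, plausible_window: float = 7.0,
              confidence: float = 0.95) -> pd.DataFrame:
    """Akaike weights, evidence ratios and the 95% confidence set.

    ``aics`` may be a mapping name -> AIC, a sequence of AIC values, or a
    sequence of :class:`ModelFit`.  The confidence set is the smallest
    weight-ordered prefix with cumulative weight >= ``confidence``; models
    within ``plausible_window`` AIC of the best are flagged equally
    plausible.
    """
    if isinstance(aics, dict):
        names = list(aics.keys())
        values = np.array([float(v) for v in aics.values()])
    else:
        seq = list(aics)
        if seq and isinstance(seq[0], ModelFit):
            names = [m.name for m in seq]
            values = np.array([m.aic for m in seq])
        else:
            values = np.array([float(v) for v in seq])
            names = names or [f"model_{i}" for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("need at least two models to compare")
    delta = values - values.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    order = np.argsort(values, kind="stable")
    tab = pd.DataFrame({"model": np.asarray(names)[order],
                        "aic": values[order],
                        "delta_aic": delta[order],
                        "weight": w[order]})
    tab["cum_weight"] = tab["weight"].cumsum()
    in_set = np.zeros(len(tab), dtype=bool)
    cum = 0.0
    for i in range(len(tab)):
        in_set[i] = True
        cum += tab["weight"].iloc[i]
        if cum >= confidence:
            break
    tab["in_confidence_set"] = in_set
    tab["equally_plausible"] = tab["delta_aic"] <= plausible_window
    return tab.reset_index(drop=True)


def evidence_ratio(table: pd.DataFrame, model_a: str, model_b: str) -> float:
    """Ratio of Akaike weights w_a / w_b."""
    w = table.set_index("model")["weight"]
    return float(w[model_a] / w[model_b])


# ---------------------------------------------------------------------------
# canonical correspondence analysis

@dataclass
class CcaResult:
    total_inertia: float
    constrained_inertia: float
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray
    axis_chi2: np.ndarray       # per-axis canonical eigenvalue (chi-square units)
    axis_p: np.ndarray
    n_perm: int
    row_index: np.ndarray
    col_index: np.ndarray


def _cca_core(Y: np.ndarray, X: np.ndarray):
    tot = Y.sum()
    P = Y / tot
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    total_inertia = float((Q ** 2).sum())
    # weighted centring of constraints, rows weighted by sqrt(r)
    Xc = X - (r[:, None] * X).sum(axis=0)
    Xw = np.sqrt(r)[:, None] * Xc
    # projection via economy QR (rank-deficient columns dropped by pivoting lstsq)
    B, *_ = np.linalg.lstsq(Xw, Q, rcond=None)
    Qfit = Xw @ B
    U, s, Vt = np.linalg.svd(Qfit, full_matrices=False)
    eig = s ** 2
    keep = eig > 1e-12 * max(eig.max(), 1.0) if eig.size else np.zeros(0, bool)
    eig = eig[keep]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    return Q, r, c, total_inertia, eig, U, s, Vt


def cca(Y, X, n_perm: int = 999, seed: int = 0) -> CcaResult:
    """Canonical correspondence analysis with per-axis permutation tests.

    ``Y`` is a non-negative site-by-species matrix (presence/absence or
    counts); ``X`` the site-by-constraint matrix.  Empty rows/columns of Y
    are removed (their indices are reported).  Axis significance: rows of X
    are permuted jointly ``n_perm`` times and the k-th canonical eigenvalue
    of each permutation is compared with the observed one.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.any(Y < 0):
        raise ValueError("Y must be non-negative")
    rows = Y.sum(axis=1) > 0
    cols = Y.sum(axis=0) > 0
    Y = Y[np.ix_(rows, cols)]
    X = X[rows]
    if Y.size == 0 or Y.sum() == 0:
        raise ValueError("Y has no positive entries")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        warnings.warn("constraint matrix is rank deficient; aliased "
                      "directions carry no constrained inertia")

    Q, r, c, total_inertia, eig, U, s, Vt = _cca_core(Y, X)
    constrained = float(eig.sum())
    site_scores = (U * s) / np.sqrt(r)[:, None]
    species_scores = Vt.T / np.sqrt(c)[:, None]

    rng = np.random.default_rng(seed)
    n_axes = eig.size
    exceed = np.zeros(n_axes)
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[0])
        peig = _cca_core(Y, X[perm])[4]
        pe = np.zeros(n_axes)
        pe[:min(n_axes, peig.size)] = peig[:n_axes]
        exceed += pe >= eig
    axis_p = (exceed + 1.0) / (n_perm + 1.0)
    return CcaResult(total_inertia, constrained, eig, site_scores,
                     species_scores, eig.copy(), axis_p, n_perm,
                     np.flatnonzero(rows), np.flatnonzero(cols))


def explained_fraction(result_or_constrained, total=None) -> float:
    """Percent of total inertia captured by the constraints, one decimal."""
    if total is None:
        constrained = result_or_constrained.constrained_inertia
        total = result_or_constrained.total_inertia
    else:
        constrained = float(result_or_constrained)
    if total <= 0:
        raise ValueError("total inertia must be positive")
    return round(100.0 * constrained / total, 1)
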