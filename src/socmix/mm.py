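"""Multi-membership linear mixed models estimated by REML.

The model is the Gaussian LMM

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma_k^2 I),  eps ~ N(0, sigma_e^2 I)

where one random block is a *multi-membership* term: each dyadic observation
loads on the identities of both member birds, so its incidence matrix has two
unit entries per row. This absorbs the repeated occurrence of every bird
across dyads, which would otherwise pseudo-replicate the data.

Estimation profiles the residual variance and maximises the restricted
likelihood over variance ratios gamma_k = sigma_k^2 / sigma_e^2 on the log
scale (nonnegativity by construction), using the Woodbury identity so that
every objective evaluation costs O(q^3) in the total number of random levels
q (a few hundred birds + years), never O(n^3) in the number of dyads.
Inference is Wald t with Satterthwaite denominator degrees of freedom from a
finite-difference Hessian of the REML criterion; post hoc level contrasts use
a single-step familywise adjustment based on the joint normal approximation
of the contrast vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

__all__ = [
    "MMDesign",
    "MMFit",
    "RandomBlock",
    "build_design",
    "fit_reml",
    "satterthwaite_df",
    "wald_table",
    "tukey_contrasts",
    "omnibus_wald",
    "vif",
]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

#: reference level and dummy levels for the pipeline's categorical terms;
#: the reference is the first-listed level of each factor
_CATEGORICAL = {
    "sex_diff": ("same", ("different",)),
    "season": ("major", ("minor",)),
    "status_pair": ("DomDom", ("DomHelp", "DomSub", "HelpSub", "SubSub")),
    "nest_sharing": ("nest_sharing", ("non_nest_sharing",)),
}


@dataclass
class RandomBlock:
    name: str
    Z: sp.csr_matrix
    levels: list


@dataclass
class MMDesign:
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    blocks: list[RandomBlock]
    #: term -> list of fixed-effect column indices belonging to it
    term_cols: dict[str, list[int]]
    #: factor term -> (reference level, ordered non-reference levels)
    factors: dict[str, tuple[str, tuple[str, ...]]]

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(dyads: pd.DataFrame, response: str, fixed_terms: list[str],
                 random_terms: tuple[str, ...] = ("year", "bird"),
                 mm_weight: float = 1.0) -> MMDesign:
    """Assemble response, fixed-effects matrix and random incidence blocks.

    Categorical terms are dummy-coded against their stated reference level
    (between-group, major season, same sex, no shared nest, Dom-Dom,
    nest-sharing). The multi-membership block ('bird') puts ``mm_weight`` in
    the columns of both member birds of each dyad. The fixed matrix is checked
    for full column rank; aliased columns are reported by name.
    """
    n = len(dyads)
    if n == 0:
        raise ValueError("empty dyad table")
    y = dyads[response].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {"(Intercept)": [0]}
    factors: dict[str, tuple[str, tuple[str, ...]]] = {}
    for term in fixed_terms:
        if term not in dyads.columns:
            raise KeyError(f"term '{term}' not in dyad table")
        col = dyads[term]
        if term in _CATEGORICAL:
            ref, levels = _CATEGORICAL[term]
            observed = set(col.unique())
            unknown = observed - ({ref} | set(levels))
            if unknown:
                raise ValueError(f"unexpected levels for '{term}': {sorted(unknown)}")
            used = tuple(l for l in levels if l in observed)
            factors[term] = (ref, used)
            idxs = []
            for lev in used:
                idxs.append(len(cols))
                names.append(f"{term}[{lev}]")
                cols.append((col == lev).to_numpy(dtype=float))
            term_cols[term] = idxs
        elif col.dtype == object:
            levels = sorted(col.unique())
            ref, rest = levels[0], tuple(levels[1:])
            factors[term] = (ref, rest)
            idxs = []
            for lev in rest:
                idxs.append(len(cols))
                names.append(f"{term}[{lev}]")
                cols.append((col == lev).to_numpy(dtype=float))
            term_cols[term] = idxs
        else:
            term_cols[term] = [len(cols)]
            names.append(term)
            cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)

    _check_full_rank(X, names)

    blocks: list[RandomBlock] = []
    for rt in random_terms:
        if rt == "bird":
            levels = sorted(set(dyads["bird_a"]) | set(dyads["bird_b"]))
            idx = {b: i for i, b in enumerate(levels)}
            rows = np.repeat(np.arange(n), 2)
            colsZ = np.empty(2 * n, dtype=np.int64)
            colsZ[0::2] = [idx[b] for b in dyads["bird_a"]]
            colsZ[1::2] = [idx[b] for b in dyads["bird_b"]]
            Z = sp.csr_matrix((np.full(2 * n, float(mm_weight)), (rows, colsZ)),
                              shape=(n, len(levels)))
            blocks.append(RandomBlock("bird", Z, levels))
        else:
            if rt not in dyads.columns:
                raise KeyError(f"random term '{rt}' not in dyad table")
            vals = dyads[rt].to_numpy()
            levels = sorted(pd.unique(vals).tolist())
            idx = {v: i for i, v in enumerate(levels)}
            if len(levels) < 2:
                # a single-level random intercept is confounded with the fixed
                # intercept and leaves the REML criterion flat; drop it
                logger.info("random term '%s' has one level; dropped", rt)
                continue
            Z = sp.csr_matrix((np.ones(n), (np.arange(n), [idx[v] for v in vals])),
                              shape=(n, len(levels)))
            blocks.append(RandomBlock(rt, Z, levels))

    return MMDesign(y=y, X=X, x_names=names, blocks=blocks,
                    term_cols=term_cols, factors=factors)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed-effects matrix is rank deficient; aliased "
                         f"columns: {aliased}")


class _Workspace:
    """Cross-product cache; every REML evaluation is O(q^3), independent of n."""

    def __init__(self, y: np.ndarray, X: np.ndarray, blocks: list[RandomBlock]):
        self.n, self.p = X.shape
        self.block_sizes = [b.Z.shape[1] for b in blocks]
        self.K = len(blocks)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        if blocks:
            Z = sp.hstack([b.Z for b in blocks], format="csr")
            self.ZtZ = (Z.T @ Z).toarray()
            self.ZtX = Z.T @ X
            self.Zty = Z.T @ y
            self.q = Z.shape[1]
        else:
            self.q = 0

    def _pieces(self, gamma: np.ndarray):
        """Woodbury pieces for H = I + Z diag(g) Z' at variance ratios gamma."""
        if self.q == 0 or self.K == 0:
            XtHiX, XtHiy, ytHiy, logdetW = self.XtX, self.Xty, self.yty, 0.0
        else:
            g = np.repeat(gamma, self.block_sizes)
            s = np.sqrt(g)
            W = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
            cW, low = sla.cho_factor(W, lower=True, check_finite=False)
            Ux = s[:, None] * self.ZtX
            uy = s * self.Zty
            WiUx = sla.cho_solve((cW, low), Ux, check_finite=False)
            Wiuy = sla.cho_solve((cW, low), uy, check_finite=False)
            XtHiX = self.XtX - Ux.T @ WiUx
            XtHiy = self.Xty - Ux.T @ Wiuy
            ytHiy = self.yty - uy @ Wiuy
            logdetW = 2.0 * float(np.sum(np.log(np.diag(cW))))
        cA, lowA = sla.cho_factor(XtHiX, lower=True, check_finite=False)
        beta = sla.cho_solve((cA, lowA), XtHiy, check_finite=False)
        rss = max(ytHiy - XtHiy @ beta, 1e-300)
        logdetXtHiX = 2.0 * float(np.sum(np.log(np.diag(cA))))
        return beta, rss, logdetW, logdetXtHiX, (cA, lowA)

    def profiled_neg2rl(self, log_gamma: np.ndarray) -> float:
        gamma = np.exp(np.clip(log_gamma, -40.0, 40.0))
        try:
            _, rss, ldW, ldA, _ = self._pieces(gamma)
        except np.linalg.LinAlgError:
            return np.inf
        nmp = self.n - self.p
        sigma2 = rss / nmp
        return nmp * (np.log(sigma2) + 1.0 + _LOG2PI) + ldW + ldA

    def neg2rl_full(self, theta: np.ndarray) -> float:
        """-2 REML log-likelihood at variances theta = (sigma_1^2..K, sigma_e^2)."""
        sigma2e = theta[-1]
        if sigma2e <= 0 or (theta[:-1] < 0).any():
            return np.inf
        gamma = theta[:-1] / sigma2e
        beta, rss, ldW, ldA, _ = self._pieces(gamma)
        nmp = self.n - self.p
        # |V| = sigma_e^{2n} |W|; |X'V^-1 X| = |X'H^-1 X| / sigma_e^{2p}
        return (self.n * np.log(sigma2e) + ldW
                + ldA - self.p * np.log(sigma2e)
                + rss / sigma2e + nmp * _LOG2PI)

    def solve_at(self, gamma: np.ndarray):
        beta, rss, ldW, ldA, (cA, lowA) = self._pieces(gamma)
        nmp = self.n - self.p
        sigma2e = rss / nmp
        cov_beta = sigma2e * sla.cho_solve((cA, lowA), np.eye(self.p),
                                           check_finite=False)
        neg2rl = nmp * (np.log(sigma2e) + 1.0 + _LOG2PI) + ldW + ldA
        return beta, sigma2e, cov_beta, neg2rl

    def cov_beta_at(self, theta: np.ndarray) -> np.ndarray:
        sigma2e = theta[-1]
        gamma = theta[:-1] / sigma2e
        *_, (cA, lowA) = self._pieces(gamma)
        return sigma2e * sla.cho_solve((cA, lowA), np.eye(self.p),
                                       check_finite=False)


@dataclass
class MMFit:
    beta: np.ndarray
    se: np.ndarray
    x_names: list[str]
    varcomp: dict[str, float]          # per random block + 'residual'
    df: np.ndarray                     # Satterthwaite df per coefficient
    t: np.ndarray
    p: np.ndarray
    reml_loglik: float
    converged: bool
    singular: bool
    n_obs: int
    n_levels: dict[str, int]
    cov_beta: np.ndarray
    design: MMDesign = field(repr=False)
    _ws: _Workspace = field(repr=False)
    _theta: np.ndarray = field(repr=False)      # (sigma_k^2 ..., sigma_e^2)
    _theta_cov: np.ndarray | None = field(default=None, repr=False)
    _theta_cov_ok: bool | None = field(default=None, repr=False)

    @property
    def residual_df(self) -> int:
        return self.n_obs - len(self.beta)


_GAMMA_FLOOR = 1e-10  # variance ratios below this are reported as zero


def fit_reml(design: MMDesign, tol: float = 1e-8, max_iter: int = 200,
             fix_variance: dict[str, float] | None = None) -> MMFit:
    """Fit the multi-membership LMM by REML.

    Variance ratios are optimised on the log scale with a quasi-Newton method
    from two starting points, then polished with a derivative-free simplex to
    ``tol`` on the relative objective. Zero variance components are allowed:
    the fit is flagged ``singular`` and inference falls back gracefully.
    ``fix_variance`` pins named components (only 0.0 is supported, collapsing
    the block); non-convergence yields a flagged fit, not an exception.
    """
    fix_variance = fix_variance or {}
    for name, v in fix_variance.items():
        if v != 0.0:
            raise NotImplementedError("only fix_variance=0.0 is supported")
    blocks = [b for b in design.blocks if b.name not in fix_variance]
    ws = _Workspace(design.y, design.X, blocks)
    K = ws.K
    converged = True

    if K == 0:
        gamma = np.zeros(0)
    else:
        best = None
        for start in (np.full(K, -1.0), np.full(K, -5.0)):
            res = optimize.minimize(ws.profiled_neg2rl, start, method="L-BFGS-B",
                                    bounds=[(-30.0, 12.0)] * K,
                                    options={"maxiter": max_iter, "ftol": 1e-12,
                                             "gtol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        polish = optimize.minimize(ws.profiled_neg2rl, best.x, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": tol,
                                            "maxiter": 4000})
        final = polish if polish.fun <= best.fun else best
        # the simplex polish certifies a local optimum even when the
        # quasi-Newton line search gave up early
        converged = bool(polish.success or best.success)
        if not converged:
            logger.warning("REML optimisation did not report convergence: %s",
                           final.message)
        gamma = np.exp(np.clip(final.x, -40.0, 40.0))
        gamma = np.where(gamma < _GAMMA_FLOOR, 0.0, gamma)

    beta, sigma2e, cov_beta, neg2rl = ws.solve_at(gamma)
    se = np.sqrt(np.diag(cov_beta))

    varcomp: dict[str, float] = {}
    fitted_i = 0
    for b in design.blocks:
        if b.name in fix_variance:
            varcomp[b.name] = 0.0
        else:
            varcomp[b.name] = float(gamma[fitted_i] * sigma2e)
            fitted_i += 1
    varcomp["residual"] = float(sigma2e)
    singular = any(v == 0.0 for n_, v in varcomp.items() if n_ != "residual")

    theta = np.array([varcomp[b.name] for b in blocks] + [sigma2e])
    fit = MMFit(beta=beta, se=se, x_names=list(design.x_names), varcomp=varcomp,
                df=np.empty(0), t=np.empty(0), p=np.empty(0),
                reml_loglik=-0.5 * neg2rl, converged=converged,
                singular=singular, n_obs=ws.n,
                n_levels={b.name: len(b.levels) for b in design.blocks},
                cov_beta=cov_beta, design=design, _ws=ws, _theta=theta)
    L = np.eye(len(beta))
    fit.df = satterthwaite_df(fit, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit.t = np.where(se > 0, beta / se, 0.0)
    fit.p = 2.0 * stats.t.sf(np.abs(fit.t), fit.df)
    return fit


def _theta_steps(theta: np.ndarray) -> np.ndarray:
    scale = max(theta[-1], 1e-12)
    return np.maximum(1e-5 * np.abs(theta), 1e-6 * scale)


def _variance_covariance(fit: MMFit) -> tuple[np.ndarray | None, bool]:
    """Asymptotic covariance of the variance estimates: 2 * inv(Hessian of
    -2 REML), Hessian by central finite differences (forward at a zero
    boundary). Cached on the fit."""
    if fit._theta_cov_ok is not None:
        return fit._theta_cov, fit._theta_cov_ok
    ws, theta = fit._ws, fit._theta
    m = len(theta)
    if ws.K == 0:
        fit._theta_cov, fit._theta_cov_ok = None, False
        return None, False
    h = _theta_steps(theta)

    def f(t: np.ndarray) -> float:
        return ws.neg2rl_full(t)

    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ti = theta.copy()
            if i == j:
                lo_ok = theta[i] - h[i] >= 0
                if lo_ok:
                    tp, tm = theta.copy(), theta.copy()
                    tp[i] += h[i]
                    tm[i] -= h[i]
                    H[i, i] = (f(tp) - 2 * f(theta) + f(tm)) / h[i] ** 2
                else:  # forward second difference at the boundary
                    t1, t2 = theta.copy(), theta.copy()
                    t1[i] += h[i]
                    t2[i] += 2 * h[i]
                    H[i, i] = (f(t2) - 2 * f(t1) + f(theta)) / h[i] ** 2
            else:
                si = h[i] if theta[i] - h[i] < 0 else 0.0
                sj = h[j] if theta[j] - h[j] < 0 else 0.0
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h[i] + si; tpp[j] += h[j] + sj
                tpm[i] += h[i] + si; tpm[j] += -h[j] + sj
                tmp[i] += -h[i] + si; tmp[j] += h[j] + sj
                tmm[i] += -h[i] + si; tmm[j] += -h[j] + sj
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h[i] * h[j])
    try:
        eig = np.linalg.eigvalsh(H)
        if eig.min() <= 0:
            raise np.linalg.LinAlgError
        cov = 2.0 * np.linalg.inv(H)
        fit._theta_cov, fit._theta_cov_ok = cov, True
    except np.linalg.LinAlgError:
        logger.warning("variance-component Hessian not positive definite; "
                       "falling back to residual df")
        fit._theta_cov, fit._theta_cov_ok = None, False
    return fit._theta_cov, fit._theta_cov_ok


def satterthwaite_df(fit: MMFit, contrast: np.ndarray) -> np.ndarray | float:
    """Satterthwaite denominator df for contrast(s) of the fixed effects.

    df = 2 C^2 / (g' Var(theta) g) with C = c' cov(beta) c and g the gradient
    of C in the variance components. Falls back to residual df (n - p) when
    the REML Hessian is not positive definite or all variances are zero.
    Accepts a single contrast vector or a matrix with one contrast per row.
    """
    c = np.atleast_2d(np.asarray(contrast, dtype=float))
    scalar = np.asarray(contrast).ndim == 1
    nmp = fit.residual_df
    ws, theta = fit._ws, fit._theta

    if ws.K == 0 or np.all(theta[:-1] == 0.0):
        out = np.full(len(c), float(nmp))
        return float(out[0]) if scalar else out

    Vt, ok = _variance_covariance(fit)
    if not ok:
        out = np.full(len(c), float(nmp))
        return float(out[0]) if scalar else out

    h = _theta_steps(theta)
    m = len(theta)
    C0 = np.einsum("ij,jk,ik->i", c, fit.cov_beta, c)
    grads = np.empty((len(c), m))
    for i in range(m):
        if theta[i] - h[i] >= 0:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            Cp = np.einsum("ij,jk,ik->i", c, ws.cov_beta_at(tp), c)
            Cm = np.einsum("ij,jk,ik->i", c, ws.cov_beta_at(tm), c)
            grads[:, i] = (Cp - Cm) / (2 * h[i])
        else:
            tp = theta.copy()
            tp[i] += h[i]
            Cp = np.einsum("ij,jk,ik->i", c, ws.cov_beta_at(tp), c)
            grads[:, i] = (Cp - C0) / h[i]

    denom = np.einsum("im,mk,ik->i", grads, Vt, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * C0 ** 2 / denom
    df = np.where((denom <= 0) | ~np.isfinite(df), float(nmp), df)
    df = np.clip(df, 1.0, float(nmp))
    return float(df[0]) if scalar else df


def wald_table(fit: MMFit) -> pd.DataFrame:
    """Coefficient table: term, Beta, SE, Statistic (t), df, p."""
    if not fit.converged:
        raise ValueError("cannot build a Wald table from a non-converged fit")
    return pd.DataFrame({
        "term": fit.x_names,
        "beta": fit.beta,
        "se": fit.se,
        "statistic": fit.t,
        "df": fit.df,
        "p": fit.p,
    })


_QMC_SEED = 20260924  # fixed: adjusted p-values are deterministic across runs
_QMC_POINTS = 1 << 15


def _max_abs_null_sf(t_abs: np.ndarray, R: np.ndarray) -> np.ndarray:
    """P(max_i |Z_i| >= t) for Z ~ N(0, R), by scrambled-Sobol quadrature.

    The correlation matrix of mixed-model contrasts is typically singular
    (k(k-1)/2 contrasts live in a (k-1)-dimensional space), so Z is generated
    through an eigendecomposition square root.
    """
    from scipy.stats import qmc

    eigval, eigvec = np.linalg.eigh(R)
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    sob = qmc.Sobol(d=R.shape[0], scramble=True, seed=_QMC_SEED)
    u = np.clip(sob.random(_QMC_POINTS), 1e-12, 1 - 1e-12)
    z = stats.norm.ppf(u) @ L.T
    m = np.abs(z).max(axis=1)
    return np.array([float(np.mean(m >= t)) for t in np.atleast_1d(t_abs)])


def tukey_contrasts(fit: MMFit, factor_name: str) -> pd.DataFrame:
    """All pairwise level contrasts of a fitted factor with single-step
    familywise adjustment (Tukey-style control).

    Because contrasts in a mixed model with unequal standard errors are not
    exchangeable, the adjustment uses the equicoordinate probability of the
    joint normal approximation of the contrast statistics rather than the
    studentized-range distribution. With two levels (a single contrast) the
    adjusted p equals the unadjusted p exactly.
    """
    if factor_name not in fit.design.factors:
        raise KeyError(f"factor '{factor_name}' is not in the fitted model")
    ref, rest = fit.design.factors[factor_name]
    levels = [ref, *rest]
    p_fixed = len(fit.beta)
    vecs = {ref: np.zeros(p_fixed)}
    for lev, col in zip(rest, fit.design.term_cols[factor_name]):
        v = np.zeros(p_fixed)
        v[col] = 1.0
        vecs[lev] = v

    pairs = [(levels[i], levels[j]) for i in range(len(levels))
             for j in range(i + 1, len(levels))]
    L = np.array([vecs[a] - vecs[b] for a, b in pairs])
    est = L @ fit.beta
    Sigma = L @ fit.cov_beta @ L.T
    se = np.sqrt(np.diag(Sigma))
    dfs = satterthwaite_df(fit, L)
    tvals = est / se
    p_unadj = 2.0 * stats.t.sf(np.abs(tvals), dfs)

    if len(pairs) == 1:
        p_adj = p_unadj.copy()
    else:
        d = np.sqrt(np.diag(Sigma))
        R = Sigma / np.outer(d, d)
        p_adj = _max_abs_null_sf(np.abs(tvals), R)
        p_adj = np.maximum(p_adj, p_unadj)  # single-step never below unadjusted

    return pd.DataFrame({
        "level_a": [a for a, _ in pairs],
        "level_b": [b for _, b in pairs],
        "estimate": est,
        "se": se,
        "df": dfs,
        "t": tvals,
        "p_unadjusted": p_unadj,
        "p_adjusted": p_adj,
    })


def omnibus_wald(fit: MMFit, factor_name: str) -> tuple[float, float, float, float]:
    """Joint Wald F test that all non-reference coefficients of a factor are
    zero. Returns (F, df1, df2, p); df2 is the smallest Satterthwaite df over
    the factor's single-coefficient contrasts (conservative)."""
    if factor_name not in fit.design.factors:
        raise KeyError(f"factor '{factor_name}' is not in the fitted model")
    cols = fit.design.term_cols[factor_name]
    L = np.zeros((len(cols), len(fit.beta)))
    for r, cidx in enumerate(cols):
        L[r, cidx] = 1.0
    est = L @ fit.beta
    Sigma = L @ fit.cov_beta @ L.T
    stat = float(est @ np.linalg.solve(Sigma, est))
    df1 = float(len(cols))
    df2 = float(np.min(satterthwaite_df(fit, L)))
    F = stat / df1
    p = float(stats.f.sf(F, df1, df2))
    return F, df1, df2, p


def vif(design: MMDesign) -> dict[str, float]:
    """Generalised variance-inflation factor per fixed-effect term.

    Computed on the correlation matrix of the fixed-effects columns with the
    intercept excluded; for a single-column term this is the classic
    VIF_j = 1 / (1 - R_j^2). Values are reported uncapped.
    """
    terms = [t for t in design.term_cols if t != "(Intercept)"]
    cols = [c for t in terms for c in design.term_cols[t]]
    Xc = design.X[:, cols]
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        zero = [design.x_names[cols[j]] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant fixed-effect columns: {zero}")
    Xs = (Xc - Xc.mean(axis=0)) / sd
    R = np.corrcoef(Xs, rowvar=False)
    R = np.atleast_2d(R)
    sign, logdet_all = np.linalg.slogdet(R)
    if sign <= 0 or logdet_all < np.log(np.finfo(float).tiny):
        raise ValueError("fixed-effects matrix is rank deficient; VIF undefined")
    pos = {c: i for i, c in enumerate(cols)}
    out: dict[str, float] = {}
    for t in terms:
        own = [pos[c] for c in design.term_cols[t]]
        others = [i for i in range(len(cols)) if i not in own]
        s1, ld1 = np.linalg.slogdet(R[np.ix_(own, own)])
        if others:
            s2, ld2 = np.linalg.slogdet(R[np.ix_(others, others)])
        else:
            s2, ld2 = 1.0, 0.0
        out[t] = float(np.exp(ld1 + ld2 - logdet_all))
    return out
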