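"""Allele-frequency cline regression with shared-ancestry control.

Two complementary regressions of derived-allele frequency on latitude and
temperature:

* **PGLS** — generalized least squares on per-population mean frequencies
  with a Brownian-motion covariance derived from a midpoint-rooted
  neighbor-joining tree of pairwise genome-wide F_ST distances.
* **Binomial GLMM** — per-individual 2-column response (derived, ancestral
  allele counts), logit link, fixed effects for the z-transformed predictors
  plus genome-wide F_ST to the reference population, and random intercepts
  for population and individual (the individual term is an observation-level
  random effect absorbing overdispersion).  Fitted by Laplace-approximated
  maximum likelihood, so AIC values are comparable across fixed-effect
  structures.

Multi-model inference follows the Akaike-weight convention: models ranked by
(corrected) AIC, weights w_i = exp(-Δ_i/2)/Σexp(-Δ_j/2), and a 95% best-model
confidence set (smallest prefix of cumulative weight >= 0.95).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .io_formats import GenotypeRecord

__all__ = [
    "RegressionFit",
    "ModelComparisonRow",
    "z_transform",
    "nj_tree",
    "midpoint_root",
    "brownian_covariance",
    "pgls_fit",
    "glmm_fit",
    "glmm_model_set",
    "lrt",
    "multimodel_table",
    "stability_analysis",
    "pearson_correlation",
]


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sd 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if len(np.unique(v)) < 2 or sd == 0:
        raise ValueError("cannot z-transform a constant predictor")
    return (v - v.mean()) / sd


def nj_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to zero."""
    d = np.asarray(distance_matrix, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    # The estimator can give slightly negative distances for very close pairs;
    # NJ requires non-negative input.
    dm = DistanceMatrix(np.clip(d, 0.0, None), list(labels))
    return _skbio_nj(dm, neg_as_zero=True)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) == 2:
        # degenerate two-leaf tree: bisect the single path directly
        half = tips[0].distance(tips[1]) / 2.0
        a, b = (t.name for t in tips)
        return TreeNode.read([f"({a}:{half},{b}:{half});"])
    return tree.root_at_midpoint()


def brownian_covariance(tree: TreeNode, labels: Sequence[str],
                        lam: float = 1.0) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-MRCA path length.

    Pagel's lambda scales off-diagonal entries; lam=0 gives a diagonal
    (star-tree / independent-residual) structure.
    """
    labels = list(labels)
    tree = tree.copy()
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    depth = {}
    for node in tree.preorder(include_self=True):
        parent_depth = depth[id(node.parent)] if node.parent is not None else 0.0
        depth[id(node)] = parent_depth + (node.length or 0.0)
    lcas = {}
    n = len(labels)
    C = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    missing = [l for l in labels if l not in tips]
    if missing:
        raise ValueError(f"tree is missing leaves {missing}")
    for i in range(n):
        C[i, i] = depth[id(tips[labels[i]])]
        for j in range(i + 1, n):
            lca = tree.lowest_common_ancestor([tips[labels[i]], tips[labels[j]]])
            C[i, j] = C[j, i] = lam * depth[id(lca)]
    return C


@dataclasses.dataclass
class RegressionFit:
    model_label: str
    coefficients: Dict[str, float]
    se: Dict[str, float]
    log_likelihood: float
    k: int
    n: int
    aic: float
    aicc: float
    sigma2_pop: float = np.nan
    sigma2_ind: float = np.nan
    dispersion: float = np.nan
    converged: bool = True
    df_fixed: Optional[int] = None

    def ci95(self, name: str) -> tuple:
        """Wald 95% interval; t quantile with between-cluster df when known.

        Cluster-level predictors carry roughly one unit of information per
        group, so the normal quantile undercovers at modest group counts.
        """
        b, s = self.coefficients[name], self.se[name]
        q = stats.t.ppf(0.975, self.df_fixed) if self.df_fixed else 1.959964
        return (b - q * s, b + q * s)


def pgls_fit(response: Sequence[float], predictors: Dict[str, Sequence[float]],
             tree: TreeNode, labels: Sequence[str], lam: float = 1.0,
             model_label: Optional[str] = None, k_base: int = 4,
             z_predictors: bool = True) -> RegressionFit:
    """Phylogenetic GLS under Brownian covariance, ML estimates.

    ``k_base`` is the parameter-count convention for the null
    (intercept-only) model; each test predictor adds one.  AICc uses
    n = number of populations.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    names = list(predictors)
    X = np.column_stack([np.ones(n)] + [
        z_transform(predictors[p]) if z_predictors else np.asarray(predictors[p], float)
        for p in names
    ])
    C = brownian_covariance(tree, labels, lam)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular phylogenetic covariance matrix") from e
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtX = Xi.T @ Xi
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta
    sigma2 = float(resid @ resid) / n
    logdetC = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetC + n)
    k = k_base + len(names)
    aic = -2 * ll + 2 * k
    aicc = aic + (2 * k * (k + 1) / (n - k - 1)) if n - k - 1 > 0 else np.inf
    cov = sigma2 * np.linalg.pinv(XtX) * n / max(n - X.shape[1], 1)
    coef = {"intercept": float(beta[0]), **{p: float(b) for p, b in zip(names, beta[1:])}}
    se = {"intercept": float(np.sqrt(cov[0, 0])),
          **{p: float(np.sqrt(cov[i + 1, i + 1])) for i, p in enumerate(names)}}
    return RegressionFit(
        model_label=model_label or ("Null" if not names else "Null+" + "+".join(names)),
        coefficients=coef, se=se, log_likelihood=ll, k=k, n=n, aic=aic, aicc=aicc,
        df_fixed=max(n - X.shape[1], 1),
    )


# ---------------------------------------------------------------------------
# Binomial GLMM with Laplace-approximated ML
# ---------------------------------------------------------------------------

def _glmm_inner_mode(y, m, Xb, pop_idx, J, s2p, s2v, max_iter=100, tol=1e-10):
    """Joint mode of (u, v) by Newton iteration.

    The Hessian has closed-form block structure (each observation-level effect
    v_i belongs to exactly one population), so each step reduces to diagonal
    Schur-complement algebra.
    """
    n = len(y)
    u = np.zeros(J)
    v = np.zeros(n)
    inv_p, inv_v = 1.0 / s2p, 1.0 / s2v
    for _ in range(max_iter):
        eta = Xb + u[pop_idx] + v
        mu = special.expit(eta)
        W = m * mu * (1 - mu)
        gv = (y - m * mu) - v * inv_v                      # d f / d v_i
        gu = np.bincount(pop_idx, weights=y - m * mu, minlength=J) - u * inv_p
        Dv = W + inv_v
        # Schur complement for u after eliminating v (diagonal in u)
        Wsum = np.bincount(pop_idx, weights=W, minlength=J)
        WD = np.bincount(pop_idx, weights=W * W / Dv, minlength=J)
        Su = Wsum + inv_p - WD
        rhs_u = gu - np.bincount(pop_idx, weights=W * gv / Dv, minlength=J)
        du = rhs_u / Su
        dv = (gv - W * du[pop_idx]) / Dv
        u += du
        v += dv
        if max(np.abs(du).max(initial=0.0), np.abs(dv).max(initial=0.0)) < tol:
            break
    eta = Xb + u[pop_idx] + v
    mu = special.expit(eta)
    W = m * mu * (1 - mu)
    Dv = W + inv_v
    Wsum = np.bincount(pop_idx, weights=W, minlength=J)
    WD = np.bincount(pop_idx, weights=W * W / Dv, minlength=J)
    Su = Wsum + inv_p - WD
    logdetH = np.log(Dv).sum() + np.log(Su).sum()
    return u, v, mu, logdetH


def _glmm_loglik(params, y, m, X, pop_idx, J, lognorm):
    p = X.shape[1]
    beta = params[:p]
    s2p = math.exp(2 * params[p])
    s2v = math.exp(2 * params[p + 1])
    u, v, mu, logdetH = _glmm_inner_mode(y, m, X @ beta, pop_idx, J, s2p, s2v)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    f = (y * np.log(mu) + (m - y) * np.log(1 - mu)).sum() + lognorm
    f -= 0.5 * (u @ u) / s2p + 0.5 * (v @ v) / s2v
    # Laplace: logL = f(mode) - 1/2 log det(H) + (J+n)/2 log(2pi) - 1/2 log|D|... combined:
    ll = f - 0.5 * logdetH - 0.5 * (J * math.log(s2p) + len(y) * math.log(s2v))
    return ll


def glmm_fit(records: Sequence[GenotypeRecord], fixed: Sequence[str] = (),
             include_fst: bool = True,
             fst_to_reference: Optional[Dict[str, float]] = None,
             model_label: Optional[str] = None,
             sigma_bounds=(-6.0, 3.0)) -> RegressionFit:
    """Binomial (logit) GLMM on per-individual derived/ancestral allele counts.

    logit(p) = β0 + β_fst·z(F_ST-to-reference) + Σ β_x·z(x) + u_pop + v_ind
    with u ~ N(0, σ²_pop) and v ~ N(0, σ²_ind); Laplace-approximated ML.

    ``fixed`` names GenotypeRecord attributes used as test predictors
    (``latitude``, ``temperature``, ``age_years``).  Records flagged missing
    are excluded from the fit.
    """
    recs = [r for r in records if not r.missing]
    if not recs:
        raise ValueError("no usable records")
    y = np.array([r.derived_count for r in recs], dtype=float)
    m = np.full(len(recs), 2.0)
    pops = [r.population for r in recs]
    pop_labels = sorted(set(pops))
    pop_idx = np.array([pop_labels.index(p) for p in pops])
    J = len(pop_labels)
    cols, names = [], []
    if include_fst:
        if fst_to_reference is None:
            raise ValueError("include_fst=True requires fst_to_reference mapping")
        fst = np.array([fst_to_reference[p] for p in pops], dtype=float)
        cols.append(z_transform(fst) if len(np.unique(fst)) > 1 else fst * 0.0)
        names.append("fst")
    for f in fixed:
        vals = np.array([getattr(r, "age_years" if f == "age" else f) for r in recs], dtype=float)
        cols.append(z_transform(vals))
        names.append(f)
    X = np.column_stack([np.ones(len(recs))] + cols)
    lognorm = float(np.log(special.comb(2, y)).sum())

    p = X.shape[1]
    x0 = np.concatenate([np.zeros(p), [-1.0, -1.0]])
    # crude intercept start at the pooled logit
    pooled = np.clip(y.sum() / m.sum(), 1e-6, 1 - 1e-6)
    x0[0] = math.log(pooled / (1 - pooled))
    neg = lambda t: -_glmm_loglik(t, y, m, X, pop_idx, J, lognorm)
    bounds = [(None, None)] * p + [tuple(sigma_bounds)] * 2
    res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
    res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    if res2.fun < res.fun:
        res = res2
    ll = -res.fun
    theta = res.x
    beta = theta[:p]
    s2p = math.exp(2 * theta[p])
    s2v = math.exp(2 * theta[p + 1])
    k = p + 2
    aic = -2 * ll + 2 * k

    se = _wald_se(neg, theta, p)
    u, v, mu, _ = _glmm_inner_mode(y, m, X @ beta, pop_idx, J, s2p, s2v)
    pearson = (y - m * mu) / np.sqrt(np.clip(m * mu * (1 - mu), 1e-12, None))
    disp = float((pearson ** 2).sum() / max(len(y) - k, 1))
    coef = {"intercept": float(beta[0]), **{nm: float(b) for nm, b in zip(names, beta[1:])}}
    ses = {"intercept": se[0], **{nm: se[i + 1] for i, nm in enumerate(names)}}
    return RegressionFit(
        model_label=model_label or ("Null" if not fixed else "Null+" + "+".join(fixed)),
        coefficients=coef, se=ses, log_likelihood=ll, k=k, n=len(recs),
        aic=aic, aicc=aic, sigma2_pop=s2p, sigma2_ind=s2v, dispersion=disp,
        converged=bool(res.success or res2.success),
        df_fixed=max(J - p, 1),
    )


def _wald_se(negloglik: Callable, theta: np.ndarray, p: int) -> np.ndarray:
    """Standard errors of the fixed effects from a finite-difference Hessian."""
    d = len(theta)
    h = 1e-3 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((d, d))
    f0 = negloglik(theta)
    for i in range(d):
        for j in range(i, d):
            ti = theta.copy(); ti[i] += h[i]
            tj = theta.copy(); tj[j] += h[j]
            tij = theta.copy(); tij[i] += h[i]; tij[j] += h[j]
            H[i, j] = H[j, i] = (negloglik(tij) - negloglik(ti) - negloglik(tj) + f0) / (h[i] * h[j])
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return se[:p]


def glmm_model_set(records, fst_to_reference, predictors=("temperature", "latitude"),
                   ancient: bool = False):
    """Fit the null model and every model constructible from the test predictors.

    Four models for the modern-sample design; adding ``age`` for ancient
    samples doubles the set to eight.
    """
    preds = list(predictors) + (["age"] if ancient else [])
    fits = []
    from itertools import combinations
    for k in range(len(preds) + 1):
        for combo in combinations(preds, k):
            fits.append(glmm_fit(records, fixed=combo, include_fst=not ancient,
                                 fst_to_reference=fst_to_reference))
    return fits


def lrt(null_fit: RegressionFit, full_fit: RegressionFit) -> tuple:
    """Likelihood-ratio test of nested fits: (chi2, df, p)."""
    df = full_fit.k - null_fit.k
    if df <= 0:
        raise ValueError("full model must have more parameters than the null")
    chi2 = 2.0 * (full_fit.log_likelihood - null_fit.log_likelihood)
    if chi2 < -1e-6:
        raise ValueError("full-model likelihood below null; models not nested or not converged")
    chi2 = max(chi2, 0.0)
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclasses.dataclass
class ModelComparisonRow:
    model_label: str
    rank: int
    aicc: float
    delta_aicc: float
    akaike_weight: float
    cumulative_probability: float
    in_confidence_set: bool
    k: int


def multimodel_table(fits_or_aics, labels=None, ks=None, use_aicc: bool = False,
                     confidence: float = 0.95) -> list:
    """Akaike-weight model comparison table.

    Accepts either RegressionFit objects or a raw list of AIC values (with
    optional labels and parameter counts).  Non-finite AICs are excluded with
    a warning.
    """
    rows = []
    items = list(fits_or_aics)
    if items and isinstance(items[0], RegressionFit):
        data = [(f.model_label, (f.aicc if use_aicc else f.aic), f.k) for f in items]
    else:
        labels = labels or [f"model{i + 1}" for i in range(len(items))]
        ks = ks or [np.nan] * len(items)
        data = list(zip(labels, [float(a) for a in items], ks))
    finite = [d for d in data if np.isfinite(d[1])]
    if len(finite) < len(data):
        warnings.warn("excluding models with non-finite AIC")
    if len(finite) < 1:
        raise ValueError("no finite AIC values")
    finite.sort(key=lambda d: d[1])
    amin = finite[0][1]
    deltas = np.array([a - amin for _, a, _ in finite])
    w = np.exp(-deltas / 2)
    w /= w.sum()
    cum = np.cumsum(w)
    # smallest prefix reaching the confidence level
    cut = int(np.searchsorted(cum, confidence - 1e-12)) + 1
    for i, ((label, a, k), d, wi, ci) in enumerate(zip(finite, deltas, w, cum)):
        rows.append(ModelComparisonRow(
            model_label=label, rank=i + 1, aicc=a, delta_aicc=float(d),
            akaike_weight=float(wi), cumulative_probability=float(ci),
            in_confidence_set=i < cut, k=k,
        ))
    return rows


def stability_analysis(fit_func: Callable, units: Sequence, ) -> pd.DataFrame:
    """Leave-one-unit-out refits; per-coefficient original/min/max.

    ``fit_func(units_subset)`` must return a RegressionFit.  Units are
    typically population labels.
    """
    units = list(units)
    if len(units) < 3:
        raise ValueError("need at least 3 units")
    full = fit_func(units)
    rows = {name: {"original": val, "min": val, "max": val}
            for name, val in full.coefficients.items()}
    for excl in units:
        sub = [u for u in units if u != excl]
        try:
            fit = fit_func(sub)
        except Exception:
            for d in rows.values():
                d["failed"] = True
            continue
        for name, val in fit.coefficients.items():
            if name in rows:
                rows[name]["min"] = min(rows[name]["min"], val)
                rows[name]["max"] = max(rows[name]["max"], val)
    return pd.DataFrame(rows).T


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
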