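"""Random-intercept linear mixed models for divergence responses.

The divergence responses (per-gametolog Dxy, per-gene dN/dS contrast) are
modelled with gene function (N-mt vs non-N-mt) and sex linkage (W vs Z) as
crossed fixed effects and gene identity as a random intercept:

    y_gj = Xb + u_g + e_gj,   u_g ~ N(0, sg2),  e_gj ~ N(0, se2)

Estimation is REML with the variance ratio lambda = sg2/se2 profiled out:
for fixed lambda the fixed effects have a closed-form GLS solution (the
inverse correlation matrix is block diagonal with a rank-one downdate per
gene), so fitting reduces to a deterministic 1-D bounded optimization.
Wald z-tests with a normal reference are reported per coefficient.

Reference levels are non-N-mt and Z, so the ``linkage`` coefficient measures
the W effect and the ``function:linkage`` interaction measures the extra W
effect in N-mt genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

log = logging.getLogger(__name__)

TERMS = ("Intercept", "function", "linkage", "function:linkage")


@dataclass(frozen=True)
class LmmSpec:
    response: str = "dxy"
    fixed: tuple = ("function", "linkage", "function:linkage")
    random_intercept_group: str = "gene"

    def __post_init__(self):
        if "function:linkage" in self.fixed and not {"function", "linkage"} <= set(self.fixed):
            raise ValueError("interaction requires both main effects")


@dataclass
class LmmFit:
    coefficients: dict
    se: dict
    z: dict
    p: dict
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    method: str = "reml"  # 'reml' or 'ols' fallback
    reference_levels: dict = field(default_factory=lambda: {"function": "non-N-mt", "linkage": "Z"})


def design_matrix(data: pd.DataFrame, fixed: tuple) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix; function: N-mt=1, linkage: W=1."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    f = data["function"].astype(int).to_numpy() if "function" in fixed else None
    l = (data["linkage"] == "W").astype(int).to_numpy() if "linkage" in fixed else None
    if f is not None:
        cols.append(f.astype(float)); names.append("function")
    if l is not None:
        cols.append(l.astype(float)); names.append("linkage")
    if "function:linkage" in fixed:
        cols.append((f * l).astype(float)); names.append("function:linkage")
    return np.column_stack(cols), names


def _group_stats(X, y, groups):
    """Per-group column sums of X, sums of y and group sizes."""
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    uniq, start = np.unique(go, return_index=True)
    bounds = np.append(start, len(go))
    S = np.add.reduceat(Xo, bounds[:-1], axis=0)
    t = np.add.reduceat(yo, bounds[:-1])
    ng = np.diff(bounds).astype(float)
    return S, t, ng


def _profile(lam, XtX, Xty, yty, S, t, ng, n, p):
    """GLS at fixed lambda; returns (neg2reml, beta, XtWX, sigma2_e)."""
    c = lam / (1.0 + lam * ng)
    XtWX = XtX - (S * c[:, None]).T @ S
    XtWy = Xty - S.T @ (c * t)
    yWy = yty - float(c @ (t * t))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = yWy - float(beta @ XtWy)
    rss = max(rss, 1e-300)
    sigma2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    neg2 = ((n - p) * math.log(sigma2) + float(np.log1p(lam * ng).sum())
            + logdet + (n - p))
    return neg2, beta, XtWX, sigma2


def _score(lam, XtX, Xty, yty, S, t, ng, n, p):
    """d(-2 REML log-lik)/d(lambda), analytic.

    With W_g = I - c_g J (c_g = lam/(1+lam*n_g)) the derivative reduces to
    group-level quantities: e_g = dc_g/dlam = (1+lam*n_g)^-2, residual group
    sums t_g - s_g'beta, and the GLS information matrix.
    """
    c = lam / (1.0 + lam * ng)
    e = (1.0 + lam * ng) ** -2
    XtWX = XtX - (S * c[:, None]).T @ S
    XtWy = Xty - S.T @ (c * t)
    yWy = yty - float(c @ (t * t))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(yWy - float(beta @ XtWy), 1e-300)
    resid_g = t - S @ beta
    d_rss = -float(e @ (resid_g ** 2))
    d_logdet_v = float((ng / (1.0 + lam * ng)).sum())
    A_inv_S = np.linalg.solve(XtWX, S.T)  # (p, G)
    d_logdet_a = -float(e @ np.einsum("gp,pg->g", S, A_inv_S))
    return (n - p) * d_rss / rss + d_logdet_v + d_logdet_a


def fit_random_intercept_lmm(data: pd.DataFrame, spec: LmmSpec | None = None) -> LmmFit:
    """REML fit of a gene-random-intercept model.

    ``data`` needs columns ``gene``, ``function`` (bool/0-1), ``linkage``
    ('Z'/'W') and the response named by the spec.  With no replication
    within any gene the intercept variance is inestimable and the fit falls
    back to OLS with a warning.
    """
    spec = spec or LmmSpec()
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values; filter before fitting")
    X, names = design_matrix(data, spec.fixed)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the term whose removal restores full rank
        for j in range(p - 1, -1, -1):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                raise ValueError(f"design matrix is rank deficient; term {names[j]!r} is aliased")
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError(f"too few observations ({n}) for {p} fixed effects")

    groups = data[spec.random_intercept_group].to_numpy()
    S, t, ng = _group_stats(X, y, groups)
    n_groups = len(ng)
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    if n_groups < 2 or (ng <= 1).all():
        log.warning("no within-gene replication; random intercept inestimable, using OLS")
        neg2, beta, XtWX, sigma2 = _profile(0.0, XtX, Xty, yty, S, t, ng, n, p)
        lam_hat = 0.0
        method = "ols"
    else:
        args = (XtX, Xty, yty, S, t, ng, n, p)

        def score(lam):
            return _score(lam, *args)

        if score(0.0) >= 0.0:
            lam_hat = 0.0  # boundary: no gene-level variance
        else:
            hi = 1.0
            while score(hi) < 0.0 and hi < 1e12:
                hi *= 8.0
            if score(hi) < 0.0:
                lam_hat = hi  # variance ratio effectively unbounded
            else:
                lam_hat = optimize.brentq(score, 0.0, hi, xtol=1e-14, rtol=1e-15,
                                          maxiter=500)
        neg2, beta, XtWX, sigma2 = _profile(lam_hat, XtX, Xty, yty, S, t, ng, n, p)
        method = "reml"

    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * sps.norm.sf(np.abs(zval))
    return LmmFit(
        coefficients=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        z=dict(zip(names, zval.tolist())),
        p=dict(zip(names, pval.tolist())),
        sigma2_g=lam_hat * sigma2,
        sigma2_e=sigma2,
        reml_loglik=-0.5 * neg2,
        n_obs=n,
        n_groups=n_groups,
        method=method,
    )


def interaction_and_contrasts(data: pd.DataFrame, spec: LmmSpec | None = None) -> dict:
    """Full-model fit plus per-class refits.

    Returns a report with the full fit, the Wald p of the interaction (when
    in the spec), per-linkage refits of the function effect, per-function
    refits of the linkage effect, and the ratio of the W-linkage coefficient
    between function classes (N-mt over non-N-mt).  Empty subsets are
    skipped with a log message.
    """
    spec = spec or LmmSpec()
    report: dict = {"reference_levels": {"function": "non-N-mt", "linkage": "Z"}}
    full = fit_random_intercept_lmm(data, spec)
    report["full_fit"] = full
    if "function:linkage" in spec.fixed:
        report["interaction_p"] = full.p["function:linkage"]

    report["function_effect_by_linkage"] = {}
    for linkage in ("W", "Z"):
        sub = data[data["linkage"] == linkage]
        if len(sub) == 0 or sub["function"].astype(int).nunique() < 2:
            log.info("linkage %s subset empty or single-class; contrast skipped", linkage)
            continue
        fit = fit_random_intercept_lmm(sub, LmmSpec(response=spec.response, fixed=("function",),
                                                    random_intercept_group=spec.random_intercept_group))
        report["function_effect_by_linkage"][linkage] = fit

    report["linkage_effect_by_function"] = {}
    for label, flag in (("N-mt", 1), ("non-N-mt", 0)):
        sub = data[data["function"].astype(int) == flag]
        if len(sub) == 0 or (sub["linkage"] == "W").astype(int).nunique() < 2:
            log.info("function %s subset empty or single-class; contrast skipped", label)
            continue
        fit = fit_random_intercept_lmm(sub, LmmSpec(response=spec.response, fixed=("linkage",),
                                                    random_intercept_group=spec.random_intercept_group))
        report["linkage_effect_by_function"][label] = fit

    by_fn = report["linkage_effect_by_function"]
    if {"N-mt", "non-N-mt"} <= set(by_fn):
        b_nmt = by_fn["N-mt"].coefficients["linkage"]
        b_non = by_fn["non-N-mt"].coefficients["linkage"]
        report["w_effect_ratio_nmt_over_non"] = b_nmt / b_non if b_non != 0 else math.inf
    return report
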