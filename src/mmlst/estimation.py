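"""Maximum-likelihood estimation of latent state-trait models.

The implied moment structure follows from the linear latent model: with
loadings Lambda, latent regressions B, exogenous latent covariance Psi and
error variances Theta,

    Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda' + Theta
    mu(theta)    = nu + Lambda (I-B)^-1 alpha.

Two estimators are available. Listwise ML fits complete cases via the normal
-2 log-likelihood of the sample moments. Full-information ML (FIML) groups
subjects by missing-data pattern and sums pattern-wise Gaussian
log-likelihoods over the observed coordinates, which is unbiased under
missing-at-random. On complete data the two coincide.

Gradients of the -2 log-likelihood are analytic (matrix path rules); the
observed information for standard errors is a central finite difference of
that gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import WideDataset
from .graph import CompiledModel, ParamGraph

__all__ = [
    "FitResult",
    "implied_moments",
    "fit_model",
    "standard_errors",
    "fit_indices",
    "chisq_difference_test",
    "em_saturated_moments",
]

LN2PI = math.log(2.0 * math.pi)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, theta=None):
        super().__init__(message)
        self.theta = theta


class EmptySampleError(ValueError):
    """No usable cases remain under the requested missing-data treatment."""


# ----------------------------------------------------------------- moments


@dataclass
class MomentStructure:
    """Implied covariance matrix and (optional) mean vector."""

    sigma: np.ndarray
    mu: np.ndarray | None


def implied_moments(graph: ParamGraph, theta: np.ndarray) -> MomentStructure:
    """Implied manifest moments at a parameter vector.

    ``theta`` is ordered as ``graph.compile().labels``.
    """
    model = graph.compile()
    sigma, mu = model.moments(np.asarray(theta, dtype=float))
    return MomentStructure(sigma=sigma, mu=mu)


# ------------------------------------------------------------- data groups


@dataclass
class _Group:
    """Per-missing-pattern sufficient statistics."""

    n: int
    obs: np.ndarray  # observed column indices
    s: np.ndarray  # ML (biased) covariance of the group
    ybar: np.ndarray


def _listwise_groups(data: WideDataset) -> tuple[list[_Group], int]:
    values = data.complete_cases()
    n = values.shape[0]
    if n == 0:
        raise EmptySampleError(
            "no complete cases available for listwise estimation"
        )
    ybar = values.mean(axis=0)
    centered = values - ybar
    s = centered.T @ centered / n
    obs = np.arange(values.shape[1])
    return [_Group(n=n, obs=obs, s=s, ybar=ybar)], n


def _fiml_groups(data: WideDataset) -> tuple[list[_Group], int]:
    mask = data.missing_mask
    keep = ~mask.all(axis=1)
    values = data.values[keep]
    mask = mask[keep]
    if values.shape[0] == 0:
        raise EmptySampleError("every subject is entirely missing")
    groups: list[_Group] = []
    patterns: dict[bytes, list[int]] = {}
    for r in range(values.shape[0]):
        patterns.setdefault(mask[r].tobytes(), []).append(r)
    for key, rows in patterns.items():
        obs = np.nonzero(~np.frombuffer(key, dtype=bool))[0]
        block = values[np.ix_(rows, obs)]
        ybar = block.mean(axis=0)
        centered = block - ybar
        s = centered.T @ centered / len(rows)
        groups.append(_Group(n=len(rows), obs=obs, s=s, ybar=ybar))
    return groups, values.shape[0]


# --------------------------------------------------- -2 loglik and gradient

def _chol_logdet_inv(mat: np.ndarray):
    """(log-determinant, inverse) via Cholesky; (nan, None) if not PD."""
    try:
        c = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        return float("nan"), None
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    cinv = np.linalg.inv(c)
    return logdet, cinv.T @ cinv



def _minus2ll(model: CompiledModel, theta, groups, use_means: bool) -> float:
    sigma, mu = model.moments(theta)
    total = 0.0
    for g in groups:
        sg = sigma[np.ix_(g.obs, g.obs)]
        logdet, sinv = _chol_logdet_inv(sg)
        if sinv is None:
            return 1e12
        k = len(g.obs)
        val = k * LN2PI + logdet + float(np.sum(sinv * g.s))
        if use_means:
            r = g.ybar - mu[g.obs]
            val += float(r @ sinv @ r)
        total += g.n * val
    return total


def _minus2ll_grad(model: CompiledModel, theta, groups, use_means: bool):
    """Value and analytic gradient of the -2 log-likelihood."""
    lam, gmat, psi, thet, nu, alpha = model.reduced_form(theta)
    phi = gmat @ psi @ gmat.T
    lg = lam @ gmat
    sigma = lam @ phi @ lam.T
    sigma[np.diag_indices_from(sigma)] += thet
    mu = nu + lg @ alpha if use_means else None

    p = sigma.shape[0]
    vfull = np.zeros((p, p))
    ufull = np.zeros(p)
    total = 0.0
    for g in groups:
        sg = sigma[np.ix_(g.obs, g.obs)]
        logdet, sinv = _chol_logdet_inv(sg)
        if sinv is None:
            return 1e12, np.zeros(model.n_free)
        k = len(g.obs)
        val = k * LN2PI + logdet + float(np.sum(sinv * g.s))
        inner = g.s.copy()
        if use_means:
            r = g.ybar - mu[g.obs]
            val += float(r @ sinv @ r)
            inner = inner + np.outer(r, r)
            ug = sinv @ r
            ufull[g.obs] += g.n * ug
        total += g.n * val
        vg = g.n * (sinv - sinv @ inner @ sinv)
        vfull[np.ix_(g.obs, g.obs)] += vg

    grad = np.zeros(model.n_free)
    idx = model._idx
    # shared intermediates
    vlamphi = vfull @ lam @ phi if idx["lam"] is not None else None
    abar = lam.T @ vfull @ lam
    if idx["lam"] is not None:
        r_, c_, t_ = idx["lam"]
        contrib = 2.0 * vlamphi[r_, c_]
        if use_means:
            w1 = gmat @ alpha
            contrib = contrib - 2.0 * ufull[r_] * w1[c_]
        np.add.at(grad, t_, contrib)
    if idx["theta"] is not None:
        pos, t_ = idx["theta"]
        np.add.at(grad, t_, vfull[pos, pos])
    if idx["psi"] is not None:
        amat = gmat.T @ abar @ gmat
        a_, b_, t_ = idx["psi"]
        contrib = np.where(a_ == b_, amat[a_, b_], 2.0 * amat[a_, b_])
        np.add.at(grad, t_, contrib)
    if idx["beta"] is not None:
        phiag = phi @ abar @ gmat
        r_, c_, t_ = idx["beta"]
        contrib = 2.0 * phiag[c_, r_]
        if use_means:
            w1 = gmat @ alpha
            w2 = lg.T @ ufull
            contrib = contrib - 2.0 * w2[r_] * w1[c_]
        np.add.at(grad, t_, contrib)
    if use_means and idx["nu"] is not None:
        pos, t_ = idx["nu"]
        np.add.at(grad, t_, -2.0 * ufull[pos])
    if use_means and idx["alpha"] is not None:
        w2 = lg.T @ ufull
        pos, t_ = idx["alpha"]
        np.add.at(grad, t_, -2.0 * w2[pos])
    return total, grad


# ------------------------------------------------- saturated and baseline


def _saturated_minus2ll(groups, use_means: bool) -> float:
    """Listwise saturated -2 loglik (single complete group)."""
    g = groups[0]
    k = len(g.obs)
    sign, logdet = np.linalg.slogdet(g.s)
    if sign <= 0:
        raise EmptySampleError(
            "sample covariance of complete cases is singular"
        )
    return g.n * (k * LN2PI + logdet + k)


def em_saturated_moments(
    data: WideDataset, tol: float = 1e-8, max_iter: int = 500
):
    """EM estimates of the unstructured MVN mean and covariance under MAR.

    Returns (mu, sigma, minus2ll) for the saturated model; this is the FIML
    reference point for chi-square statistics.
    """
    groups, n_used = _fiml_groups(data)
    p = data.values.shape[1]
    # initial values from observed marginals
    mu = np.zeros(p)
    var = np.ones(p)
    for j in range(p):
        col = data.values[:, j]
        obs = col[~np.isnan(col)]
        mu[j] = obs.mean()
        var[j] = max(obs.var(), 1e-6)
    sigma = np.diag(var)
    prev = np.inf
    for _ in range(max_iter):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        n_total = 0
        for g in groups:
            obs = g.obs
            mis = np.setdiff1d(np.arange(p), obs, assume_unique=True)
            soo = sigma[np.ix_(obs, obs)]
            soo_inv = np.linalg.inv(soo)
            resid = g.ybar - mu[obs]
            n_total += g.n
            if mis.size == 0:
                ey = np.zeros((p,))
                ey[obs] = g.ybar
                eyy = np.zeros((p, p))
                eyy[np.ix_(obs, obs)] = g.s + np.outer(g.ybar, g.ybar)
            else:
                smo = sigma[np.ix_(mis, obs)]
                reg = smo @ soo_inv
                m_mis = mu[mis] + reg @ resid
                cond_cov = sigma[np.ix_(mis, mis)] - reg @ smo.T
                ey = np.zeros(p)
                ey[obs] = g.ybar
                ey[mis] = m_mis
                eyy = np.zeros((p, p))
                c_oo = g.s + np.outer(g.ybar, g.ybar)
                eyy[np.ix_(obs, obs)] = c_oo
                cross = reg @ (g.s + np.outer(resid, g.ybar)) + np.outer(
                    mu[mis], g.ybar
                )
                eyy[np.ix_(mis, obs)] = cross
                eyy[np.ix_(obs, mis)] = cross.T
                mm = (
                    cond_cov
                    + reg @ (g.s + np.outer(resid, resid)) @ reg.T
                    + np.outer(mu[mis] + reg @ resid, mu[mis] + reg @ resid)
                )
                eyy[np.ix_(mis, mis)] = mm
            sum_y += g.n * ey
            sum_yy += g.n * eyy
        mu = sum_y / n_total
        sigma = sum_yy / n_total - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _mvn_minus2ll_at(groups, mu, sigma)
        if abs(prev - ll) < tol * (abs(ll) + 1.0):
            prev = ll
            break
        prev = ll
    return mu, sigma, prev


def _mvn_minus2ll_at(groups, mu, sigma) -> float:
    total = 0.0
    for g in groups:
        so = sigma[np.ix_(g.obs, g.obs)]
        sign, logdet = np.linalg.slogdet(so)
        sinv = np.linalg.inv(so)
        r = g.ybar - mu[g.obs]
        k = len(g.obs)
        total += g.n * (
            k * LN2PI
            + logdet
            + float(np.sum(sinv * g.s))
            + float(r @ sinv @ r)
        )
    return total


def _baseline_minus2ll_listwise(groups, use_means: bool) -> tuple[float, int]:
    """Independence-model -2 loglik and free-parameter count (listwise)."""
    g = groups[0]
    k = len(g.obs)
    variances = np.diag(g.s)
    val = g.n * (k * LN2PI + float(np.sum(np.log(variances))) + k)
    n_free = k + (k if use_means else 0)
    return val, n_free


def _baseline_minus2ll_fiml(data: WideDataset) -> tuple[float, int]:
    """Independence model under FIML: per-column univariate ML."""
    total = 0.0
    p = data.values.shape[1]
    for j in range(p):
        col = data.values[:, j]
        obs = col[~np.isnan(col)]
        nj = obs.size
        var = obs.var()
        total += nj * (LN2PI + math.log(var) + 1.0)
    return total, 2 * p


# ----------------------------------------------------------------- results


@dataclass
class FitResult:
    """Estimation output: estimates, likelihood, fit statistics, flags."""

    graph: ParamGraph
    model: CompiledModel
    theta: np.ndarray
    estimates: dict[str, float]
    loglik: float
    loglik_saturated: float
    loglik_baseline: float
    n_used: int
    n_free: int
    df: int
    df_baseline: int
    chisq: float
    pvalue: float
    chisq_baseline: float
    estimator: str
    converged: bool
    n_restarts_used: int
    grad_norm: float
    implied: MomentStructure
    sample_cov: np.ndarray
    sample_mean: np.ndarray | None
    negative_variances: list[str]
    latent_cov_psd: bool
    indices: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] | None = None
    zstat: dict[str, float] | None = None
    non_identified: list[str] = field(default_factory=list)

    @property
    def admissible(self) -> bool:
        return self.converged and not self.negative_variances and self.latent_cov_psd

    def parameter_table(self):
        import pandas as pd

        rows = []
        for lab in self.model.labels:
            row = {
                "label": lab,
                "role": self.graph.params[lab].role,
                "estimate": self.estimates[lab],
            }
            if self.se is not None:
                row["se"] = self.se.get(lab, float("nan"))
                row["z"] = self.zstat.get(lab, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def _augment_saturated_means(graph: ParamGraph) -> ParamGraph:
    """FIML needs a mean model; add one free mean per manifest in place.

    Leaves df unchanged: p extra modeled moments, p extra free parameters.
    """
    for row, name in enumerate(graph.manifest_names):
        if row not in graph.nu:
            graph.nu[row] = graph.new_param(f"mY_{name}", "mean", 0.0)
    graph.log.append("FIML: saturated manifest means added (df unchanged)")
    return graph


def _reference_trait_start(data: WideDataset, s: int) -> float | None:
    """Method-of-moments trait-variance start: the cross-occasion covariance
    of the reference indicator within situation s (stable variance is what
    the trait factor carries)."""
    from .design import manifest_layout

    cols = [
        j
        for j, (i, m, t, ss) in enumerate(manifest_layout(data.design))
        if (i, m, ss) == (1, 1, s)
    ]
    if len(cols) < 2:
        return None
    a, b = cols[0], cols[1]
    pair = data.values[:, [a, b]]
    pair = pair[~np.isnan(pair).any(axis=1)]
    if pair.shape[0] < 10:
        return None
    return float(np.cov(pair[:, 0], pair[:, 1], bias=True)[0, 1])


def _data_start_values(model: CompiledModel, data: WideDataset) -> np.ndarray:
    """Start values: unit loadings, intercepts/means at manifest sample
    means, zero slopes and covariances, and moment-informed variances (trait
    variance from the reference indicator's cross-occasion covariance; small
    occasion/method shares of the reference variance)."""
    theta = model.start_vector()
    graph = model.graph
    col0 = data.values[:, 0]
    obs0 = col0[~np.isnan(col0)]
    ref_var = float(obs0.var()) if obs0.size else 1.0
    if not np.isfinite(ref_var) or ref_var <= 0:
        ref_var = 1.0
    ref_mean = float(obs0.mean()) if obs0.size else 0.0
    col_means = np.array(
        [
            np.nanmean(data.values[:, j]) if (~np.isnan(data.values[:, j])).any() else 0.0
            for j in range(data.values.shape[1])
        ]
    )
    trait_starts: dict[int, float] = {}
    for s in range(1, graph.design.n_situations + 1):
        mom = _reference_trait_start(data, s)
        if mom is not None:
            trait_starts[s] = min(max(mom, 0.1 * ref_var), 2.0 * ref_var)
    # per-situation reference-indicator means (the trait means' metric)
    from .design import manifest_layout

    layout = manifest_layout(data.design)
    ref_mean_s: dict[int, float] = {}
    row_situation: dict[int, int] = {}
    for j, (i, m, t, s) in enumerate(layout):
        row_situation[j] = s
        if (i, m, t) == (1, 1, 1):
            col = data.values[:, j]
            obs = col[~np.isnan(col)]
            ref_mean_s[s] = float(obs.mean()) if obs.size else 0.0
    # map intercept/mean parameters to the first manifest they touch
    nu_rows: dict[str, int] = {}
    for row, ref in graph.nu.items():
        if ref[0] == "par" and ref[1] not in nu_rows:
            nu_rows[ref[1]] = row
    for k, lab in enumerate(model.labels):
        role = model.roles[k]
        if role == "variance":
            if lab.startswith("vT_"):
                s = graph.params[lab].indices[0]
                theta[k] = trait_starts.get(s, 0.5 * ref_var)
            elif lab.startswith("vW_"):
                s = graph.params[lab].indices[-1]
                theta[k] = 0.5 * trait_starts.get(s, 0.5 * ref_var)
            elif lab.startswith(("vO_", "vOM_")):
                theta[k] = 0.15 * ref_var
            elif lab.startswith(("vTM_", "vWTM_")):
                theta[k] = 0.25 * ref_var
            else:
                theta[k] = 0.4 * ref_var
        elif role == "loading":
            theta[k] = 1.0
        elif role in ("regression", "covariance"):
            theta[k] = 0.0
        elif role == "intercept" or role == "mean":
            if lab in nu_rows:
                row = nu_rows[lab]
                if graph.alpha:
                    # latent means are modeled: the intercept is the item
                    # mean net of the trait mean carried by the reference
                    base = ref_mean_s.get(row_situation.get(row, 1), 0.0)
                    theta[k] = col_means[row] - base
                else:
                    theta[k] = col_means[row]
            elif lab.startswith("mT_"):
                s = graph.params[lab].indices[0]
                theta[k] = ref_mean_s.get(s, ref_mean)
            else:
                theta[k] = 0.0
    return theta


def fit_model(
    data: WideDataset,
    graph: ParamGraph,
    missing: str | None = None,
    max_restarts: int = 3,
    seed: int = 0,
    compute_se: bool = False,
) -> FitResult:
    """Fit a parameter graph to wide-format data by maximum likelihood.

    ``missing`` overrides the graph options' estimator ("listwise" or
    "fiml"). Variances are unconstrained so that inadmissible (Heywood)
    solutions surface as negative estimates and are flagged, not hidden. On
    non-convergence, up to ``max_restarts`` jittered restarts (seeded) are
    attempted before a :class:`ConvergenceError` carrying the best-found
    parameters is raised.
    """
    missing = missing or graph.options.missing
    if missing not in ("listwise", "fiml"):
        raise ValueError(f"unknown missing-data treatment {missing!r}")

    if data.values.shape[1] != graph.n_manifest:
        raise ValueError(
            f"data has {data.values.shape[1]} columns, model expects "
            f"{graph.n_manifest}"
        )

    work = graph
    if missing == "fiml" and not graph.has_mean_structure:
        import copy

        work = copy.deepcopy(graph)
        _augment_saturated_means(work)
    use_means = work.has_mean_structure

    if missing == "listwise":
        groups, n_used = _listwise_groups(data)
    else:
        groups, n_used = _fiml_groups(data)

    model = work.compile()
    theta0 = _data_start_values(model, data)

    def fun(th):
        return _minus2ll_grad(model, th, groups, use_means)

    rng = np.random.default_rng(seed)
    best = None
    attempts = 0
    start = theta0
    for attempt in range(max_restarts + 1):
        attempts = attempt + 1
        res = optimize.minimize(
            fun,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-12,
                     "gtol": 1e-7},
        )
        # short polish pass: restarting L-BFGS-B refreshes its Hessian
        # approximation and reliably sharpens the optimum
        _, g_first = fun(res.x)
        if np.max(np.abs(g_first)) / max(n_used, 1) > 1e-6:
            res2 = optimize.minimize(
                fun,
                res.x,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-8},
            )
            if res2.fun <= res.fun:
                res = res2
        val, grad = fun(res.x)
        gnorm = float(np.max(np.abs(grad))) if np.ndim(grad) else np.inf
        scaled_gnorm = gnorm / max(n_used, 1)
        ok = np.isfinite(val) and val < 1e11 and scaled_gnorm < 1e-4
        if best is None or (ok and not best[3]) or (
            ok == best[3] and val < best[0]
        ):
            best = (val, res.x.copy(), gnorm, ok)
        heywood = any(
            role == "variance" and res.x[k] < 0
            for k, role in enumerate(model.roles)
        )
        if ok and not heywood:
            break
        # jittered restart; an inadmissible converged solution may be a local
        # optimum, so alternative basins are probed and the best kept
        start = theta0 + rng.normal(scale=0.1, size=theta0.size)
        for k, role in enumerate(model.roles):
            if role == "variance":
                start[k] = abs(theta0[k]) * rng.uniform(0.5, 1.5) + 0.05

    val, theta_hat, gnorm, ok = best
    if not ok:
        raise ConvergenceError(
            f"optimizer failed to converge after {attempts} attempt(s); "
            f"best -2loglik {val:.6g}, max |grad| {gnorm:.3g}",
            theta=theta_hat,
        )

    # reference logliks
    if missing == "listwise":
        sat_m2ll = _saturated_minus2ll(groups, use_means)
        base_m2ll, base_free = _baseline_minus2ll_listwise(groups, use_means)
        sample_cov = groups[0].s
        sample_mean = groups[0].ybar if use_means else None
    else:
        _, em_sigma, sat_m2ll = em_saturated_moments(data)
        base_m2ll, base_free = _baseline_minus2ll_fiml(data)
        sample_cov = em_sigma
        sample_mean = None

    p = work.n_manifest
    moments = p * (p + 1) // 2 + (p if use_means else 0)
    df = moments - model.n_free
    base_moments = moments if use_means else p * (p + 1) // 2
    df_base = base_moments - base_free

    chisq = max(val - sat_m2ll, 0.0)
    chisq_base = max(base_m2ll - sat_m2ll, 0.0)
    pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0

    estimates = {lab: float(v) for lab, v in zip(model.labels, theta_hat)}
    neg = [
        lab
        for lab, role in zip(model.labels, model.roles)
        if role == "variance" and estimates[lab] < 0
    ]
    phi, _ = model.latent_moments(theta_hat)
    eigmin = float(np.linalg.eigvalsh(phi).min()) if phi.size else 0.0
    sigma_hat, mu_hat = model.moments(theta_hat)

    fit = FitResult(
        graph=work,
        model=model,
        theta=theta_hat,
        estimates=estimates,
        loglik=-0.5 * val,
        loglik_saturated=-0.5 * sat_m2ll,
        loglik_baseline=-0.5 * base_m2ll,
        n_used=n_used,
        n_free=model.n_free,
        df=df,
        df_baseline=df_base,
        chisq=chisq,
        pvalue=pvalue,
        chisq_baseline=chisq_base,
        estimator="fiml" if missing == "fiml" else "ml_listwise",
        converged=ok,
        n_restarts_used=attempts - 1,
        grad_norm=gnorm,
        implied=MomentStructure(sigma=sigma_hat, mu=mu_hat),
        sample_cov=sample_cov,
        sample_mean=sample_mean,
        negative_variances=neg,
        latent_cov_psd=eigmin >= -1e-8,
    )
    fit.indices = _compute_indices(fit)
    if compute_se:
        standard_errors(fit, groups=groups, use_means=use_means)
    else:
        fit._groups = groups  # type: ignore[attr-defined]
        fit._use_means = use_means  # type: ignore[attr-defined]
    return fit


# --------------------------------------------------------------- inference


def standard_errors(fit: FitResult, groups=None, use_means=None):
    """Observed-information standard errors and z statistics.

    The observed information is the Hessian of the negative log-likelihood at
    the estimate, obtained by central differences of the analytic gradient.
    Parameters whose information is (numerically) singular are reported in
    ``fit.non_identified`` instead of receiving numbers.
    """
    if fit.se is not None:
        return fit.se
    if groups is None:
        groups = fit._groups  # type: ignore[attr-defined]
        use_means = fit._use_means  # type: ignore[attr-defined]
    model = fit.model
    theta = fit.theta
    k = theta.size
    hess = np.zeros((k, k))
    step = 1e-5 * np.maximum(np.abs(theta), 0.1)
    for j in range(k):
        tp = theta.copy()
        tp[j] += step[j]
        _, gp = _minus2ll_grad(model, tp, groups, use_means)
        tm = theta.copy()
        tm[j] -= step[j]
        _, gm = _minus2ll_grad(model, tm, groups, use_means)
        hess[:, j] = (gp - gm) / (2.0 * step[j])
    hess = 0.5 * (hess + hess.T)  # Hessian of -2 loglik
    info = 0.5 * hess  # Hessian of -loglik
    se = np.full(k, np.nan)
    non_identified: list[str] = []
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        bad = diag <= 0
        se[~bad] = np.sqrt(diag[~bad])
        non_identified = [model.labels[j] for j in np.nonzero(bad)[0]]
    except np.linalg.LinAlgError:
        # rank-deficient information: flag parameters in the null space
        eigval, eigvec = np.linalg.eigh(info)
        null = np.abs(eigval) < 1e-8 * max(np.abs(eigval).max(), 1.0)
        weight = (eigvec[:, null] ** 2).sum(axis=1)
        non_identified = [
            model.labels[j] for j in np.nonzero(weight > 1e-6)[0]
        ]
        pinv = np.linalg.pinv(info)
        diag = np.diag(pinv)
        good = ~np.isin(np.array(model.labels), np.array(non_identified))
        se[good & (diag > 0)] = np.sqrt(diag[good & (diag > 0)])
    fit.se = {lab: float(se[j]) for j, lab in enumerate(model.labels)}
    fit.zstat = {
        lab: (fit.estimates[lab] / fit.se[lab])
        if np.isfinite(fit.se[lab]) and fit.se[lab] > 0
        else float("nan")
        for lab in model.labels
    }
    fit.non_identified = non_identified
    return fit.se


def _rmsea_ci(chisq: float, df: int, n: int, level=0.90):
    """RMSEA confidence bounds via the noncentral chi-square."""
    if df <= 0:
        return 0.0, 0.0
    lo_q, hi_q = (1 + level) / 2.0, (1 - level) / 2.0

    def bound(q):
        # find lambda with ncx2.cdf(chisq, df, lam) = q
        if stats.chi2.cdf(chisq, df) < q:
            return 0.0
        lo, hi = 0.0, max(chisq * 2, 10.0)
        while stats.ncx2.cdf(chisq, df, hi) > q and hi < 1e7:
            hi *= 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if stats.ncx2.cdf(chisq, df, mid) > q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lam_lo = bound(lo_q)
    lam_hi = bound(hi_q)
    denom = n * df
    return math.sqrt(max(lam_lo, 0.0) / denom), math.sqrt(
        max(lam_hi, 0.0) / denom
    )


def _compute_indices(
    fit: FitResult, chisq_b: float | None = None, df_b: int | None = None
) -> dict[str, float]:
    chisq, df = fit.chisq, fit.df
    if chisq_b is None:
        chisq_b, df_b = fit.chisq_baseline, fit.df_baseline
    n = fit.n_used
    d = max(chisq - df, 0.0)
    d_b = max(chisq_b - df_b, 0.0)
    cfi = 1.0 - (d / d_b) if d_b > 0 else 1.0
    cfi = min(max(cfi, 0.0), 1.0)
    if df > 0 and df_b > 0 and chisq_b / df_b > 1.0:
        tli = ((chisq_b / df_b) - (chisq / df)) / ((chisq_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = math.sqrt(d / (df * n)) if df > 0 else 0.0
    rl, ru = _rmsea_ci(chisq, df, n)
    # SRMR from standardized covariance residuals (means excluded)
    s = fit.sample_cov
    sig = fit.implied.sigma
    dvec = np.sqrt(np.diag(s))
    denom = np.outer(dvec, dvec)
    resid = (s - sig) / denom
    tri = np.tril_indices_from(resid)
    srmr = float(np.sqrt(np.mean(resid[tri] ** 2)))
    k = fit.n_free
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * math.log(n)
    out = {
        "chisq": chisq,
        "df": float(df),
        "pvalue": fit.pvalue,
        "chisq_df_ratio": chisq / df if df > 0 else 0.0,
        "baseline_chisq": chisq_b,
        "baseline_df": float(df_b),
        "cfi": cfi,
        "tli": tli,
        "rmsea": rmsea,
        "rmsea_ci_lower": rl,
        "rmsea_ci_upper": ru,
        "srmr": srmr,
        "aic": aic,
        "bic": bic,
    }
    out["out_of_range"] = float(chisq_b < chisq)
    return out


def fit_indices(fit: FitResult, baseline: FitResult | None = None) -> dict:
    """Fit-index set with the conventional benchmark annotations.

    Benchmarks: chi2/df <= 3, CFI and TLI >= 0.90, RMSEA <= 0.08 and
    SRMR <= 0.10 count as acceptable fit. A user-supplied independence-model
    fit can replace the internally computed baseline.
    """
    if baseline is not None:
        indices = _compute_indices(fit, baseline.chisq, baseline.df)
    else:
        indices = dict(fit.indices)
    df = indices["df"]
    indices["benchmarks"] = {
        "chisq_df_ratio<=3": bool(df > 0 and indices["chisq_df_ratio"] <= 3),
        "cfi>=0.90": bool(indices["cfi"] >= 0.90),
        "tli>=0.90": bool(indices["tli"] >= 0.90),
        "rmsea<=0.08": bool(indices["rmsea"] <= 0.08),
        "srmr<=0.10": bool(indices["srmr"] <= 0.10),
    }
    return indices


def chisq_difference_test(fit_restricted: FitResult, fit_free: FitResult):
    """Likelihood-ratio test between nested fits on the same data.

    Returns (delta_chisq, delta_df, p). The restricted model must have more
    degrees of freedom; a negative difference beyond tolerance indicates a
    local optimum and is flagged via warning in the returned tuple's p=nan.
    """
    if fit_restricted.n_used != fit_free.n_used:
        raise ValueError("fits use different numbers of subjects")
    if fit_restricted.estimator != fit_free.estimator:
        raise ValueError("fits use different estimators")
    ddf = fit_restricted.df - fit_free.df
    dchi = fit_restricted.chisq - fit_free.chisq
    if fit_restricted.df == fit_free.df and abs(dchi) < 1e-6:
        return 0.0, 0, 1.0
    if ddf <= 0:
        raise ValueError(
            "models are not nested in the required direction "
            f"(delta df = {ddf})"
        )
    if dchi < -1e-4:
        import warnings

        warnings.warn(
            f"negative chi-square difference ({dchi:.4g}); the less "
            "restrictive model may not have reached its optimum",
            stacklevel=2,
        )
    p = float(stats.chi2.sf(max(dchi, 0.0), ddf))
    return float(dchi), int(ddf), p
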