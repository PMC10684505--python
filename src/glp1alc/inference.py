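"""Random-intercept mixed models, BIC model selection and power analysis.

The survey outcomes are modelled with a participant-level random
intercept and fixed effects drawn from {Group, Time, Group x Time}:

* daily drink counts — Poisson with log link,
* daily binge indicator — binomial with logit link,
* AUDIT / BAES / drinks-per-episode — Gaussian.

For the Poisson and binomial families the marginal likelihood
integrates the random intercept out with Gauss-Hermite quadrature and is
maximised directly; the Gaussian family is delegated to
``statsmodels`` ``MixedLM`` with full maximum likelihood (not REML) so
BIC values are comparable across fixed-effect structures.  BIC is
-2 loglik + p log(n_obs) with p counting fixed effects plus variance
parameters.

The a priori sample-size computation follows the conventional
repeated-measures, within-factor ANOVA calculator: noncentrality
lambda = f^2 N m eps / (1 - rho), numerator df (m-1) eps, denominator
df (N-k)(m-1) eps, power from the noncentral F distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FitResult",
    "fit_glmm",
    "candidate_fits",
    "select_by_bic",
    "effect_table",
    "power_rm_anova",
    "extrapolate_controls",
    "CANDIDATE_STRUCTURES",
]

FAMILIES = ("poisson", "binomial", "gaussian")

# the candidate fixed-effect structures ranked simplest-first
CANDIDATE_STRUCTURES: tuple[tuple[str, ...], ...] = (
    ("group",),
    ("time",),
    ("group", "time"),
    ("group", "time", "group:time"),
)


@dataclass
class FitResult:
    family: str
    terms: list[str]
    params: pd.Series  # fixed effects (coefficients B)
    se: pd.Series
    sigma_u: float  # random-intercept SD
    loglik: float
    n_obs: int
    n_params: int  # fixed + variance parameters
    converged: bool
    fixed: tuple[str, ...] = ()
    resid_sd: float | None = None  # gaussian only

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def _design(
    data: pd.DataFrame,
    fixed: tuple[str, ...],
    group_col: str,
    time_col: str,
    arm_col: str,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Treatment-coded design matrix with intercept.

    ``arm_col`` is the between-subject group (reference = first level in
    sorted order unless the column is categorical with an explicit
    order); ``time_col`` must be binary 0/1.
    """
    for t in fixed:
        if t == "group:time" and not {"group", "time"} <= set(fixed):
            raise ValueError("interaction requires both main effects")
        if t not in ("group", "time", "group:time"):
            raise ValueError(f"unknown term {t!r}")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    arm = data[arm_col]
    if isinstance(arm.dtype, pd.CategoricalDtype):
        levels = [lv for lv in arm.cat.categories if (arm == lv).any()]
    else:
        levels = sorted(arm.unique())
    time = data[time_col].to_numpy(dtype=float)
    if "group" in fixed:
        for lv in levels[1:]:
            cols.append((arm == lv).to_numpy(dtype=float))
            names.append(f"group[{lv}]")
    if "time" in fixed:
        cols.append(time)
        names.append("time")
    if "group:time" in fixed:
        for lv in levels[1:]:
            cols.append((arm == lv).to_numpy(dtype=float) * time)
            names.append(f"group[{lv}]:time")
    groups = data[group_col].to_numpy()
    return np.column_stack(cols), names, groups


def _gh_negloglik_factory(y, X, groups, family, n_nodes=201):
    """Marginal negative log likelihood over Gauss-Hermite nodes.

    Observations sharing a participant and a design row are exchangeable
    given the random intercept, so they are collapsed to sufficient
    statistics (count, outcome sum) per (participant, design-row) cell;
    per-participant contributions are then summed with
    ``np.add.reduceat`` and the node dimension collapsed with
    log-sum-exp.  Returns (value, gradient) in (beta, log sigma).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    group_codes = pd.factorize(np.asarray(groups))[0]
    if family == "poisson":
        const = -special.gammaln(y + 1).sum()
    else:
        const = 0.0
    # collapse to per-(participant, design-row) cells
    key = np.column_stack([group_codes.astype(float), X])
    cells, inverse = np.unique(key, axis=0, return_inverse=True)
    n_cell = np.bincount(inverse).astype(float)
    y_cell = np.bincount(inverse, weights=y)
    g_cell = cells[:, 0].astype(int)  # sorted: participants contiguous
    X_cell = cells[:, 1:]
    starts = np.searchsorted(g_cell, np.unique(g_cell))
    n_parts = starts.size
    part_of_cell = np.searchsorted(starts, np.arange(len(g_cell)), side="right") - 1

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X_cell @ beta  # (n_cells,)
        b = np.sqrt(2.0) * sigma * nodes  # (q,)
        lin = eta[:, None] + b[None, :]  # (n_cells, q)
        if family == "poisson":
            # clip the linear predictor at far-tail nodes whose posterior
            # weight underflows to zero anyway, avoiding exp overflow
            mu = np.exp(np.minimum(lin, 500.0))
            ll_cell = y_cell[:, None] * lin - n_cell[:, None] * mu
        else:  # binomial, logit link
            mu = special.expit(lin)
            ll_cell = y_cell[:, None] * lin - n_cell[:, None] * np.logaddexp(0.0, lin)
        per_part = np.add.reduceat(ll_cell, starts, axis=0)  # (n_parts, q)
        inner = per_part + log_w[None, :]
        ll_part = special.logsumexp(inner, axis=1)
        ll = ll_part.sum() + const
        # gradient: posterior node weights times per-cell score statistics
        post = np.exp(inner - ll_part[:, None])  # (n_parts, q)
        resid = y_cell[:, None] - n_cell[:, None] * mu  # d ll_cell / d lin
        w_cell = resid * post[part_of_cell]  # (n_cells, q)
        grad_beta = X_cell.T @ w_cell.sum(axis=1)
        grad_logsig = float((w_cell * b[None, :]).sum())  # d lin / d log sigma = b_k
        return -ll, -np.append(grad_beta, grad_logsig)

    return negloglik


def _fit_gh(y, X, names, groups, family, n_nodes=201):
    import statsmodels.api as sm

    fam = sm.families.Poisson() if family == "poisson" else sm.families.Binomial()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=fam).fit()
    x0 = np.append(glm.params, np.log(0.3))
    nll = _gh_negloglik_factory(y, X, groups, family, n_nodes)
    res = optimize.minimize(
        nll, x0, jac=True, method="BFGS", options={"maxiter": 500, "gtol": 1e-6}
    )
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-2
    theta = res.x
    p = len(names)

    # the variance MLE may sit on the sigma = 0 boundary, where the
    # marginal model collapses to the plain GLM
    nll_boundary = nll(np.append(glm.params, np.log(1e-8)))[0]
    if nll_boundary <= res.fun + 1e-8:
        return FitResult(
            family=family,
            terms=names,
            params=pd.Series(np.asarray(glm.params), index=names),
            se=pd.Series(np.asarray(glm.bse), index=names),
            sigma_u=0.0,
            loglik=float(-nll_boundary),
            n_obs=len(y),
            n_params=p + 1,
            converged=True,
        )

    # observed-information standard errors via central finite differences
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(theta, lambda th: nll(th)[0])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(theta.size, np.nan)
        converged = False
    return FitResult(
        family=family,
        terms=names,
        params=pd.Series(theta[:p], index=names),
        se=pd.Series(se_all[:p], index=names),
        sigma_u=float(np.exp(theta[-1])),
        loglik=float(-res.fun),
        n_obs=len(y),
        n_params=p + 1,
        converged=converged,
    )


def _fit_gaussian(y, X, names, groups):
    import statsmodels.api as sm

    res = None
    for method in ("lbfgs", "powell", "cg"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            try:
                res = model.fit(reml=False, method=method)
                break
            except np.linalg.LinAlgError:
                continue  # boundary variance can break one optimizer's Hessian
    if res is None:
        raise np.linalg.LinAlgError("mixed linear model failed to converge")
    var_u = float(np.asarray(res.cov_re).ravel()[0])
    return FitResult(
        family="gaussian",
        terms=names,
        params=pd.Series(np.asarray(res.fe_params), index=names),
        se=pd.Series(np.asarray(res.bse_fe), index=names),
        sigma_u=float(np.sqrt(max(var_u, 0.0))),
        loglik=float(res.llf),
        n_obs=len(y),
        n_params=len(names) + 2,  # random-intercept and residual variances
        converged=bool(res.converged),
        resid_sd=float(np.sqrt(res.scale)),
    )


def fit_glmm(
    data: pd.DataFrame,
    outcome: str,
    family: str,
    fixed: tuple[str, ...] = ("group", "time", "group:time"),
    group_col: str = "participant",
    time_col: str = "time",
    arm_col: str = "group",
    n_nodes: int = 201,
) -> FitResult:
    """Fit a random-intercept model for ``outcome``.

    ``fixed`` selects terms among {"group", "time", "group:time"} (the
    interaction requires both main effects).  Counts must be nonnegative
    integers for the Poisson family and 0/1 for the binomial family; the
    Gaussian family uses ML so BIC is comparable across candidates.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y = data[outcome].to_numpy(dtype=float)
    if family == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson outcome must be nonnegative integer counts")
    if family == "binomial":
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("binomial outcome must be 0/1")
    X, names, groups = _design(data, fixed, group_col, time_col, arm_col)
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        raise ValueError("random-intercept fit needs >= 2 observations per participant")
    if family == "gaussian":
        fit = _fit_gaussian(y, X, names, groups)
    else:
        fit = _fit_gh(y, X, names, groups, family, n_nodes)
    fit.fixed = tuple(fixed)
    if not fit.converged:
        warnings.warn(f"{family} fit with terms {fixed} did not converge cleanly")
    return fit


def candidate_fits(data, outcome, family, **kwargs) -> list[FitResult]:
    """Fit the four candidate fixed-effect structures."""
    return [fit_glmm(data, outcome, family, fixed=f, **kwargs) for f in CANDIDATE_STRUCTURES]


def select_by_bic(fits: list[FitResult]) -> tuple[FitResult, list[FitResult]]:
    """Minimum-BIC fit among converged candidates (ties -> fewer params)."""
    usable = [f for f in fits if f.converged]
    dropped = len(fits) - len(usable)
    if dropped:
        warnings.warn(f"excluding {dropped} non-converged fit(s) from selection")
    if not usable:
        raise ValueError("no converged fits to select from")
    ranking = sorted(usable, key=lambda f: (f.bic, f.n_params))
    return ranking[0], ranking


def effect_table(fit: FitResult, z: float = 1.96) -> pd.DataFrame:
    """Per-term estimates with Wald 95% CIs.

    Non-Gaussian families add the exponentiated scale: incidence-rate
    ratios (Poisson/log) or odds ratios (binomial/logit).
    """
    if not fit.converged:
        raise ValueError("effect table requires a converged fit")
    rows = []
    for term in fit.terms:
        b = float(fit.params[term])
        se = float(fit.se[term])
        row = {
            "term": term,
            "estimate": b,
            "se": se,
            "ci_low": b - z * se,
            "ci_high": b + z * se,
        }
        if fit.family != "gaussian":
            label = "irr" if fit.family == "poisson" else "or"
            row[label] = np.exp(b)
            row[f"{label}_ci_low"] = np.exp(b - z * se)
            row[f"{label}_ci_high"] = np.exp(b + z * se)
        rows.append(row)
    return pd.DataFrame(rows)


def _rm_anova_power(
    N: int, f: float, alpha: float, k: int, m: int, rho: float, eps: float
) -> float:
    lam = f * f * N * m * eps / (1.0 - rho)
    df1 = (m - 1) * eps
    df2 = (N - k) * (m - 1) * eps
    if df2 <= 0:
        return 0.0
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def power_rm_anova(
    f: float,
    alpha: float,
    power: float,
    k_groups: int,
    m_measurements: int,
    rho: float = 0.5,
    eps: float = 1.0,
    n_max: int = 10**6,
) -> tuple[int, float]:
    """Minimal total N for a within-factor repeated-measures ANOVA.

    Searches the smallest N reaching the target power under the
    noncentral-F parameterisation above, then rounds N up to an equal
    allocation across ``k_groups``.  Returns (N, achieved power at N).
    """
    if not (f > 0 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("need f > 0, 0 < alpha < 1, 0 < power < 1")
    if m_measurements < 2 or not (0 <= rho < 1) or eps <= 0:
        raise ValueError("need m >= 2, rho in [0,1), eps > 0")
    N = k_groups + 1
    while _rm_anova_power(N, f, alpha, k_groups, m_measurements, rho, eps) < power:
        N += 1
        if N > n_max:
            raise ValueError(f"target power unreachable at N <= {n_max}")
    if N % k_groups:
        N += k_groups - (N % k_groups)
    achieved = _rm_anova_power(N, f, alpha, k_groups, m_measurements, rho, eps)
    return N, achieved


def extrapolate_controls(n_medication: int, k_medication_groups: int) -> int:
    """Add one control group of per-group size: total = N + N/k."""
    if n_medication % k_medication_groups:
        raise ValueError(
            f"N={n_medication} is not divisible across {k_medication_groups} groups"
        )
    return n_medication + n_medication // k_medication_groups
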