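"""Minimal fully-conditional-specification (chained-equations) imputation engine.

Supports Bayesian normal-linear regression, type-1 predictive mean matching,
and logistic regression imputation, plus joint (x, x^2) block methods from
:mod:`overimpute.quadratic`. Cells to draw are given by a "where" mask, which
covers every genuinely missing cell and may additionally mark observed cells
for over-imputation; over-imputed rows never contribute to model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .datasets import IncompleteDataset, MultipleImputations

NORM = "norm"
PMM = "pmm"
LOGREG = "logreg"
PC = "pc"
SMCFCS = "smcfcs"
NONE = "none"
_METHODS = {NORM, PMM, LOGREG, PC, SMCFCS, NONE}
_BLOCK_METHODS = {PC, SMCFCS}


@dataclass
class ParameterDraw:
    """Estimates and one posterior draw of a univariate regression model."""

    beta_hat: np.ndarray
    beta_star: np.ndarray
    sigma_star: float | None = None  # residual SD draw; None for logistic

    def __post_init__(self) -> None:
        if self.sigma_star is not None and self.sigma_star < 0:
            raise ValueError("sigma_star must be nonnegative")


@dataclass
class MethodSpec:
    """Per-variable imputation methods and admitted predictors.

    ``methods`` maps variable name to one of norm / pmm / logreg / pc /
    smcfcs / none; unlisted variables default to "none". ``predictors`` maps
    a variable to the names it may condition on (an intercept is always
    added). ``square_pairs`` maps a base variable to its squared companion
    for the joint pc / smcfcs block methods.
    """

    methods: dict[str, str]
    predictors: dict[str, list[str]]
    pmm_donors: int = 5
    square_pairs: dict[str, str] = field(default_factory=dict)
    max_reject: int = 10_000

    def __post_init__(self) -> None:
        for name, meth in self.methods.items():
            if meth not in _METHODS:
                raise ValueError(f"unknown method {meth!r} for {name!r}")
        for name, preds in self.predictors.items():
            if name in preds:
                raise ValueError(f"variable {name!r} may not predict itself")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be >= 1")

    def method_for(self, name: str) -> str:
        return self.methods.get(name, NONE)

    def predictor_matrix(self, var_names: list[str]) -> np.ndarray:
        """p x p boolean matrix; row = target, column = admitted predictor."""
        p = len(var_names)
        idx = {name: j for j, name in enumerate(var_names)}
        mat = np.zeros((p, p), dtype=bool)
        for name, preds in self.predictors.items():
            for q in preds:
                mat[idx[name], idx[q]] = True
        return mat


# ---------------------------------------------------------------------------
# Bayesian linear regression draws
# ---------------------------------------------------------------------------


def _collinear_columns(X: np.ndarray, names=None) -> list:
    """Identify (near-)dependent columns via a pivoted QR."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [int(piv[k]) for k in range(len(d)) if d[k] <= tol]
    if names is not None:
        bad = [names[j] for j in bad]
    return bad


def draw_linear_params(
    y: np.ndarray, X: np.ndarray, rng: np.random.Generator, names=None
) -> ParameterDraw:
    """Noninformative-prior posterior draw for a normal linear model.

    sigma*^2 = SSE / chi2_{n-q}, then beta* | sigma* ~ N(beta_hat,
    sigma*^2 (X'X)^{-1}).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, q = X.shape
    if len(y) != n:
        raise ValueError("y and X row counts differ")
    if n <= q:
        raise ValueError(
            f"need more rows than parameters to fit ({n} rows, {q} coefficients)"
        )
    xtx = X.T @ X
    try:
        low = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        low = None
    diag = None if low is None else np.diag(low)
    # squared diagonal ratio estimates rcond of X'X
    if low is None or (diag.min() / diag.max()) ** 2 <= max(n, q) * np.finfo(float).eps:
        bad = _collinear_columns(X, names)
        raise ValueError(f"singular design matrix; collinear columns: {bad}")
    beta_hat = sla.cho_solve((low, True), X.T @ y)
    resid = y - X @ beta_hat
    sse = float(resid @ resid)
    sigma2_star = sse / rng.chisquare(n - q)
    sigma_star = float(np.sqrt(sigma2_star))
    z = rng.standard_normal(q)
    # chol(sigma^2 (X'X)^{-1}) z == sigma * solve(L', z) with L L' = X'X
    beta_star = beta_hat + sigma_star * sla.solve_triangular(low, z, lower=True, trans="T")
    return ParameterDraw(beta_hat, beta_star, sigma_star)


def impute_normal(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_targets: np.ndarray,
    rng: np.random.Generator,
    names=None,
) -> np.ndarray:
    """Draw target values under a Bayesian normal linear imputation model."""
    params = draw_linear_params(y_obs, X_obs, rng, names=names)
    X_targets = np.asarray(X_targets, dtype=float)
    noise = params.sigma_star * rng.standard_normal(X_targets.shape[0])
    return X_targets @ params.beta_star + noise


# ---------------------------------------------------------------------------
# Predictive mean matching (type 1)
# ---------------------------------------------------------------------------


def pmm_match(
    yhat_obs: np.ndarray,
    yhat_target: np.ndarray,
    y_obs: np.ndarray,
    d: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each target prediction, draw uniformly from the d observed rows
    with the closest predicted means; distance ties broken uniformly."""
    yhat_obs = np.asarray(yhat_obs, dtype=float)
    yhat_target = np.asarray(yhat_target, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    n_obs = len(y_obs)
    if d < 1 or d > n_obs:
        raise ValueError(f"donor count d={d} must be in [1, {n_obs}]")
    dist = np.abs(yhat_obs[None, :] - yhat_target[:, None])
    if len(np.unique(yhat_obs)) < n_obs:
        # duplicate predictions: break ties uniformly and independently per
        # target with a tiny jitter that cannot disturb the real ordering
        gaps = np.diff(np.unique(yhat_obs))
        resol = gaps[gaps > 0].min() if np.any(gaps > 0) else 1.0
        dist = dist + rng.random(dist.shape) * (1e-3 * resol)
    if d < n_obs:
        nearest = np.argpartition(dist, d - 1, axis=1)[:, :d]
    else:
        nearest = np.broadcast_to(np.arange(n_obs), dist.shape).copy()
    pick = rng.integers(0, d, size=len(yhat_target))
    donors = nearest[np.arange(len(yhat_target)), pick]
    return y_obs[donors]


def impute_pmm(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_targets: np.ndarray,
    d: int = 5,
    rng: np.random.Generator | None = None,
    names=None,
) -> np.ndarray:
    """Type-1 predictive mean matching.

    Predicted means for the observed rows use the least-squares estimate
    beta_hat; those for the target rows use a posterior draw beta*, so that
    parameter uncertainty propagates into donor selection.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    params = draw_linear_params(y_obs, X_obs, rng, names=names)
    yhat_obs = np.asarray(X_obs, dtype=float) @ params.beta_hat
    yhat_target = np.asarray(X_targets, dtype=float) @ params.beta_star
    return pmm_match(yhat_obs, yhat_target, np.asarray(y_obs, float), d, rng)


# ---------------------------------------------------------------------------
# Logistic imputation
# ---------------------------------------------------------------------------


def impute_logistic(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_targets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bayesian logistic imputation via the asymptotic normal posterior.

    beta* ~ N(beta_hat, I^{-1}) around the ML fit; imputations are
    Bernoulli(expit(X_targets beta*)). A constant observed outcome is the
    degenerate limit with no identifiable slope: the success probability is
    then drawn from its Jeffreys Beta posterior instead.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X_obs = np.asarray(X_obs, dtype=float)
    X_targets = np.asarray(X_targets, dtype=float)
    if not np.isin(y_obs, (0.0, 1.0)).all():
        raise ValueError("logistic imputation needs a 0/1 outcome")
    n_t = X_targets.shape[0]
    if y_obs.min() == y_obs.max():
        # degenerate: all observed outcomes equal; Jeffreys Beta(k+1/2, n-k+1/2)
        k = float(y_obs.sum())
        p_star = rng.beta(k + 0.5, len(y_obs) - k + 0.5)
        return (rng.random(n_t) < p_star).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "perfect separation in logistic imputation model: the observed "
            "outcome is exactly predicted by the covariates, so the ML fit "
            "does not exist"
        ) from exc
    if not res.mle_retvals.get("converged", False) or not np.all(
        np.isfinite(res.params)
    ):
        raise ValueError(
            "logistic ML fit did not converge (possible quasi-separation)"
        )
    cov = np.asarray(res.cov_params())
    low = np.linalg.cholesky(cov)
    beta_star = np.asarray(res.params) + low @ rng.standard_normal(len(res.params))
    p = expit(X_targets @ beta_star)
    return (rng.random(n_t) < p).astype(float)


# ---------------------------------------------------------------------------
# FCS sweep
# ---------------------------------------------------------------------------


def _imputation_units(
    data: IncompleteDataset, spec: MethodSpec, where: np.ndarray
) -> list[tuple]:
    """Group marked columns into update units (singles and (x, x^2) blocks),
    in column order, validating the method assignment."""
    marked_cols = [j for j in range(data.n_cols) if where[:, j].any()]
    marked_names = {data.var_names[j] for j in marked_cols}
    sq_of = dict(spec.square_pairs)
    base_of = {v: k for k, v in sq_of.items()}
    units: list[tuple] = []
    handled: set[str] = set()
    for j in marked_cols:
        name = data.var_names[j]
        if name in handled:
            continue
        meth = spec.method_for(name)
        if meth == NONE:
            raise ValueError(f"variable {name!r} has cells to impute but method 'none'")
        if meth in _BLOCK_METHODS:
            base = base_of.get(name, name)
            if base not in sq_of:
                raise ValueError(
                    f"method {meth!r} for {name!r} needs a square_pairs entry"
                )
            sq = sq_of[base]
            jb, js = data.column(base), data.column(sq)
            if not np.array_equal(where[:, jb], where[:, js]):
                raise ValueError(
                    f"block ({base}, {sq}) must be marked in the same rows"
                )
            units.append(("block", meth, jb, js))
            handled.update((base, sq))
        else:
            units.append(("single", meth, j, None))
            handled.add(name)
    # enforce the iff: a non-"none" method on a column with nothing to impute
    for name, meth in spec.methods.items():
        if meth != NONE and name not in marked_names:
            raise ValueError(
                f"variable {name!r} has method {meth!r} but no cells to impute; "
                "use 'none' for fully observed, non-over-imputed variables"
            )
    return units


def _predictor_indices(data: IncompleteDataset, spec: MethodSpec, name: str) -> list[int]:
    preds = spec.predictors.get(name, [])
    return [data.column(q) for q in preds]


def fcs_impute(
    data: IncompleteDataset,
    spec: MethodSpec,
    where: np.ndarray | None = None,
    m: int = 5,
    n_iter: int | None = None,
    seed: int | None = None,
) -> MultipleImputations:
    """Multiply impute every cell marked in ``where`` by chained equations.

    Each of the m streams starts from a random draw from the observed values
    of each variable, then sweeps the incomplete variables in column order
    ``n_iter`` times. Models are refit at every visit on the rows where the
    target is genuinely observed and not marked for over-imputation. Streams
    use seed-derived substreams, so results are reproducible and earlier
    streams are unchanged when m grows.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if where is None:
        where = ~data.observed_mask
    else:
        where = np.asarray(where, dtype=bool)
        if where.shape != data.values.shape:
            raise ValueError("where mask shape mismatch")
        if np.any(~data.observed_mask & ~where):
            raise ValueError("every genuinely missing cell must be marked in where")

    from . import quadratic  # deferred: quadratic imports draw_linear_params

    units = _imputation_units(data, spec, where)
    # predictors must be observed or themselves imputed somewhere
    for kind, meth, j, js in units:
        name = data.var_names[j]
        for q in spec.predictors.get(name, []):
            jq = data.column(q)
            unreachable = ~data.observed_mask[:, jq] & ~where[:, jq]
            if unreachable.any():
                raise ValueError(
                    f"predictor {q!r} of {name!r} has cells that are never filled"
                )
    if n_iter is None:
        n_iter = 1 if len(units) <= 1 else 5
    # a single unit has no cross-variable feedback: extra sweeps would only
    # re-draw from the same distribution, so clamp for exact reproducibility
    if len(units) <= 1:
        n_iter = 1
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    n, p = data.values.shape
    completed = np.empty((m, n, p))
    streams = np.random.SeedSequence(seed).spawn(m)
    for s, child in enumerate(streams):
        rng = np.random.default_rng(child)
        work = data.values.copy()
        # initial fill: random draws from each variable's observed values
        for kind, meth, j, js in units:
            for col in (j, js) if js is not None else (j,):
                marked = where[:, col]
                pool = data.values[data.observed_mask[:, col], col]
                if pool.size == 0:
                    raise ValueError(
                        f"variable {data.var_names[col]!r} has no observed values"
                    )
                work[marked, col] = rng.choice(pool, size=int(marked.sum()))
        for _ in range(n_iter):
            for kind, meth, j, js in units:
                name = data.var_names[j]
                marked = where[:, j]
                if kind == "single":
                    fit = data.observed_mask[:, j] & ~where[:, j]
                    pred_idx = _predictor_indices(data, spec, name)
                    X = np.column_stack([np.ones(n), work[:, pred_idx]])
                    pred_names = ["(intercept)"] + [data.var_names[q] for q in pred_idx]
                    y_fit = work[fit, j]
                    if meth == NORM:
                        draws = impute_normal(
                            y_fit, X[fit], X[marked], rng, names=pred_names
                        )
                    elif meth == PMM:
                        draws = impute_pmm(
                            y_fit, X[fit], X[marked],
                            d=spec.pmm_donors, rng=rng, names=pred_names,
                        )
                    elif meth == LOGREG:
                        draws = impute_logistic(y_fit, X[fit], X[marked], rng)
                    else:  # pragma: no cover - guarded in _imputation_units
                        raise ValueError(f"unhandled method {meth!r}")
                    work[marked, j] = draws
                else:  # (x, x^2) block
                    preds = [
                        q for q in spec.predictors.get(name, [])
                        if q != data.var_names[js]
                    ]
                    if len(preds) != 1:
                        raise ValueError(
                            f"block method for {name!r} needs exactly one outcome "
                            f"predictor besides its square; got {preds}"
                        )
                    y_col = work[:, data.column(preds[0])]
                    x_col = work[:, j].copy()
                    x_col[marked] = np.nan
                    if meth == PC:
                        pairs = quadratic.impute_pc(
                            y_col, x_col, marked, d=spec.pmm_donors, rng=rng
                        )
                    else:
                        pairs = quadratic.impute_smcfcs_quadratic(
                            y_col, x_col, marked, rng=rng, max_reject=spec.max_reject
                        )
                    work[marked, j] = pairs[:, 0]
                    work[marked, js] = pairs[:, 1]
        completed[s] = work
    return MultipleImputations(
        completed, where, list(data.var_names), seed=seed, iterations=n_iter
    )
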