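"""Joint imputation of a covariate and its square under a quadratic model.

Two methods for the substantive model Y = alpha + beta1 X + beta2 X^2 + eps
with (X, X^2) jointly missing: the polynomial-combination (PC) hot-deck and a
substantive-model-compatible rejection sampler (SMC-FCS). Both return (x, x^2)
pairs that satisfy the square constraint exactly — the property that plain
per-column predictive mean matching breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm as norm_dist
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .engine import ParameterDraw, draw_linear_params, pmm_match


@dataclass
class QuadraticModelDraw:
    """One posterior draw of the quadratic substantive model."""

    alpha_star: float
    beta1_star: float
    beta2_star: float
    sigma_star: float

    def __post_init__(self) -> None:
        if self.sigma_star < 0:
            raise ValueError("sigma_star must be nonnegative")


def _quadratic_design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones_like(x), x, x * x])


def solve_parabola_arms(b1: float, b2: float, c: np.ndarray):
    """Roots of b2 x^2 + b1 x - c = 0 as (left arm, right arm).

    With b2 = 0 the equation is linear and both arms coincide at c / b1.
    Requires a nonnegative discriminant.
    """
    c = np.asarray(c, dtype=float)
    if abs(b2) < 1e-12:
        if abs(b1) < 1e-12:
            raise ValueError("degenerate combination: b1 = b2 = 0")
        x = c / b1
        return x, x
    disc = b1 * b1 + 4.0 * b2 * c
    if np.any(disc < 0):
        raise ValueError("negative discriminant: combination value unreachable")
    half_span = np.sqrt(disc) / (2.0 * abs(b2))
    vertex = -b1 / (2.0 * b2)
    return vertex - half_span, vertex + half_span


def _right_arm_probability(
    arm_obs: np.ndarray, y_obs: np.ndarray, y_mis: np.ndarray
) -> np.ndarray:
    """P(right parabola arm | y) via logistic regression of the observed arm
    indicator on y; falls back to the empirical arm share when the indicator
    is (nearly) constant or the fit separates."""
    share = float(arm_obs.mean())
    if share < 1e-12 or share > 1 - 1e-12:
        return np.full(len(y_mis), share)
    X = np.column_stack([np.ones_like(y_obs), y_obs])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(arm_obs, X).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", False):
            raise PerfectSeparationError
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return np.full(len(y_mis), share)
    return expit(np.column_stack([np.ones_like(y_mis), y_mis]) @ res.params)


def impute_pc(
    y: np.ndarray,
    x: np.ndarray,
    missing: np.ndarray,
    d: int = 5,
    rng: np.random.Generator | None = None,
    on_negative: str = "redraw",
    max_redraw: int = 100,
) -> np.ndarray:
    """Polynomial-combination imputation of jointly missing (x, x^2).

    Fits the quadratic regression of y on (x, x^2) over the observed rows,
    forms the combination c = b1 x + b2 x^2, imputes c for the missing rows
    by type-1 predictive mean matching on y, solves the quadratic for x, and
    picks the parabola arm with a probability from a logistic model of the
    observed arm indicator on y.

    Returns an (n_missing, 2) array of (x, x^2) pairs with the square
    constraint holding exactly.
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    y = np.asarray(y, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    x = np.asarray(x, dtype=float)
    obs = ~missing
    y_obs, x_obs = y[obs], x[obs]
    if not np.all(np.isfinite(x_obs)):
        raise ValueError("observed x must be finite")
    params = draw_linear_params(y_obs, _quadratic_design(x_obs), rng)
    _, b1, b2 = params.beta_hat
    c_obs = b1 * x_obs + b2 * x_obs * x_obs
    y_mis = y[missing]

    design_obs = np.column_stack([np.ones_like(y_obs), y_obs])
    design_mis = np.column_stack([np.ones_like(y_mis), y_mis])
    for attempt in range(max_redraw + 1):
        cpar = draw_linear_params(c_obs, design_obs, rng)
        chat_obs = design_obs @ cpar.beta_hat
        chat_mis = design_mis @ cpar.beta_star
        c_imp = pmm_match(chat_obs, chat_mis, c_obs, d, rng)
        # donor c values are b1 x + b2 x^2 of observed x, so the discriminant
        # (b1 + 2 b2 x_donor)^2 is nonnegative by construction; the guard
        # covers degenerate numerics only
        disc_ok = (abs(b2) < 1e-12) or np.all(b1 * b1 + 4.0 * b2 * c_imp >= 0)
        if disc_ok:
            break
        if on_negative == "error":
            raise ValueError("negative discriminant for an imputed combination")
    else:
        raise ValueError(
            f"negative discriminant persisted over {max_redraw} re-draws"
        )

    x_left, x_right = solve_parabola_arms(b1, b2, c_imp)
    if abs(b2) < 1e-12:
        x_imp = x_right
    else:
        vertex = -b1 / (2.0 * b2)
        arm_obs = (x_obs > vertex).astype(float)
        p_right = _right_arm_probability(arm_obs, y_obs, y_mis)
        take_right = rng.random(len(y_mis)) < p_right
        x_imp = np.where(take_right, x_right, x_left)
    return np.column_stack([x_imp, x_imp * x_imp])


# ---------------------------------------------------------------------------
# SMC-FCS
# ---------------------------------------------------------------------------


def smcfcs_reject(
    y_mis: np.ndarray,
    mu: float,
    tau: float,
    draw: QuadraticModelDraw,
    rng: np.random.Generator,
    max_reject: int = 10_000,
    grid_size: int = 512,
    row_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Rejection sampler for x | y under the quadratic substantive model.

    Proposes x ~ N(mu, tau^2) and accepts with probability
    f(y | x, theta) / c, where c bounds the conditional density over a wide
    grid of x. The accepted draws follow p(x | y) ∝ phi_{mu,tau}(x) f(y | x).
    """
    y_mis = np.asarray(y_mis, dtype=float)
    n_mis = len(y_mis)
    a, b1, b2, sigma = (
        draw.alpha_star, draw.beta1_star, draw.beta2_star, draw.sigma_star,
    )
    if sigma <= 0:
        raise ValueError("sigma_star must be positive for rejection sampling")
    grid = mu + tau * np.linspace(-8.0, 8.0, grid_size)
    g = a + b1 * grid + b2 * grid * grid
    dens = norm_dist.pdf(y_mis[:, None], loc=g[None, :], scale=sigma)
    bound = dens.max(axis=1) * 1.05  # small pad: grid max can undershoot
    bound = np.maximum(bound, 1e-300)

    x_out = np.empty(n_mis)
    remaining = np.arange(n_mis)
    attempts = np.zeros(n_mis, dtype=int)
    chunk = 64  # proposals per row per pass; pure efficiency, no bias
    while remaining.size:
        if attempts[remaining].min() >= max_reject:
            row = remaining[np.argmax(attempts[remaining])]
            label = row if row_labels is None else row_labels[row]
            raise ValueError(
                f"rejection sampling did not accept within {max_reject} "
                f"proposals for row {label}"
            )
        r = remaining.size
        prop = rng.normal(mu, tau, size=(r, chunk))
        f = norm_dist.pdf(
            y_mis[remaining, None], loc=a + b1 * prop + b2 * prop * prop, scale=sigma
        )
        accept = rng.random((r, chunk)) * bound[remaining, None] < f
        any_hit = accept.any(axis=1)
        first = accept.argmax(axis=1)
        hits = remaining[any_hit]
        x_out[hits] = prop[any_hit, first[any_hit]]
        attempts[remaining] += chunk
        remaining = remaining[~any_hit]
    return x_out


def impute_smcfcs_quadratic(
    y: np.ndarray,
    x: np.ndarray,
    missing: np.ndarray,
    rng: np.random.Generator | None = None,
    max_reject: int = 10_000,
) -> np.ndarray:
    """Substantive-model-compatible imputation of jointly missing (x, x^2).

    Draws the quadratic-model parameters from their posterior given the
    observed rows, draws the normal covariate-model parameters (mu, tau) from
    their posterior given observed x, and rejection-samples x for each
    missing row so the imputations are exactly compatible with the stated
    substantive model. Returns (n_missing, 2) pairs (x, x^2).
    """
    if rng is None:
        raise ValueError("an explicit rng is required")
    y = np.asarray(y, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    x = np.asarray(x, dtype=float)
    obs = ~missing
    y_obs, x_obs = y[obs], x[obs]
    params = draw_linear_params(y_obs, _quadratic_design(x_obs), rng)
    draw = QuadraticModelDraw(*params.beta_star, params.sigma_star)
    # covariate model x ~ N(mu, tau^2), noninformative-prior posterior draw
    n_o = len(x_obs)
    if n_o < 3:
        raise ValueError("need at least 3 observed x values")
    xbar = float(x_obs.mean())
    ss = float(((x_obs - xbar) ** 2).sum())
    tau2 = ss / rng.chisquare(n_o - 1)
    mu = xbar + np.sqrt(tau2 / n_o) * rng.standard_normal()
    tau = float(np.sqrt(tau2))
    x_imp = smcfcs_reject(
        y[missing], mu, tau, draw, rng,
        max_reject=max_reject, row_labels=np.flatnonzero(missing),
    )
    return np.column_stack([x_imp, x_imp * x_imp])
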