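"""Posterior predictive checking of imputation models by over-imputation.

The central design duplicates every case observed on the target variable,
blanks the target in the duplicates, and multiply imputes the blanks. Each
observed value is then compared to its own m-draw empirical posterior
predictive distribution, summarized by coverage (COV), mean absolute
distance from the replicate means (Distance), mean interval width (CIW) for
continuous targets, and the mean squared deviance for binary targets.
Classical completed-data posterior predictive p-values are provided through
a plug-in test-quantity interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import BINARY, CONTINUOUS, IncompleteDataset, MultipleImputations


# ---------------------------------------------------------------------------
# Over-imputation design
# ---------------------------------------------------------------------------


@dataclass
class OverimputationDesign:
    """The duplicate-and-blank layout fed to the imputation engine.

    Rows 0..n_original-1 are the cases observed on the target (incomplete
    target cases are dropped); rows n_original..2*n_original-1 are their
    duplicates with the target blanked. ``where`` marks every blanked cell
    plus any genuinely missing cell of the other variables.
    """

    data: IncompleteDataset
    where: np.ndarray
    targets: tuple[str, ...]
    n_original: int
    source_rows: np.ndarray  # augmented row index of each duplicate's source
    duplicate_rows: np.ndarray


def build_overimputation_design(
    data: IncompleteDataset, target: str | Sequence[str]
) -> OverimputationDesign:
    """Remove target-incomplete cases, duplicate the rest, blank the target
    in the duplicates, and mark the blanks for imputation."""
    targets = (target,) if isinstance(target, str) else tuple(target)
    t_idx = [data.column(t) for t in targets]
    observed = data.observed_mask[:, t_idx].all(axis=1)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise ValueError(f"target {targets} is fully missing")
    if n_obs < 2:
        raise ValueError("need at least 2 rows observed on the target")

    kept_vals = data.values[observed]
    kept_mask = data.observed_mask[observed]
    dup_vals = kept_vals.copy()
    dup_mask = kept_mask.copy()
    dup_vals[:, t_idx] = np.nan
    dup_mask[:, t_idx] = False

    values = np.vstack([kept_vals, dup_vals])
    mask = np.vstack([kept_mask, dup_mask])
    augmented = IncompleteDataset(values, mask, data.var_names, data.var_kinds)
    where = ~mask  # blanked target cells plus remaining genuine missingness
    return OverimputationDesign(
        data=augmented,
        where=where,
        targets=targets,
        n_original=n_obs,
        source_rows=np.arange(n_obs),
        duplicate_rows=np.arange(n_obs, 2 * n_obs),
    )


# ---------------------------------------------------------------------------
# Replicate summaries
# ---------------------------------------------------------------------------


@dataclass
class ReplicateMatrix:
    """Observed target values with their m replicate draws (one row per
    observed case)."""

    obs: np.ndarray  # (n_obs,)
    draws: np.ndarray  # (n_obs, m)
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=float)
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or len(self.obs) != self.draws.shape[0]:
            raise ValueError("draws must be (n_obs, m)")
        if not (np.all(np.isfinite(self.obs)) and np.all(np.isfinite(self.draws))):
            raise ValueError("replicate matrix must be fully observed and finite")
        if self.kind not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def m(self) -> int:
        return self.draws.shape[1]


def extract_replicates(
    design: OverimputationDesign,
    imputations: MultipleImputations,
    target: str | None = None,
) -> ReplicateMatrix:
    """Collect the observed values and their over-imputed draws for one
    target variable of an over-imputation design."""
    name = design.targets[0] if target is None else target
    if name not in design.targets:
        raise ValueError(f"{name!r} is not a target of this design")
    j = design.data.column(name)
    obs = design.data.values[design.source_rows, j]
    draws = imputations.completed[:, design.duplicate_rows, j].T
    kind = design.data.var_kinds[j]
    return ReplicateMatrix(obs, draws, kind)


@dataclass
class ReplicateSummary:
    """Per-observation predictive intervals and their aggregates."""

    level: float
    obs: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    center: np.ndarray
    covered: np.ndarray
    cov: float
    distance: float
    ciw: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "obs": self.obs,
                "center": self.center,
                "lower": self.lower,
                "upper": self.upper,
                "covered": self.covered,
            }
        )


def summarize_replicates(rep: ReplicateMatrix, level: float = 0.95) -> ReplicateSummary:
    """Empirical per-point intervals and the COV / Distance / CIW aggregates.

    Bounds are the alpha/2 and 1-alpha/2 empirical quantiles of the m draws
    (linear interpolation of order statistics); the center is their mean.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if rep.m < 2:
        raise ValueError("need at least 2 replicates per observation")
    alpha = 1.0 - level
    lower, upper = np.quantile(
        rep.draws, [alpha / 2.0, 1.0 - alpha / 2.0], axis=1, method="linear"
    )
    center = rep.draws.mean(axis=1)
    covered = (rep.obs >= lower) & (rep.obs <= upper)
    return ReplicateSummary(
        level=level,
        obs=rep.obs,
        lower=lower,
        upper=upper,
        center=center,
        covered=covered,
        cov=float(covered.mean()),
        distance=float(np.abs(rep.obs - center).mean()),
        ciw=float((upper - lower).mean()),
    )


def replicate_probabilities(rep: ReplicateMatrix) -> np.ndarray:
    """Per-row replicate success probabilities p~, clipped away from 0 and 1
    so the deviance stays finite with a finite number of draws."""
    if rep.kind != BINARY:
        raise ValueError("replicate probabilities require a binary target")
    if not np.isin(rep.obs, (0.0, 1.0)).all() or not np.isin(
        rep.draws, (0.0, 1.0)
    ).all():
        raise ValueError("binary replicate matrix must contain only 0/1")
    eps = 1.0 / (2.0 * rep.m)
    return np.clip(rep.draws.mean(axis=1), eps, 1.0 - eps)


def deviance_residuals(rep: ReplicateMatrix) -> np.ndarray:
    """Signed per-row deviance residuals of the observed outcomes against
    their replicate probabilities."""
    p = replicate_probabilities(rep)
    d2 = -2.0 * (rep.obs * np.log(p) + (1.0 - rep.obs) * np.log1p(-p))
    return np.sign(rep.obs - p) * np.sqrt(d2)


def mean_squared_deviance(rep: ReplicateMatrix) -> float:
    """Sum of squared deviance residuals divided by the number of observed
    cases (binary targets)."""
    p = replicate_probabilities(rep)
    d2 = -2.0 * (rep.obs * np.log(p) + (1.0 - rep.obs) * np.log1p(-p))
    return float(d2.mean())


# ---------------------------------------------------------------------------
# Posterior predictive p-values
# ---------------------------------------------------------------------------


@dataclass
class DiscrepancyResult:
    """A posterior predictive p-value with the draws behind it."""

    p_value: float
    n_outer: int
    n_inner: int | None = None
    differences: np.ndarray | None = None  # (N,) or (N1, N2) D_{j,k}
    mean_differences: np.ndarray | None = None  # (N1,) inner means D-bar_j

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def _fill_missing(data: IncompleteDataset, y_mis: np.ndarray) -> np.ndarray:
    out = data.values.copy()
    out[~data.observed_mask] = y_mis
    return out


def _merge(obs_source: np.ndarray, data: IncompleteDataset, y_mis: np.ndarray) -> np.ndarray:
    out = np.where(data.observed_mask, obs_source, 0.0)
    out[~data.observed_mask] = y_mis
    return out


def ppp_completed(
    T: Callable[[np.ndarray], float],
    imputer: Callable,
    replicator: Callable,
    data: IncompleteDataset,
    N: int,
    rng: np.random.Generator,
) -> DiscrepancyResult:
    """Completed-data posterior predictive p-value.

    For each of N parameter draws theta_j, the imputer fills the missing
    cells and the replicator simulates a full replicate of the completed
    data from the same theta_j; the p-value is the proportion of draws with
    T(replicate) >= T(completed).

    ``imputer(data, rng)`` must return ``(theta, y_mis)`` with y_mis the
    values for the missing cells (row-major order); ``replicator(data,
    theta, rng)`` must return a full n x p replicate matrix.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    diffs = np.empty(N)
    hits = 0
    for j in range(N):
        theta, y_mis = imputer(data, rng)
        t_com = float(T(_fill_missing(data, y_mis)))
        t_rep = float(T(replicator(data, theta, rng)))
        if not (np.isfinite(t_com) and np.isfinite(t_rep)):
            raise ValueError(f"test quantity non-finite at draw {j}")
        diffs[j] = t_rep - t_com
        hits += t_rep >= t_com
    return DiscrepancyResult(p_value=hits / N, n_outer=N, differences=diffs)


def ppp_expected_completed(
    T: Callable[[np.ndarray], float],
    imputer: Callable,
    replicator: Callable,
    data: IncompleteDataset,
    N1: int,
    N2: int,
    rng: np.random.Generator,
) -> DiscrepancyResult:
    """Expected-completed-data posterior predictive p-value.

    Nested simulation: for each outer draw theta_j the replicator produces a
    replicate of the observed part; N2 inner re-imputations at the same
    theta_j are shared between the replicated and the actual observed part,
    D_{j,k} = T(y_obs^rep_j, y_mis^rep_{j,k}) - T(y_obs, y_mis^rep_{j,k}).
    Inner averaging cancels imputation noise; the p-value is the proportion
    of inner means D-bar_j >= 0.

    ``imputer`` must additionally accept ``theta=`` to re-impute at a fixed
    parameter draw.
    """
    if N1 < 1 or N2 < 1:
        raise ValueError("N1 and N2 must be >= 1")
    D = np.empty((N1, N2))
    for j in range(N1):
        theta, _ = imputer(data, rng)
        y_rep_full = replicator(data, theta, rng)
        for k in range(N2):
            _, y_mis_k = imputer(data, rng, theta=theta)
            t_rep = float(T(_merge(y_rep_full, data, y_mis_k)))
            t_obs = float(T(_merge(data.values, data, y_mis_k)))
            if not (np.isfinite(t_rep) and np.isfinite(t_obs)):
                raise ValueError(f"test quantity non-finite at draw ({j}, {k})")
            D[j, k] = t_rep - t_obs
    dbar = D.mean(axis=1)
    return DiscrepancyResult(
        p_value=float((dbar >= 0).mean()),
        n_outer=N1,
        n_inner=N2,
        differences=D,
        mean_differences=dbar,
    )


class NormalMeanModel:
    """Congenial conjugate normal model for one variable; a reference
    imputer/replicator pair for calibration checks of the p-values."""

    def __init__(self, column: int = 0):
        self.column = column

    def _posterior(self, data: IncompleteDataset, rng: np.random.Generator):
        j = self.column
        y = data.values[data.observed_mask[:, j], j]
        n = len(y)
        if n < 2:
            raise ValueError("need at least 2 observed values")
        ss = float(((y - y.mean()) ** 2).sum())
        sigma2 = ss / rng.chisquare(n - 1)
        mu = float(y.mean() + np.sqrt(sigma2 / n) * rng.standard_normal())
        return mu, float(np.sqrt(sigma2))

    def imputer(self, data: IncompleteDataset, rng: np.random.Generator, theta=None):
        if theta is None:
            theta = self._posterior(data, rng)
        mu, sigma = theta
        n_mis = int((~data.observed_mask).sum())
        y_mis = mu + sigma * rng.standard_normal(n_mis)
        return theta, y_mis

    def replicator(self, data: IncompleteDataset, theta, rng: np.random.Generator):
        mu, sigma = theta
        out = data.values.copy()
        out[:, self.column] = mu + sigma * rng.standard_normal(data.n_rows)
        return out


# ---------------------------------------------------------------------------
# End-to-end diagnosis of one target variable
# ---------------------------------------------------------------------------


def diagnose_target(
    data: IncompleteDataset,
    target: str | Sequence[str],
    spec,
    m: int = 50,
    levels: Sequence[float] = (0.95,),
    n_iter: int | None = None,
    seed: int | None = None,
):
    """Build the over-imputation design for ``target``, multiply impute it,
    and summarize the replicates at each nominal level.

    Returns ``(report, points, rep)``: a plain-dict report (one entry per
    level, plus the mean squared deviance for binary targets), the per-point
    table of the first level, and the raw :class:`ReplicateMatrix`.
    """
    from .engine import fcs_impute

    design = build_overimputation_design(data, target)
    imps = fcs_impute(
        design.data, spec, where=design.where, m=m, n_iter=n_iter, seed=seed
    )
    rep = extract_replicates(design, imps)
    report: dict = {
        "target": design.targets[0],
        "kind": rep.kind,
        "n_obs": int(len(rep.obs)),
        "m": int(m),
        "seed": seed,
        "levels": {},
    }
    points = None
    if rep.kind == CONTINUOUS:
        for level in levels:
            s = summarize_replicates(rep, level)
            report["levels"][str(level)] = {
                "cov": s.cov, "distance": s.distance, "ciw": s.ciw,
            }
            if points is None:
                points = s.to_frame()
    else:
        report["mean_squared_deviance"] = mean_squared_deviance(rep)
        for level in levels:
            s = summarize_replicates(rep, level)
            report["levels"][str(level)] = {"cov": s.cov}
            if points is None:
                points = s.to_frame()
                points["deviance_residual"] = deviance_residuals(rep)
    return report, points, rep
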