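"""Generate missingness in complete data through weighted sum scores.

Whole cases of a pattern (one or more columns) are blanked jointly, either
completely at random (MCAR) or with a right-tailed MAR mechanism (MARr) in
which rows with a higher standardized weighted sum score of fully observed
covariates are more likely to lose their pattern values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datasets import IncompleteDataset

MCAR = "MCAR"
MARR = "MARr"


@dataclass
class AmputationSpec:
    """What to blank, how much, and which mechanism drives it."""

    pattern: list[str]
    prop: float
    mechanism: str = MCAR
    weights: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    slope: float = 1.0  # MARr logistic slope on the standardized score

    def __post_init__(self) -> None:
        if not 0.0 < self.prop < 1.0:
            raise ValueError("prop must be strictly between 0 and 1")
        if self.mechanism not in (MCAR, MARR):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not self.pattern:
            raise ValueError("pattern must name at least one column")
        overlap = set(self.pattern) & set(self.weights)
        if overlap:
            raise ValueError(
                f"weight columns must be disjoint from the pattern: {sorted(overlap)}"
            )
        if self.mechanism == MARR:
            if not self.weights or all(w == 0 for w in self.weights.values()):
                raise ValueError("MARr needs at least one nonzero weight")
        if self.slope <= 0:
            raise ValueError("MARr slope must be positive")


def weighted_sum_score(
    data: pd.DataFrame, weights: dict[str, float], standardize: bool = True
) -> np.ndarray:
    """Per-row linear combination of covariates, w'x, standardized to mean 0
    and SD 1 by default (so only relative weights matter)."""
    if not weights:
        raise ValueError("weights must name at least one column")
    cols = list(weights)
    block = data[cols].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("weighted columns must be fully observed")
    w = np.array([weights[c] for c in cols], dtype=float)
    score = block @ w
    if not standardize:
        return score
    sd = score.std(ddof=0)
    if sd == 0:
        raise ValueError("weighted sum score is constant; cannot standardize")
    return (score - score.mean()) / sd


def _solve_intercept(wss: np.ndarray, slope: float, prop: float) -> float:
    """Intercept a with mean(expit(a + slope * wss)) = prop."""

    def gap(a: float) -> float:
        return float(expit(a + slope * wss).mean()) - prop

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("could not bracket the MARr intercept")
    return brentq(gap, lo, hi, xtol=1e-10)


def ampute(
    data: pd.DataFrame,
    spec: AmputationSpec,
    rng: np.random.Generator | None = None,
) -> IncompleteDataset:
    """Blank the pattern columns jointly in randomly selected rows.

    MCAR selects each row with probability ``prop`` independently of the
    data; MARr selects with probability expit(a + b * wss) on the
    standardized weighted sum score, with the intercept solved so the mean
    selection probability equals ``prop``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    missing_cols = [c for c in spec.pattern if c not in data.columns]
    if missing_cols:
        raise KeyError(f"pattern columns not in data: {missing_cols}")
    pat = data[spec.pattern].to_numpy(dtype=float)
    if np.isnan(pat).any():
        raise ValueError("pattern columns must be complete before amputation")
    n = len(data)
    if spec.mechanism == MCAR:
        prob = np.full(n, spec.prop)
    else:
        wss = weighted_sum_score(data, spec.weights)
        a = _solve_intercept(wss, spec.slope, spec.prop)
        prob = expit(a + spec.slope * wss)
    incomplete = rng.random(n) < prob
    out = data.copy()
    out.loc[incomplete, spec.pattern] = np.nan
    return IncompleteDataset.from_dataframe(out)
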