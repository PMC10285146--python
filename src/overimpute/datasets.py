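"""In-memory containers for incomplete data and stacks of completed copies.

Missing cells are encoded as NaN in the value matrix and as ``False`` in the
observedness mask. Variables are either continuous or binary (0/1); no other
categorical support is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
BINARY = "binary"


def _as_2d_float(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be a 2-D matrix")
    return arr


@dataclass
class IncompleteDataset:
    """A rectangular numeric dataset with an explicit observedness mask.

    Parameters
    ----------
    values
        n x p float matrix; unobserved cells hold NaN.
    observed_mask
        n x p booleans, True where the cell is observed.
    var_names
        Column labels, length p.
    var_kinds
        Per-column kind, each ``"continuous"`` or ``"binary"``.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    var_names: list[str]
    var_kinds: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.var_names = list(self.var_names)
        self.var_kinds = list(self.var_kinds)
        n, p = self.values.shape
        if self.observed_mask.shape != (n, p):
            raise ValueError("observed_mask shape does not match values")
        if len(self.var_names) != p or len(self.var_kinds) != p:
            raise ValueError("var_names/var_kinds length does not match columns")
        if len(set(self.var_names)) != p:
            raise ValueError("duplicate variable names")
        bad_kinds = set(self.var_kinds) - {CONTINUOUS, BINARY}
        if bad_kinds:
            raise ValueError(f"unknown variable kinds: {sorted(bad_kinds)}")
        obs_vals = self.values[self.observed_mask]
        if not np.all(np.isfinite(obs_vals)):
            raise ValueError("observed cells must be finite")
        if not np.all(np.isnan(self.values[~self.observed_mask])):
            raise ValueError("unobserved cells must hold the NaN sentinel")
        for j, kind in enumerate(self.var_kinds):
            if kind == BINARY:
                col = self.values[self.observed_mask[:, j], j]
                if col.size and not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(
                        f"binary variable {self.var_names[j]!r} has values outside {{0,1}}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(self.observed_mask.all())

    def column(self, name: str) -> int:
        """Index of a variable by name."""
        try:
            return self.var_names.index(name)
        except ValueError:
            raise KeyError(f"no variable named {name!r}") from None

    # -- conversion -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        var_kinds: Sequence[str] | dict[str, str] | None = None,
    ) -> "IncompleteDataset":
        """Build from a DataFrame; NaN marks missing.

        Kinds are auto-detected (observed values within {0,1} => binary)
        unless given explicitly, either as a full sequence or as a
        name -> kind override dict.
        """
        values = df.to_numpy(dtype=float)
        mask = ~np.isnan(values)
        names = [str(c) for c in df.columns]
        if isinstance(var_kinds, dict):
            overrides, var_kinds = dict(var_kinds), None
        else:
            overrides = {}
        if var_kinds is None:
            kinds = []
            for j, name in enumerate(names):
                if name in overrides:
                    kinds.append(overrides[name])
                    continue
                col = values[mask[:, j], j]
                is_bin = col.size > 0 and np.isin(col, (0.0, 1.0)).all()
                kinds.append(BINARY if is_bin else CONTINUOUS)
        else:
            kinds = list(var_kinds)
        return cls(values, mask, names, kinds)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.var_names)

    def copy(self) -> "IncompleteDataset":
        return IncompleteDataset(
            self.values.copy(),
            self.observed_mask.copy(),
            list(self.var_names),
            list(self.var_kinds),
        )


def make_where(data: IncompleteDataset, overimpute: np.ndarray | None = None) -> np.ndarray:
    """Build an imputation ("where") mask: all missing cells, plus any
    additional observed cells flagged for over-imputation."""
    where = ~data.observed_mask
    if overimpute is not None:
        overimpute = np.asarray(overimpute, dtype=bool)
        if overimpute.shape != where.shape:
            raise ValueError("overimpute mask shape mismatch")
        where = where | overimpute
    return where


@dataclass
class MultipleImputations:
    """m completed copies of a dataset plus the mask of drawn cells."""

    completed: np.ndarray  # (m, n, p)
    where: np.ndarray  # (n, p) bool: cells that were drawn
    var_names: list[str]
    seed: int | None = None
    iterations: int = 1

    def __post_init__(self) -> None:
        self.completed = np.asarray(self.completed, dtype=float)
        self.where = np.asarray(self.where, dtype=bool)
        if self.completed.ndim != 3:
            raise ValueError("completed must be (m, n, p)")
        if self.completed.shape[1:] != self.where.shape:
            raise ValueError("where mask does not match completed copies")
        if self.m < 1:
            raise ValueError("need at least one imputation")
        if not np.all(np.isfinite(self.completed)):
            raise ValueError("completed copies must be fully filled and finite")

    @property
    def m(self) -> int:
        return self.completed.shape[0]

    def dataset(self, i: int) -> pd.DataFrame:
        return pd.DataFrame(self.completed[i], columns=self.var_names)

    def long_frame(self) -> pd.DataFrame:
        """All copies stacked, with ``.imp`` (1..m) and ``.id`` columns."""
        frames = []
        n = self.completed.shape[1]
        for i in range(self.m):
            df = self.dataset(i)
            df.insert(0, ".id", np.arange(n))
            df.insert(0, ".imp", i + 1)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)
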