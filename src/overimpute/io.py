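"""CSV / YAML / JSON plumbing for incomplete datasets, method specs, and
diagnosis reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import IncompleteDataset, MultipleImputations
from .engine import MethodSpec

log = logging.getLogger("overimpute")

DEFAULT_NA = ("NA", "")


def read_incomplete_csv(
    path,
    na_markers: Sequence[str] = DEFAULT_NA,
    binary: Sequence[str] | None = None,
) -> IncompleteDataset:
    """Read a rectangular numeric CSV; ``na_markers`` cells become missing.

    Binary variables are auto-detected (observed values within {0,1}) unless
    named explicitly. Non-numeric cells raise with their row and column.
    """
    try:
        raw = pd.read_csv(path, dtype=str, na_values=list(na_markers),
                          keep_default_na=False, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric cell at row {row}, column {col!r}: {raw[col][row]!r}"
            )
        numeric[col] = converted
    df = pd.DataFrame(numeric)
    if binary is None:
        return IncompleteDataset.from_dataframe(df)
    kinds = {c: "binary" if c in set(binary) else "continuous" for c in df.columns}
    return IncompleteDataset.from_dataframe(df, var_kinds=kinds)


def write_incomplete_csv(data: IncompleteDataset, path, na: str = "NA") -> None:
    data.to_dataframe().to_csv(path, index=False, na_rep=na)


def write_imputations_csv(imps: MultipleImputations, path) -> None:
    """Long format: all completed copies stacked with `.imp` and `.id`."""
    imps.long_frame().to_csv(path, index=False)


def read_method_spec(path) -> MethodSpec:
    """Method configuration from YAML/JSON: keys ``methods``, ``predictors``,
    optional ``donors``, ``square_pairs``, ``max_reject``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return MethodSpec(
        methods=dict(cfg.get("methods", {})),
        predictors={k: list(v) for k, v in cfg.get("predictors", {}).items()},
        pmm_donors=int(cfg.get("donors", 5)),
        square_pairs=dict(cfg.get("square_pairs", {})),
        max_reject=int(cfg.get("max_reject", 10_000)),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, points: pd.DataFrame | None, out_dir) -> dict:
    """Write ``report.json`` and ``points.csv`` under ``out_dir``; returns
    the paths used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    paths = {"report": str(report_path)}
    if points is not None:
        points_path = out / "points.csv"
        points.to_csv(points_path, index=False)
        paths["points"] = str(points_path)
    log.info("report written to %s", out)
    return paths
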