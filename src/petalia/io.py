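"""Landmark-table and report input/output.

The primary exchange format is a flat wide CSV/TSV with one row per
specimen: ``specimen_id, group, sex, EV_cc`` followed by 21 coordinate
columns (``G_x ... LOP_z``) for the seven named landmarks.  Header names
are matched case-insensitively.  Missing pole coordinates (empty cells)
are allowed and propagate as missing traits; EV is optional.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import LandmarkSet, TRAITS, POLE_POSITIONS

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkTableError",
    "RunConfig",
    "landmark_columns",
    "read_landmark_table",
    "write_landmark_table",
    "write_components",
    "read_components",
    "write_report",
]

LANDMARK_NAMES = ("G", "I", "B", "RFP", "LFP", "ROP", "LOP")
_META_COLUMNS = ("specimen_id", "group", "sex", "EV_cc")


class LandmarkTableError(ValueError):
    """Malformed landmark table (bad header, row or duplicate id)."""


@dataclass
class RunConfig:
    """Analysis configuration shared by the CLI subcommands."""

    alpha: float = 0.05
    size_correct: bool = True
    da_test: str = "t"  # "t" | "wilcoxon"
    seed: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.da_test not in ("t", "wilcoxon"):
            raise ValueError(f"da_test must be 't' or 'wilcoxon', got {self.da_test!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def landmark_columns() -> list[str]:
    cols = list(_META_COLUMNS)
    for lm in LANDMARK_NAMES:
        cols += [f"{lm}_x", f"{lm}_y", f"{lm}_z"]
    return cols


def _sep(path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError("dialect must be 'csv' or 'tsv'")
        return "," if dialect == "csv" else "\t"
    name = str(path).lower()
    return "\t" if name.endswith((".tsv", ".tab")) else ","


def read_landmark_table(path, dialect: Optional[str] = None) -> list[LandmarkSet]:
    """Read a wide landmark table into typed, validated landmark sets.

    Raises :class:`LandmarkTableError` with the offending row number for
    invalid geometry, duplicate specimen ids or missing required columns.
    """
    df = pd.read_csv(path, sep=_sep(path, dialect), dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    wanted = landmark_columns()
    missing = [c for c in wanted if c.lower() not in lower
               and c not in ("group", "sex", "EV_cc")]
    if missing:
        raise LandmarkTableError(f"missing required columns: {missing}")

    def get(row, name, default=None):
        col = lower.get(name.lower())
        if col is None:
            return default
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return default
        v = str(v).strip()
        return v if v else default

    out, seen = [], set()
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based with header
        sid = get(row, "specimen_id")
        if not sid:
            raise LandmarkTableError(f"row {rowno}: missing specimen_id")
        if sid in seen:
            raise LandmarkTableError(f"row {rowno}: duplicate specimen_id {sid!r}")
        seen.add(sid)

        def point(lm, required):
            vals = [get(row, f"{lm}_{ax}") for ax in "xyz"]
            if all(v is None for v in vals):
                if required:
                    raise LandmarkTableError(
                        f"row {rowno} ({sid!r}): landmark {lm} is required"
                    )
                return None
            if any(v is None for v in vals):
                raise LandmarkTableError(
                    f"row {rowno} ({sid!r}): landmark {lm} has partial coordinates"
                )
            try:
                return [float(v) for v in vals]
            except ValueError as exc:
                raise LandmarkTableError(
                    f"row {rowno} ({sid!r}): non-numeric coordinate for {lm}: {exc}"
                ) from None

        ev = get(row, "EV_cc")
        try:
            lm = LandmarkSet(
                specimen_id=sid,
                G=point("G", True), I=point("I", True), B=point("B", True),
                RFP=point("RFP", False), LFP=point("LFP", False),
                ROP=point("ROP", False), LOP=point("LOP", False),
                EV=float(ev) if ev is not None else None,
                group=get(row, "group", "") or "",
                sex=get(row, "sex"),
            )
        except LandmarkTableError:
            raise
        except ValueError as exc:
            raise LandmarkTableError(f"row {rowno} ({sid!r}): {exc}") from exc
        out.append(lm)
    return out


def write_landmark_table(specimens: Iterable[LandmarkSet], path, dialect=None) -> None:
    """Write landmark sets as a wide table (inverse of :func:`read_landmark_table`)."""
    rows = []
    for lm in specimens:
        row = {
            "specimen_id": lm.specimen_id,
            "group": lm.group,
            "sex": lm.sex if lm.sex is not None else "",
            "EV_cc": lm.EV if lm.EV is not None else "",
        }
        for name in LANDMARK_NAMES:
            p = getattr(lm, name)
            for ax, v in zip("xyz", p if p is not None else (None,) * 3):
                row[f"{name}_{ax}"] = "" if v is None else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=landmark_columns()).to_csv(
        path, sep=_sep(path, dialect), index=False
    )


def write_components(components: pd.DataFrame, path) -> None:
    """Write a cohort component table as TSV with 6 significant digits."""
    components.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_components(path) -> pd.DataFrame:
    """Read a component table written by :func:`write_components`."""
    df = pd.read_csv(path, sep="\t")
    required = {"specimen_id", "group", *TRAITS}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkTableError(f"component table missing columns: {sorted(missing)}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_report(report: dict, path, config: Optional[RunConfig] = None) -> None:
    """Write a JSON analysis report with config/version/method metadata.

    Non-finite numbers become ``null`` so the output is strict JSON; key
    order is fixed for byte-identical reruns.
    """
    doc = {
        "software": {"name": "petalia", "version": __version__},
        "config": asdict(config) if config is not None else None,
        "methods": {
            "da_test": "one-sample t (two-tailed)" if (config is None or
                config.da_test == "t") else "Wilcoxon signed-rank (two-tailed)",
            "skewness": "bias-corrected g1, large-sample SE z test",
            "kurtosis": "bias-corrected g2, one-tailed large-sample SE z tests",
            "multiple_testing": "Holm step-down within the six-trait family per test",
        },
        "report": report,
    }
    payload = json.dumps(_jsonable(doc), indent=2, allow_nan=False)
    if hasattr(path, "write"):
        path.write(payload + "\n")
    else:
        with open(path, "w") as fh:
            fh.write(payload + "\n")
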