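"""Delimited-text I/O for designs, trial logs, and result tables.

All artifacts are plain text: trial logs and tables as comma-separated
files with documented headers, configurations as flat ``key = value``
sidecars. Missing RTs (omissions) are written as ``NA``.
"""

from __future__ import annotations

import ast
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DesignConfig
from .designs import ParadigmDesign, TRIAL_COLUMNS
from .errors import SchemaError
from .simulate import LOG_COLUMNS

_NA = "NA"


def write_trial_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write a trial log as CSV (header = documented column order)."""
    out = log[LOG_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep=_NA)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read a trial log, validating the schema.

    Missing columns raise :class:`SchemaError` naming the column; rows with
    unparseable accuracy/RT are rejected with their 1-based line numbers.
    """
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=True,
                     dtype={"condition": str, "rule": str, "paradigm": str,
                            "correct_hand": str, "response_hand": str,
                            "feedback": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log {path} is missing column(s): "
                          f"{', '.join(missing)}")
    bad_lines = []
    acc = pd.to_numeric(df["accuracy"], errors="coerce")
    bad = acc.isna() | ~acc.isin([0, 1])
    bad_lines += [int(i) + 2 for i in df.index[bad]]   # +2: header + 1-based
    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad_rt = df["rt"].notna() & rt.isna()
    bad_lines += [int(i) + 2 for i in df.index[bad_rt]]
    if bad_lines:
        raise SchemaError(f"trial log {path}: malformed rows at line(s) "
                          f"{sorted(set(bad_lines))}")
    df["accuracy"] = acc.astype(np.int8)
    df["rt"] = rt
    for c in ("subject", "run", "trial"):
        df[c] = pd.to_numeric(df[c]).astype(int)
    return df[LOG_COLUMNS]


def write_design(design: ParadigmDesign, path: str | Path) -> None:
    """Write a design's trial table (CSV) plus a ``.config`` sidecar."""
    path = Path(path)
    design.trials[TRIAL_COLUMNS].to_csv(path, index=False)
    side = path.with_suffix(path.suffix + ".config")
    with open(side, "w") as fh:
        for key, value in design.config.to_dict().items():
            fh.write(f"{key} = {value!r}\n")
        fh.write(f"segment_boundaries = {list(design.segment_boundaries)!r}\n")


def read_design(path: str | Path) -> ParadigmDesign:
    """Read a design written by :func:`write_design`."""
    path = Path(path)
    trials = pd.read_csv(path, dtype={"stimulus": str})
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"design {path} is missing column(s): "
                          f"{', '.join(missing)}")
    side = path.with_suffix(path.suffix + ".config")
    fields: dict = {}
    with open(side) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = ast.literal_eval(value.strip())
    boundaries = fields.pop("segment_boundaries", [])
    for k in ("post_critical_gap", "run_length_interval",
              "inter_reversal_interval", "iti_interval"):
        if k in fields:
            fields[k] = tuple(fields[k])
    config = DesignConfig(**fields)
    return ParadigmDesign(config=config, trials=trials[TRIAL_COLUMNS],
                          segment_boundaries=list(boundaries))


def write_index_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, na_rep=_NA)


def read_index_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA], index_col="subject")
    return df


def write_provenance(provenance: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
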