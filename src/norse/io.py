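"""Participant-table ingest, export and population filters.

The canonical interchange format is a flat CSV in the documented schema
(cm / kg / years, flags in {0, 1, blank}).  Survey extracts in other
codings — SAS transport (XPT) files or CSVs with agency variable names and
questionnaire codes such as 1=yes / 2=no / 7=refused / 9=don't know — are
mapped onto the schema by a small YAML/JSON mapping config:

.. code-block:: yaml

    columns:            # source column -> schema column
      BMXWAIST: waist_circ
      BPQ020: hypertension
    sex_codes: {1: male, 2: female}
    flag_recodes:       # per flag column: source code -> 0/1/null
      hypertension: {1: 1, 2: 0, 7: null, 9: null}
    scale:              # multiplicative unit fixes, e.g. inches -> cm
      waist_circ: 2.54
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .registry import CONDITIONS, validate_table

__all__ = ["read_table", "write_table", "load_mapping", "AnalysisFilter"]

log = logging.getLogger("norse")


def load_mapping(path_or_dict) -> dict:
    if isinstance(path_or_dict, Mapping):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        return yaml.safe_load(fh) or {}


def _apply_mapping(df: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    cols = mapping.get("columns") or {}
    if cols:
        df = df.rename(columns=cols)
    sex_codes = mapping.get("sex_codes")
    if sex_codes and "sex" in df.columns:
        df["sex"] = df["sex"].map(lambda v: sex_codes.get(v, sex_codes.get(str(v), v)))
    for col, codes in (mapping.get("flag_recodes") or {}).items():
        if col not in df.columns:
            continue
        codes = {float(k): (np.nan if v is None else float(v)) for k, v in codes.items()}
        df[col] = pd.to_numeric(df[col], errors="coerce").map(
            lambda v: codes.get(v, np.nan)
        )
    for col, factor in (mapping.get("scale") or {}).items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce") * float(factor)
    return df


def read_table(path, mapping=None) -> pd.DataFrame:
    """Read a participant table from CSV or SAS transport (.xpt).

    ``mapping`` (dict, or path to YAML/JSON) translates source columns and
    questionnaire codes into the canonical schema before validation.
    Unparseable measurement entries become missing; the retained row count
    is logged.
    """
    path = Path(path)
    if path.suffix.lower() == ".xpt":
        df = pd.read_sas(path, format="xport")
        df.columns = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path)
    n_raw = len(df)
    if mapping is not None:
        df = _apply_mapping(df, load_mapping(mapping))
    df = validate_table(df)
    log.info("read %d rows from %s (%d in file)", len(df), path, n_raw)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class AnalysisFilter:
    """Pure row predicate for selecting an analysis population.

    ``exclude_flags`` names binary columns whose positives are dropped
    (e.g. ``smoker_flag`` to exclude ever-smokers); rows with the flag
    missing are kept.  Filters are idempotent by construction.
    """

    sexes: tuple[str, ...] = ("male", "female")
    age_range: tuple[float, float] = (20.0, 110.0)
    exclude_flags: tuple[str, ...] = ()
    require_present: tuple[str, ...] = ()

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = df["sex"].isin(self.sexes)
        lo, hi = self.age_range
        m &= (df["age"] >= lo) & (df["age"] <= hi)
        for flag in self.exclude_flags:
            m &= df[flag].fillna(0.0) != 1.0
        for col in self.require_present:
            m &= df[col].notna()
        return m

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        m = self.mask(df)
        out = df[m].reset_index(drop=True)
        log.info(
            "filter %s: %d -> %d rows", self._describe(), len(df), len(out)
        )
        return out

    def _describe(self) -> str:
        parts = [f"sex in {list(self.sexes)}", f"age in {list(self.age_range)}"]
        parts += [f"{f}!=1" for f in self.exclude_flags]
        parts += [f"{c} present" for c in self.require_present]
        return ", ".join(parts)
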