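"""Biomarker registry: raw-measurement schema, derived indices, z-scores.

The participant table is a plain :class:`pandas.DataFrame` with a documented
schema (see :data:`RAW_FIELDS`, :data:`CONDITIONS`).  Body-composition indices
(BMI, WHR, ABSI, RFM, ...) are derived row-wise from the raw anthropometrics
by :func:`derive_biomarker`; every index is registered as a
:class:`BiomarkerDefinition` and may be overridden or extended by the user,
so alternative published formulas can be swapped in without touching the
analysis code.

All lengths are in cm, masses in kg, age in years.  Formulas convert to
metres internally where an index is conventionally defined in SI units.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RAW_FIELDS",
    "CONDITIONS",
    "GROUPS",
    "BiomarkerDefinition",
    "BiomarkerVector",
    "BiomarkerRegistry",
    "default_registry",
    "derive_biomarker",
    "zscore",
    "list_pairs",
    "validate_table",
    "registry_to_config",
    "registry_from_config",
]

#: Raw measurement columns (cm / kg / years).  Any of these may be missing
#: per participant; ``participant_id``, ``sex`` and ``age`` may not.
RAW_FIELDS = (
    "weight",
    "height",
    "waist_circ",
    "hip_circ",
    "thigh_circ",
    "max_calf_circ",
    "bicep_circ",
    "upper_arm_len",
    "leg_len",
    "total_fat_mass",
    "trunk_fat_mass",
    "lean_mass",
)

#: Self-reported doctor-diagnosed condition flags, coded 0/1/NaN.
CONDITIONS = (
    "hypertension",
    "arthritis",
    "diabetes",
    "high_cholesterol",
    "coronary_heart_disease",
    "cancer",
)

GROUPS = ("regional", "global", "non_composition")

ID_FIELDS = ("participant_id", "sex", "age")

ADULT_AGE_RANGE = (20.0, 110.0)


class RegistryError(KeyError):
    """Unknown biomarker name or invalid registry operation."""


class DegenerateDistributionError(ValueError):
    """A biomarker is constant: standard deviation is zero."""


def validate_table(df: pd.DataFrame, adult_filter: bool = False) -> pd.DataFrame:
    """Validate and canonicalize a participant table.

    Checks the id/sex/age columns exist, coerces measurement columns to
    float, normalizes ``sex`` to the strings ``male``/``female``, restricts
    condition flags to {0, 1, NaN}, and (optionally) applies the adult
    age filter 20 <= age <= 110.  Non-positive measurements are set to
    missing with a warning: a zero or negative circumference or mass is a
    recording error, not data.
    """
    missing_cols = [c for c in ID_FIELDS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"participant table lacks required columns: {missing_cols}")
    out = df.copy()
    out["sex"] = out["sex"].astype(str).str.lower()
    bad_sex = ~out["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(f"unrecognized sex values: {sorted(out.loc[bad_sex, 'sex'].unique())}")
    out["age"] = pd.to_numeric(out["age"], errors="coerce")
    for col in RAW_FIELDS:
        if col not in out.columns:
            out[col] = np.nan
        out[col] = pd.to_numeric(out[col], errors="coerce")
        nonpos = out[col] <= 0
        if nonpos.any():
            warnings.warn(
                f"{int(nonpos.sum())} non-positive values in '{col}' set to missing",
                stacklevel=2,
            )
            out.loc[nonpos, col] = np.nan
    for col in CONDITIONS + ("smoker_flag",):
        if col not in out.columns:
            out[col] = np.nan
        out[col] = pd.to_numeric(out[col], errors="coerce")
        ok = out[col].isin([0.0, 1.0]) | out[col].isna()
        if not ok.all():
            warnings.warn(
                f"{int((~ok).sum())} values in '{col}' outside {{0,1}} set to missing",
                stacklevel=2,
            )
            out.loc[~ok, col] = np.nan
    if adult_filter:
        lo, hi = ADULT_AGE_RANGE
        out = out[(out["age"] >= lo) & (out["age"] <= hi)].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Definitions


@dataclass(frozen=True)
class BiomarkerDefinition:
    """A named derived biomarker.

    ``formula`` maps the participant table (cm/kg units) to a float Series;
    it is only ever evaluated on rows where all ``required_fields`` are
    present and positive.  ``sex`` and ``age`` are always available to the
    formula (RFM, for instance, has a sex-specific offset).
    """

    name: str
    group: str
    required_fields: tuple[str, ...]
    formula: Callable[[pd.DataFrame], pd.Series]
    units: str = ""
    description: str = ""

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class BiomarkerVector:
    """Per-participant values of one biomarker plus its population moments.

    ``mu``/``sigma``/``zscores`` are filled by :func:`zscore`; moments are
    population-level (ddof=0) over non-missing values of the analysis
    population the vector was derived from.
    """

    name: str
    values: pd.Series
    mu: float | None = None
    sigma: float | None = None
    zscores: pd.Series | None = None

    @property
    def n_nonmissing(self) -> int:
        return int(self.values.notna().sum())


def _m(series: pd.Series) -> pd.Series:
    """cm -> m."""
    return series / 100.0


def _bmi(df):
    return df["weight"] / _m(df["height"]) ** 2


def _rfm(df):
    base = 64.0 - 20.0 * df["height"] / df["waist_circ"]
    return base + 12.0 * (df["sex"] == "female").astype(float)


def _absi(df):
    bmi = _bmi(df)
    return _m(df["waist_circ"]) / (bmi ** (2.0 / 3.0) * _m(df["height"]) ** 0.5)


def _passthrough(col: str):
    def f(df, _col=col):
        return df[_col].astype(float)

    return f


def _builtin_definitions(ptf_of_total: bool = False) -> list[BiomarkerDefinition]:
    """The 23 built-in indices, in ranking-table group order.

    ``ptf_of_total`` switches percent trunk fat to trunk/total fat instead
    of trunk fat as a share of body weight.
    """
    ptf_fields = ("trunk_fat_mass", "total_fat_mass") if ptf_of_total else ("trunk_fat_mass", "weight")
    ptf_formula = (
        (lambda df: 100.0 * df["trunk_fat_mass"] / df["total_fat_mass"])
        if ptf_of_total
        else (lambda df: 100.0 * df["trunk_fat_mass"] / df["weight"])
    )
    D = BiomarkerDefinition
    return [
        # -- regional composition ------------------------------------------
        D("WHR", "regional", ("waist_circ", "hip_circ"),
          lambda df: df["waist_circ"] / df["hip_circ"], "", "waist-to-hip ratio"),
        D("WThR", "regional", ("waist_circ", "thigh_circ"),
          lambda df: df["waist_circ"] / df["thigh_circ"], "", "waist-to-thigh ratio"),
        D("ABSI", "regional", ("waist_circ", "weight", "height"), _absi,
          "m^11/6 kg^-2/3", "a body shape index"),
        D("RFM", "regional", ("height", "waist_circ"), _rfm, "%", "relative fat mass"),
        D("WeThR", "regional", ("weight", "thigh_circ"),
          lambda df: df["weight"] / df["thigh_circ"], "kg/cm", "weight-to-thigh ratio"),
        D("WHtR", "regional", ("waist_circ", "height"),
          lambda df: df["waist_circ"] / df["height"], "", "waist-to-height ratio"),
        D("BAI", "regional", ("hip_circ", "height"),
          lambda df: df["hip_circ"] / _m(df["height"]) ** 1.5 - 18.0, "%",
          "body adiposity index"),
        D("PTF", "regional", ptf_fields, ptf_formula, "%", "percent trunk fat"),
        D("Waist circ", "regional", ("waist_circ",), _passthrough("waist_circ"), "cm"),
        D("Hip circ", "regional", ("hip_circ",), _passthrough("hip_circ"), "cm"),
        # -- global composition --------------------------------------------
        D("PBF", "global", ("total_fat_mass", "weight"),
          lambda df: 100.0 * df["total_fat_mass"] / df["weight"], "%", "percent body fat"),
        D("FTL", "global", ("total_fat_mass", "lean_mass"),
          lambda df: df["total_fat_mass"] / df["lean_mass"], "", "fat-to-lean ratio"),
        D("FMI", "global", ("total_fat_mass", "height"),
          lambda df: df["total_fat_mass"] / _m(df["height"]) ** 2, "kg/m^2", "fat mass index"),
        D("PI", "global", ("weight", "height"),
          lambda df: df["weight"] / _m(df["height"]) ** 3, "kg/m^3", "ponderal index"),
        D("BMI", "global", ("weight", "height"), _bmi, "kg/m^2", "body mass index"),
        D("Weight", "global", ("weight",), _passthrough("weight"), "kg"),
        D("FFMI", "global", ("lean_mass", "height"),
          lambda df: df["lean_mass"] / _m(df["height"]) ** 2, "kg/m^2", "fat-free mass index"),
        # -- weakly composition-related ------------------------------------
        D("Upper arm len", "non_composition", ("upper_arm_len",), _passthrough("upper_arm_len"), "cm"),
        D("Bicep circ", "non_composition", ("bicep_circ",), _passthrough("bicep_circ"), "cm"),
        D("Max calf circ", "non_composition", ("max_calf_circ",), _passthrough("max_calf_circ"), "cm"),
        D("Thigh circ", "non_composition", ("thigh_circ",), _passthrough("thigh_circ"), "cm"),
        D("Height", "non_composition", ("height",), _passthrough("height"), "cm"),
        D("Leg length", "non_composition", ("leg_len",), _passthrough("leg_len"), "cm"),
    ]


class BiomarkerRegistry:
    """Ordered mapping of biomarker name -> definition, with overrides."""

    def __init__(self, definitions: Sequence[BiomarkerDefinition] = ()):
        self._defs: dict[str, BiomarkerDefinition] = {}
        for d in definitions:
            self.register(d, overwrite=False)

    def register(self, definition: BiomarkerDefinition, overwrite: bool = True) -> None:
        if not overwrite and definition.name in self._defs:
            raise RegistryError(f"biomarker {definition.name!r} already registered")
        self._defs[definition.name] = definition

    def get(self, name: str) -> BiomarkerDefinition:
        try:
            return self._defs[name]
        except KeyError:
            raise RegistryError(f"unknown biomarker {name!r}") from None

    def names(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self._defs)
        return [n for n, d in self._defs.items() if d.group == group]

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())


def default_registry(ptf_of_total: bool = False) -> BiomarkerRegistry:
    """Registry holding the 23 built-in body-composition indices."""
    return BiomarkerRegistry(_builtin_definitions(ptf_of_total=ptf_of_total))


# -- registry config serialization ------------------------------------------
#
# A registry round-trips through a YAML/JSON-able list of entries:
#   {name, group, required_fields, units, formula: {id, params}}
# Formula ids: "builtin" (one of the 23 stock formulas, looked up by name),
# "passthrough" (one raw field), "ratio" (scale * numerator / denominator).
# User-supplied Python callables cannot be serialized and are rejected.


def _formula_spec(definition: BiomarkerDefinition) -> dict:
    builtin_names = {d.name for d in _builtin_definitions()}
    if definition.name in builtin_names:
        return {"id": "builtin", "params": {}}
    raise ValueError(
        f"cannot serialize custom formula for {definition.name!r}; "
        "use a 'passthrough' or 'ratio' config entry instead"
    )


def registry_to_config(registry: BiomarkerRegistry) -> list[dict]:
    return [
        {
            "name": d.name,
            "group": d.group,
            "required_fields": list(d.required_fields),
            "units": d.units,
            "formula": _formula_spec(d),
        }
        for d in registry
    ]


def registry_from_config(entries: Sequence[Mapping]) -> BiomarkerRegistry:
    builtins = {d.name: d for d in _builtin_definitions()}
    reg = BiomarkerRegistry()
    for e in entries:
        spec = e.get("formula", {"id": "builtin"})
        fid = spec.get("id", "builtin")
        params = spec.get("params", {})
        if fid == "builtin":
            base = builtins.get(e["name"])
            if base is None:
                raise RegistryError(f"no builtin formula named {e['name']!r}")
            formula = base.formula
        elif fid == "passthrough":
            formula = _passthrough(params.get("field", e["required_fields"][0]))
        elif fid == "ratio":
            num, den = params["numerator"], params["denominator"]
            scale = float(params.get("scale", 1.0))

            def formula(df, _n=num, _d=den, _s=scale):
                return _s * df[_n] / df[_d]

        else:
            raise RegistryError(f"unknown formula id {fid!r}")
        reg.register(
            BiomarkerDefinition(
                name=e["name"],
                group=e["group"],
                required_fields=tuple(e["required_fields"]),
                formula=formula,
                units=e.get("units", ""),
            )
        )
    return reg


# ---------------------------------------------------------------------------
# Operations


def derive_biomarker(
    table: pd.DataFrame,
    definition: BiomarkerDefinition | str,
    registry: BiomarkerRegistry | None = None,
) -> BiomarkerVector:
    """Compute one biomarker over a participant table.

    A row's value is missing iff any required field is missing there.
    Derivation is purely row-wise; the index of ``table`` is preserved.
    """
    if isinstance(definition, str):
        registry = registry if registry is not None else default_registry()
        definition = registry.get(definition)
    missing_fields = [f for f in definition.required_fields if f not in table.columns]
    if missing_fields:
        raise RegistryError(
            f"table lacks fields {missing_fields} required by {definition.name!r}"
        )
    mask = pd.Series(True, index=table.index)
    for f in definition.required_fields:
        col = pd.to_numeric(table[f], errors="coerce")
        mask &= col.notna() & (col > 0)
    values = pd.Series(np.nan, index=table.index, dtype=float, name=definition.name)
    if mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            computed = definition.formula(table.loc[mask])
        values.loc[mask] = pd.to_numeric(computed, errors="coerce").astype(float)
    return BiomarkerVector(name=definition.name, values=values)


def zscore(vector: BiomarkerVector, ddof: int = 0) -> BiomarkerVector:
    """Standardize a biomarker vector: X = (B - mu_B) / sigma_B.

    ``mu``/``sigma`` are computed over the non-missing values (population
    SD by default, ``ddof=0``).  Re-standardizing an already z-scored
    vector returns the z-scores unchanged (mu=0, sigma=1).
    """
    finite = vector.values.dropna()
    if len(finite) < 2:
        raise ValueError(
            f"need >= 2 non-missing values to standardize {vector.name!r}, got {len(finite)}"
        )
    mu = float(finite.mean())
    sigma = float(finite.std(ddof=ddof))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise DegenerateDistributionError(
            f"biomarker {vector.name!r} is constant (sigma=0); z-scores undefined"
        )
    z = (vector.values - mu) / sigma
    return replace(vector, mu=mu, sigma=sigma, zscores=z)


def list_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered distinct pairs, in the input's combinatorial order."""
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if list(names).count(n) > 1})
        raise ValueError(f"duplicate biomarker names: {dupes}")
    return list(itertools.combinations(names, 2))
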