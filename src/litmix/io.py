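"""Config and data file handling: parameter YAML, observation CSV,
trajectory output, and the external-deposit helper.

Formats
-------
* Parameter files are YAML (JSON, being a YAML subset, is accepted) with a
  top-level ``litters`` list; each block carries exactly the fields of
  :class:`~litmix.params.LitterParams`. Constants of the inactive moisture
  model may be omitted.
* Observation files are comma-separated UTF-8 with a mandatory header and
  columns ``day, replicate, litter, treatment, variable, value``
  (``treatment`` ∈ {alone, mixture}; ``variable`` ∈ {lwc, mass_fraction}).
  External layouts are adapted through a column-mapping dict, and mass
  given in percent of initial dry weight is rescaled to fractions when the
  ``mass_unit="percent"`` hint is set.

The laboratory dataset for the peatland case study lives in an external
Zenodo deposit; it is never fetched automatically (:func:`zenodo_info`
prints the DOI and the layout this module expects).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd
import yaml

from .calibration import DataError, ObservationSeries
from .mixture import MixtureResult, nonadditive_delta
from .params import ConfigurationError, LitterParams

__all__ = [
    "PARAM_FIELDS",
    "OBS_COLUMNS",
    "packaged_params",
    "read_params",
    "write_params",
    "load_observation_table",
    "load_observations",
    "write_observations",
    "write_trajectory",
    "write_mixture_pair",
    "zenodo_info",
]

PARAM_FIELDS = ("name", "lwc_max", "k_max", "e", "model_kind",
                "a", "b", "c", "d")
OBS_COLUMNS = ("day", "replicate", "litter", "treatment", "variable", "value")

ZENODO_DOI = "10.5281/zenodo.4789262"


def _params_from_mapping(block: Mapping) -> LitterParams:
    unknown = set(block) - set(PARAM_FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown parameter fields {sorted(unknown)}")
    try:
        return LitterParams(**block)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def _parse_params_doc(doc: object, source: str) -> Dict[str, LitterParams]:
    if not isinstance(doc, Mapping) or "litters" not in doc:
        raise ConfigurationError(
            f"{source}: expected a mapping with a top-level 'litters' list"
        )
    out: Dict[str, LitterParams] = {}
    for block in doc["litters"]:
        params = _params_from_mapping(block)
        if params.name in out:
            raise ConfigurationError(
                f"{source}: duplicate litter name {params.name!r}"
            )
        out[params.name] = params
    return out


def packaged_params(fixture: str) -> Dict[str, LitterParams]:
    """Load one of the packaged parameter fixtures by stem name."""
    ref = resources.files("litmix.data") / f"{fixture}.yaml"
    with ref.open("r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    return _parse_params_doc(doc, f"packaged fixture {fixture!r}")


def read_params(path) -> Dict[str, LitterParams]:
    """Read a litter parameter file (YAML/JSON) into a name-keyed dict."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    return _parse_params_doc(doc, str(path))


def write_params(params: Iterable[LitterParams], path) -> None:
    """Write litter parameter sets, omitting unset constants."""
    blocks = []
    for p in params:
        block = {field: getattr(p, field) for field in PARAM_FIELDS}
        blocks.append({k: v for k, v in block.items() if v is not None})
    Path(path).write_text(
        yaml.safe_dump({"litters": blocks}, sort_keys=False),
        encoding="utf-8",
    )


def load_observation_table(
    path,
    column_mapping: Optional[Mapping[str, str]] = None,
    mass_unit: str = "fraction",
) -> pd.DataFrame:
    """Read and validate an observation CSV into the canonical schema.

    ``column_mapping`` maps canonical names to the file's column names
    (e.g. ``{"day": "time_d"}``) for external layouts. With
    ``mass_unit="percent"``, mass values are divided by 100 on load.
    Validation failures name the offending data row (1-based, excluding
    the header).
    """
    path = Path(path)
    table = pd.read_csv(path)
    mapping = dict(column_mapping or {})
    rename = {mapping.get(col, col): col for col in OBS_COLUMNS}
    table = table.rename(columns=rename)
    missing = set(OBS_COLUMNS) - set(table.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    table = table[list(OBS_COLUMNS)].copy()

    for col in ("day", "value"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise DataError(
                f"{path}: non-numeric {col!r} value at data row {row}"
            )
        table[col] = coerced
    if table[["day", "value"]].isna().any().any():
        row = int(table[["day", "value"]].isna().any(axis=1).idxmax()) + 1
        raise DataError(f"{path}: missing value at data row {row}")

    if mass_unit == "percent":
        is_mass = table["variable"] == "mass_fraction"
        table.loc[is_mass, "value"] /= 100.0
    elif mass_unit != "fraction":
        raise DataError("mass_unit must be 'fraction' or 'percent'")

    for idx, row in table.iterrows():
        problems = []
        if row["day"] < 0 or row["day"] != int(row["day"]):
            problems.append(f"day={row['day']}")
        if row["variable"] not in ("lwc", "mass_fraction"):
            problems.append(f"variable={row['variable']!r}")
        elif row["variable"] == "mass_fraction" and not 0 < row["value"] <= 1:
            problems.append(f"mass_fraction={row['value']}")
        elif row["variable"] == "lwc" and row["value"] < 0:
            problems.append(f"lwc={row['value']}")
        if row["treatment"] not in ("alone", "mixture"):
            problems.append(f"treatment={row['treatment']!r}")
        if problems:
            raise DataError(
                f"{path}: invalid {', '.join(problems)} at data row {int(idx) + 1}"
            )
    table["day"] = table["day"].astype(int)
    return table


def load_observations(
    path,
    litter: str,
    treatment: str = "alone",
    column_mapping: Optional[Mapping[str, str]] = None,
    mass_unit: str = "fraction",
) -> ObservationSeries:
    """Extract one litter/treatment series from an observation CSV."""
    table = load_observation_table(path, column_mapping, mass_unit)
    sub = table[(table["litter"] == litter) & (table["treatment"] == treatment)]
    if len(sub) == 0:
        available = sorted(
            set(zip(table["litter"], table["treatment"]))
        )
        raise DataError(
            f"{path}: no rows for litter={litter!r}, treatment={treatment!r}; "
            f"available: {available}"
        )
    data = sub[["day", "replicate", "variable", "value"]].reset_index(drop=True)
    return ObservationSeries(litter=litter, data=data)


def write_observations(series: ObservationSeries, path,
                       treatment: str = "alone") -> None:
    """Write one series back out in the canonical CSV schema."""
    table = series.data.copy()
    table.insert(2, "litter", series.litter)
    table.insert(3, "treatment", treatment)
    table[list(OBS_COLUMNS)].to_csv(path, index=False)


def write_trajectory(traj, path) -> None:
    """Single-litter trajectory CSV: day, litter, lwc, k, mass_fraction."""
    traj.to_frame().to_csv(path, index=False)


def write_mixture_pair(result_no_int: MixtureResult, result_int: MixtureResult,
                       path) -> None:
    """Paired-scenario CSV with the per-day nonadditive delta column."""
    delta = nonadditive_delta(result_no_int, result_int)
    frames = []
    for result in (result_no_int, result_int):
        frame = result.to_frame()
        frame["delta"] = pd.concat(
            [pd.Series(delta), pd.Series(delta)], ignore_index=True
        )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out = out[["day", "scenario", "litter", "lwc", "k", "mass_fraction",
               "combined_mass", "delta"]]
    out.to_csv(path, index=False)


def zenodo_info() -> str:
    """Describe the external laboratory dataset and the layout expected here.

    The deposit is never downloaded automatically; fetch it yourself and
    convert it to the canonical observation CSV (see
    :func:`load_observation_table` for the column-mapping hook).
    """
    return (
        f"Laboratory incubation data: https://doi.org/{ZENODO_DOI}\n"
        "Expected after conversion: one CSV with columns\n"
        f"  {', '.join(OBS_COLUMNS)}\n"
        "treatment 'alone' for each single litter (used for calibration),\n"
        "'mixture' for the 50:50 mixture (used for validation); mass as a\n"
        "fraction of initial dry weight (or pass mass_unit='percent').\n"
        "Place it at data/zenodo/observations.csv to run the packaged\n"
        "validation study."
    )
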