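"""CSV readers/writers and YAML configuration handling.

CSV files carry column data plus leading ``# key: value`` metadata
lines (infusion rate, animal id, condition, generator seed...).  The
readers validate the schema and name the offending column on failure;
extra columns are preserved as metadata.
"""

from __future__ import annotations

import copy
import importlib.resources
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import pandas as pd
import yaml

from .kinetics import EffluxSeries
from .secretion import PerfusionTimeSeries

PathLike = Union[str, Path]


class SchemaError(ValueError):
    pass


PERFUSION_COLUMNS = ("time_min", "inflow_fluor", "outflow_fluor")
EFFLUX_COLUMNS = ("time_s", "rb_counts", "mannitol_counts")
DOSE_COLUMNS = ("dose_um", "response")


def _read_metadata(path: PathLike) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_table(
    path: PathLike, required_columns: Tuple[str, ...]
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a metadata-headed CSV and validate its column schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in required_columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path.name}: column {col!r} is not numeric") from exc
    return df, meta


def _write_table(path: PathLike, df: pd.DataFrame, meta: Dict[str, object]) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_perfusion_csv(path: PathLike) -> PerfusionTimeSeries:
    df, meta = read_table(path, PERFUSION_COLUMNS)
    if "infusion_rate_ul_min" not in meta:
        raise SchemaError(f"{Path(path).name}: missing metadata 'infusion_rate_ul_min'")
    return PerfusionTimeSeries(
        time_min=df["time_min"].to_numpy(),
        inflow_fluor=df["inflow_fluor"].to_numpy(),
        outflow_fluor=df["outflow_fluor"].to_numpy(),
        infusion_rate_ul_min=float(meta["infusion_rate_ul_min"]),
        animal_id=meta.get("animal_id", ""),
        condition=meta.get("condition", ""),
    )


def write_perfusion_csv(
    path: PathLike, series: PerfusionTimeSeries, extra_meta: Optional[Dict] = None
) -> None:
    meta: Dict[str, object] = {
        "infusion_rate_ul_min": series.infusion_rate_ul_min,
        "animal_id": series.animal_id,
        "condition": series.condition,
    }
    meta.update(extra_meta or {})
    df = pd.DataFrame(
        {
            "time_min": series.time_min,
            "inflow_fluor": series.inflow_fluor,
            "outflow_fluor": series.outflow_fluor,
        }
    )
    _write_table(path, df, meta)


def read_efflux_csv(path: PathLike) -> EffluxSeries:
    df, meta = read_table(path, EFFLUX_COLUMNS)
    return EffluxSeries(
        time_s=df["time_s"].to_numpy(),
        rb_counts=df["rb_counts"].to_numpy(),
        mannitol_counts=df["mannitol_counts"].to_numpy(),
        label=meta.get("label", ""),
    )


def write_efflux_csv(
    path: PathLike, series: EffluxSeries, extra_meta: Optional[Dict] = None
) -> None:
    meta: Dict[str, object] = {"label": series.label}
    meta.update(extra_meta or {})
    df = pd.DataFrame(
        {
            "time_s": series.time_s,
            "rb_counts": series.rb_counts,
            "mannitol_counts": series.mannitol_counts,
        }
    )
    _write_table(path, df, meta)


def read_dose_response_csv(path: PathLike) -> pd.DataFrame:
    df, _ = read_table(path, DOSE_COLUMNS)
    return df


def write_dose_response_csv(
    path: PathLike, df: pd.DataFrame, extra_meta: Optional[Dict] = None
) -> None:
    _write_table(path, df[list(DOSE_COLUMNS)], extra_meta or {})


# --- configuration ------------------------------------------------------


def default_config() -> Dict:
    """The packaged reference constants (a fresh copy)."""
    text = (
        importlib.resources.files("csfosmo")
        .joinpath("data/reference_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _deep_merge(base: Dict, override: Dict) -> Dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: Optional[PathLike] = None) -> Dict:
    """Load a YAML config, merged over the packaged defaults."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"{Path(path).name}: config must be a mapping")
        config = _deep_merge(config, user)
    return config
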