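"""Table and config readers/writers shared by the CLI and the library.

TSV is the canonical dialect (search-engine exports are TSV); CSV is
accepted by extension or explicit override. Experiment configs are JSON or
YAML mappings of channel label to role/concentration/time/replicate, with
explicit unit strings that are converted to SI exactly once, at this
boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .occupancy import ChannelDesign, ExperimentDesign, DEFAULT_REFERENCE

__all__ = [
    "SchemaError",
    "ExperimentConfig",
    "conc_to_molar",
    "time_to_seconds",
    "read_table",
    "read_abundance_table",
    "write_table",
    "read_experiment_config",
]

CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}
TIME_UNITS = {"s": 1.0, "min": 60.0, "h": 3600.0}


class SchemaError(ValueError):
    """A config or table does not match its expected shape; names the field."""


def conc_to_molar(value: float, unit: str) -> float:
    if unit not in CONC_UNITS:
        raise SchemaError(f"unknown concentration unit {unit!r}; use one of {sorted(CONC_UNITS)}")
    return float(value) * CONC_UNITS[unit]


def time_to_seconds(value: float, unit: str) -> float:
    if unit not in TIME_UNITS:
        raise SchemaError(f"unknown time unit {unit!r}; use one of {sorted(TIME_UNITS)}")
    return float(value) * TIME_UNITS[unit]


@dataclass
class ExperimentConfig:
    """Validated experiment design plus pipeline options.

    Built from a JSON/YAML document shaped as::

        reference: ACC1
        cr_convention: treated_over_dmso
        seed: 1
        channels:
          "126":  {role: dmso_control}
          "127N": {role: saturation_control}
          "127C": {role: treated, conc: 25, conc_unit: nM, time: 2, time_unit: min}
    """

    design: ExperimentDesign
    reference: str = DEFAULT_REFERENCE
    cr_convention: str = "treated_over_dmso"
    seed: int = 0
    analyte_column: str = "analyte"

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        if "channels" not in doc or not isinstance(doc["channels"], dict):
            raise SchemaError("config needs a 'channels' mapping")
        channels = []
        for label, spec in doc["channels"].items():
            if not isinstance(spec, dict) or "role" not in spec:
                raise SchemaError(f"channel {label!r}: needs a 'role' field")
            role = spec["role"]
            conc = time = None
            if role == "treated":
                for key in ("conc", "time"):
                    if key not in spec:
                        raise SchemaError(f"channel {label!r}: treated channel needs {key!r}")
                conc = conc_to_molar(spec["conc"], spec.get("conc_unit", "M"))
                time = time_to_seconds(spec["time"], spec.get("time_unit", "s"))
            channels.append(ChannelDesign(
                channel=str(label), role=role, conc=conc, time=time,
                replicate=str(spec.get("replicate", "")),
            ))
        try:
            design = ExperimentDesign(channels)
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
        return cls(
            design=design,
            reference=str(doc.get("reference", DEFAULT_REFERENCE)),
            cr_convention=str(doc.get("cr_convention", "treated_over_dmso")),
            seed=int(doc.get("seed", 0)),
            analyte_column=str(doc.get("analyte_column", "analyte")),
        )


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    return ExperimentConfig.from_dict(doc)


def _sep_for(path: Path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, sep: Optional[str] = None) -> pd.DataFrame:
    """Read a tidy TSV/CSV table (dialect from extension unless overridden)."""
    path = Path(path)
    # round_trip parsing keeps written floats bit-exact on re-read
    return pd.read_csv(path, sep=_sep_for(path, sep), float_precision="round_trip")


def read_abundance_table(
    path: str | Path,
    config: ExperimentConfig,
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a wide abundance table: analyte-id column + one column per channel.

    Columns not named in the design are ignored with a warning; a design
    channel missing from the file is a SchemaError naming the column, and
    duplicated analyte ids are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), float_precision="round_trip")
    idcol = config.analyte_column
    if idcol not in df.columns:
        raise SchemaError(f"{path}: missing analyte-id column {idcol!r}")
    missing = [c for c in config.design.labels if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing channel column(s) {missing}")
    if df[idcol].duplicated().any():
        dupes = df.loc[df[idcol].duplicated(), idcol].unique()[:5].tolist()
        raise SchemaError(f"{path}: duplicate analyte ids, e.g. {dupes}")
    extra = [c for c in df.columns if c != idcol and c not in config.design.labels]
    if extra:
        warnings.warn(f"{path}: ignoring {len(extra)} unmapped column(s): {extra[:5]}")
    return df.set_index(idcol)[config.design.labels]


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a table as TSV/CSV with deterministic columns and full precision."""
    path = Path(path)
    if len(df) == 0:
        warnings.warn(f"{path}: writing header-only file (empty input)")
    df.to_csv(path, sep=_sep_for(path, None), index=index, float_format="%.17g")
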