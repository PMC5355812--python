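"""CSV readers/writers and run configuration.

CSV is the only input format (the study data are small tables): UTF-8,
header required, '.' decimal.  Structured outputs are JSON; run
configuration is YAML.  Readers validate hard and report the offending row
number, because silent coercion of a stratigraphic table is how age models
get corrupted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import ProxySeries
from .fractionation import FractionationSystem

logger = logging.getLogger("silutil")

__all__ = [
    "ISOTOPE_COLUMNS",
    "RunConfig",
    "read_proxy_csv",
    "read_isotope_csv",
    "write_proxy_csv",
    "read_assemblage_csv",
    "write_json_report",
]

ISOTOPE_COLUMNS = ("depth_mcd", "age_kyr", "d30si_permil", "sigma_permil")


def _read_validated(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
        if coerced.isna().any():
            raise ValueError(
                f"{path.name}: empty cell in column {col!r} at row "
                f"{coerced.index[coerced.isna()][0] + 2}"
            )
        df[col] = coerced
    return df


def read_proxy_csv(path, name: str, age_column: str = "age_kyr",
                   value_column: str = "value",
                   sigma_column: str | None = None) -> ProxySeries:
    """Read one age/value table into a validated, age-sorted series."""
    cols = (age_column, value_column) + ((sigma_column,) if sigma_column else ())
    df = _read_validated(path, cols)
    df = df.sort_values(age_column, kind="mergesort").reset_index(drop=True)
    dup = df[age_column].duplicated()
    if dup.any():
        raise ValueError(
            f"{Path(path).name}: duplicated age {df[age_column][dup.idxmax()]} "
            f"at sorted row {int(dup.idxmax()) + 2}"
        )
    return ProxySeries(
        name=name,
        ages=df[age_column].to_numpy(),
        values=df[value_column].to_numpy(),
        sigmas=df[sigma_column].to_numpy() if sigma_column else None,
    )


def read_isotope_csv(path) -> pd.DataFrame:
    """Read an isotope table (depth_mcd, age_kyr, d30si_permil, sigma_permil)."""
    df = _read_validated(path, ISOTOPE_COLUMNS)
    df = df.sort_values("age_kyr", kind="mergesort").reset_index(drop=True)
    dup = df["age_kyr"].duplicated()
    if dup.any():
        raise ValueError(
            f"{Path(path).name}: duplicated age_kyr at sorted row {int(dup.idxmax()) + 2}"
        )
    if (df["sigma_permil"] < 0).any():
        raise ValueError(f"{Path(path).name}: negative sigma_permil")
    return df


def write_proxy_csv(series: ProxySeries, path,
                    age_column: str = "age_kyr", value_column: str = "value") -> None:
    cols = {age_column: series.ages, value_column: series.values}
    if series.sigmas is not None:
        cols["sigma"] = series.sigmas
    pd.DataFrame(cols).to_csv(path, index=False)


def read_assemblage_csv(path) -> pd.DataFrame:
    """Read an assemblage table (age_kyr, taxon, rel_abundance_pct[, eco_class])."""
    df = _read_validated(path, ("age_kyr", "rel_abundance_pct"))
    if "taxon" not in df.columns:
        raise ValueError(f"{Path(path).name}: missing required column(s) ['taxon']")
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, cls=_NumpyEncoder,
                                     allow_nan=True) + "\n", encoding="utf-8")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, YAML-loadable."""

    isotope_csv: str | None = None
    covariate_csvs: dict[str, str] = field(default_factory=dict)
    delta_source: float = 1.4
    epsilon: float = -1.2
    epsilon_sd: float = 0.1
    delta_source_sd: float = 0.0
    tolerance_years: float = 50.0
    transform: str = "sqrt"
    max_zones: int = 10
    dca_threshold: float = 1.5
    gap_exempt: tuple[str, ...] = ("sww_clay_silt",)
    clamp: bool = True
    seed: int = 1
    output_dir: str = "silutil_output"

    def __post_init__(self) -> None:
        if self.dca_threshold <= 0:
            raise ValueError("dca_threshold must be positive")

    @property
    def system(self) -> FractionationSystem:
        return FractionationSystem(
            delta_source=self.delta_source,
            epsilon=self.epsilon,
            epsilon_sd=self.epsilon_sd,
            delta_source_sd=self.delta_source_sd,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "gap_exempt" in raw:
            raw["gap_exempt"] = tuple(raw["gap_exempt"])
        return cls(**raw)
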