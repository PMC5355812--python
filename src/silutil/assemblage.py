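"""Diatom assemblage composition and the cryophilic mass-balance bound.

Diatoms that grow inside sea-ice brine channels (cryophilic taxa) do so in a
semi-closed system and carry a heavier silicon-isotope composition than
open-water populations.  Because they are thinly silicified they are rare in
the sediment record, but a bulk-opal delta30Si measurement is still a
mixture.  This module inverts the two-end-member mixing relation

    delta_measured = p * delta_cryophilic + (1 - p) * delta_open

to recover the open-water component, and sweeps (p, offset) grids to bound
the worst-case distortion of the record and of the derived utilization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fractionation import FractionationSystem, WAP_SYSTEM

logger = logging.getLogger("silutil")

__all__ = [
    "ECO_CLASSES",
    "DEFAULT_TAXONOMY",
    "AssemblageSample",
    "mixing_correct_delta",
    "forward_mixing",
    "cryophilic_fraction",
    "cryophilic_sensitivity",
    "assign_eco_classes",
]

#: Closed vocabulary of ecological classes.
ECO_CLASSES = frozenset({"cryophilic", "sea_ice_associated", "open_water"})

#: Default taxon -> ecological class lookup.  Cryophilic taxa live within or
#: attached to sea ice (brine channels); sea-ice-associated taxa bloom in
#: open water seeded from the retreating ice edge; Hyalochaete Chaetoceros
#: resting spores dominate the open-water spring bloom.
DEFAULT_TAXONOMY: dict[str, str] = {
    "Amphiprora kjellmanii": "cryophilic",
    "Nitzschia stellata": "cryophilic",
    "Nitzschia lecointei": "cryophilic",
    "Pinnularia quadratarea": "cryophilic",
    "Pleurosigma sp.": "cryophilic",
    "Berkleya sp.": "cryophilic",
    "Fragilariopsis curta": "sea_ice_associated",
    "Fragilariopsis cylindrus": "sea_ice_associated",
    "Hyalochaete chaetoceros": "open_water",
}


@dataclass(frozen=True)
class AssemblageSample:
    """Per-sample taxon relative abundances with ecological class labels.

    ``abundances`` holds (taxon, rel_abundance as fraction, eco_class)
    triples; abundances must be non-negative and sum to at most 1.
    """

    age: float  # kyr BP
    abundances: tuple[tuple[str, float, str], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for taxon, ab, eco in self.abundances:
            if ab < 0:
                raise ValueError(f"negative abundance for {taxon}")
            if eco not in ECO_CLASSES:
                raise ValueError(
                    f"unknown eco_class {eco!r} for {taxon}; "
                    f"must be one of {sorted(ECO_CLASSES)}"
                )
            total += ab
        if total > 1 + 1e-9:
            raise ValueError(f"abundances sum to {total:.6f} > 1")


def cryophilic_fraction(sample: AssemblageSample) -> float:
    """Total relative abundance of cryophilic taxa in a sample."""
    return sum(ab for _, ab, eco in sample.abundances if eco == "cryophilic")


def forward_mixing(delta_open, p_cryophilic, delta_cryophilic):
    """Bulk delta30Si of a two-component mixture (forward model)."""
    return p_cryophilic * np.asarray(delta_cryophilic, float) + (
        1.0 - p_cryophilic
    ) * np.asarray(delta_open, float)


def mixing_correct_delta(delta_measured, p_cryophilic, delta_cryophilic):
    """Recover the non-cryophilic delta30Si component from a bulk value.

    Exact inverse of :func:`forward_mixing`:
    ``delta_open = (delta_measured - p * delta_cryophilic) / (1 - p)``.
    Raises for ``p >= 1`` (the open-water component vanishes).
    """
    p = float(p_cryophilic)
    if not 0 <= p < 1:
        raise ValueError(f"p_cryophilic must lie in [0, 1), got {p}")
    d = np.asarray(delta_measured, float)
    out = (d - p * np.asarray(delta_cryophilic, float)) / (1.0 - p)
    return float(out) if np.ndim(delta_measured) == 0 else out


def cryophilic_sensitivity(
    deltas,
    p_values,
    offsets,
    system: FractionationSystem = WAP_SYSTEM,
) -> pd.DataFrame:
    """Grid sweep of the cryophilic mixing correction.

    For every (p, offset) pair the cryophilic end member is placed ``offset``
    per mil above each measured value (brine-channel opal is heavier), the
    mixing correction is applied to every measurement in ``deltas``, and the
    worst-case delta shift and the induced open-system utilization shift are
    tabulated.  Under the linear open model the utilization shift is the
    delta shift divided by ``|epsilon|``.

    Returns a DataFrame with columns ``p, offset_permil, max_abs_shift_permil,
    max_abs_utilization_shift`` (utilization shift as a fraction).
    """
    deltas = np.atleast_1d(np.asarray(deltas, float))
    p_values = np.atleast_1d(np.asarray(p_values, float))
    offsets = np.atleast_1d(np.asarray(offsets, float))
    if deltas.size == 0 or p_values.size == 0 or offsets.size == 0:
        raise ValueError("empty grid: deltas, p_values and offsets must be non-empty")
    if np.any((p_values < 0) | (p_values > 0.05)):
        raise ValueError("p_values must lie in [0, 0.05]")
    rows = []
    for p in p_values:
        for off in offsets:
            corrected = mixing_correct_delta(deltas, p, deltas + off)
            shift = corrected - deltas  # = -p*off/(1-p), uniform over deltas
            max_shift = float(np.max(np.abs(shift)))
            rows.append(
                {
                    "p": float(p),
                    "offset_permil": float(off),
                    "max_abs_shift_permil": max_shift,
                    "max_abs_utilization_shift": max_shift / abs(system.epsilon),
                }
            )
    return pd.DataFrame(rows)


def assign_eco_classes(
    table: pd.DataFrame,
    override: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fill/validate the ``eco_class`` column of an assemblage table.

    ``table`` needs columns ``taxon`` and optionally ``eco_class``; missing
    classes are looked up in :data:`DEFAULT_TAXONOMY` updated with
    ``override``.  Unknown taxa default to ``open_water`` with a warning.
    """
    lookup = dict(DEFAULT_TAXONOMY)
    if override:
        bad = {v for v in override.values()} - ECO_CLASSES
        if bad:
            raise ValueError(f"override contains unknown eco classes: {sorted(bad)}")
        lookup.update(override)
    out = table.copy()
    if "eco_class" not in out.columns:
        out["eco_class"] = pd.NA
    unknown = set()

    def _resolve(row):
        if pd.notna(row["eco_class"]):
            if row["eco_class"] not in ECO_CLASSES:
                raise ValueError(
                    f"unknown eco_class {row['eco_class']!r} for {row['taxon']}"
                )
            return row["eco_class"]
        cls = lookup.get(row["taxon"])
        if cls is None:
            unknown.add(row["taxon"])
            return "open_water"
        return cls

    out["eco_class"] = out.apply(_resolve, axis=1)
    if unknown:
        logger.warning(
            "taxa missing from taxonomy, defaulted to open_water: %s",
            ", ".join(sorted(unknown)),
        )
    return out
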