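"""Putting covariate records on the isotope sample ages.

The isotope series defines the master age grid; covariates sampled on their
own (often coarser or offset) grids are linearly interpolated to those ages.
Interpolation across a large age gap manufactures information, so a target
age whose distance to the *nearest original observation* of a covariate
exceeds a tolerance (50 years by default) is excluded rather than
interpolated, and every exclusion is logged with the triggering gap.
Coarse-resolution covariates (the westerly-wind clay/silt ratio) may be
declared exempt from the gap rule; they are interpolated regardless but
flagged.  No extrapolation ever happens: targets outside a covariate's span
are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("silutil")

__all__ = [
    "ProxySeries",
    "AlignedMatrix",
    "interpolate_to_ages",
    "age_gap_filter",
    "build_matrix",
]


@dataclass(frozen=True)
class ProxySeries:
    """Ordered (age, value[, sigma]) samples for one stratigraphic variable.

    Ages are kyr BP, strictly increasing (youngest first).
    """

    name: str
    ages: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if self.sigmas is not None:
            object.__setattr__(self, "sigmas", np.asarray(self.sigmas, dtype=float))
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ValueError("ages and values must be 1-D and the same length")
        if ages.size == 0:
            raise ValueError(f"series {self.name!r} is empty")
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"series {self.name!r}: ages must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.name!r}: missing values inside the span")

    def __len__(self) -> int:
        return int(self.ages.size)

    @property
    def span(self) -> tuple[float, float]:
        return (float(self.ages[0]), float(self.ages[-1]))


@dataclass
class AlignedMatrix:
    """Samples x variables table on the isotope ages, with exclusion log.

    ``data`` is indexed by retained target ages (column ``age_kyr`` kept as
    the index name); ``exclusion_log`` has one row per (age, variable) drop
    with the triggering gap in years (``inf`` marks an out-of-span target).
    """

    data: pd.DataFrame
    exclusion_log: pd.DataFrame
    flagged_variables: tuple[str, ...] = ()

    @property
    def n_excluded_rows(self) -> int:
        if self.exclusion_log.empty:
            return 0
        return int(self.exclusion_log["age_kyr"].nunique())


def interpolate_to_ages(series: ProxySeries, target_ages):
    """Piecewise-linear interpolation of a series at target ages.

    Returns ``(values, in_span)``: values are NaN where the target lies
    outside the series span (never extrapolated), and ``in_span`` marks the
    valid targets.  Coincident ages pass the observed value through exactly.
    """
    t = np.asarray(target_ages, dtype=float)
    lo, hi = series.span
    in_span = (t >= lo) & (t <= hi)
    vals = np.interp(t, series.ages, series.values)
    vals = np.where(in_span, vals, np.nan)
    return vals, in_span


def age_gap_filter(
    series: ProxySeries,
    target_ages,
    tolerance_years: float = 50.0,
    rule: str = "nearest",
):
    """Keep/drop mask for targets by age distance to original observations.

    ``rule="nearest"`` measures the gap to the nearest observation of the
    series; ``rule="bracket"`` uses the farther of the two bracketing
    observations (out-of-span targets get an infinite gap under either
    rule).  Returns ``(keep, gaps_years)``.
    """
    if tolerance_years <= 0:
        raise ValueError("tolerance_years must be positive")
    if rule not in ("nearest", "bracket"):
        raise ValueError(f"unknown gap rule {rule!r}")
    t = np.asarray(target_ages, dtype=float)
    obs = series.ages
    lo, hi = series.span
    if rule == "nearest":
        gaps_kyr = np.min(np.abs(t[:, None] - obs[None, :]), axis=1)
    else:
        idx = np.searchsorted(obs, t)
        left = np.where(idx > 0, t - obs[np.clip(idx - 1, 0, len(obs) - 1)], np.inf)
        right = np.where(idx < len(obs), obs[np.clip(idx, 0, len(obs) - 1)] - t, np.inf)
        exact = np.isin(t, obs)
        gaps_kyr = np.where(exact, 0.0, np.maximum(left, right))
    gaps_years = gaps_kyr * 1000.0  # ages in kyr, tolerance quoted in years
    gaps_years = np.where((t < lo) | (t > hi), np.inf, gaps_years)
    keep = gaps_years <= tolerance_years
    return keep, gaps_years


def build_matrix(
    isotope_ages,
    utilization,
    covariates: dict[str, ProxySeries],
    tolerance_years: float = 50.0,
    zone_spans: dict[str, tuple[float, float]] | None = None,
    exempt: tuple[str, ...] = (),
    joint: bool = True,
    gap_rule: str = "nearest",
):
    """Assemble aligned samples x variables matrices, applying the gap rule.

    Parameters
    ----------
    isotope_ages, utilization : array-like
        The master grid (isotope sample ages, kyr BP, increasing) and the
        utilization values carried into the matrix.
    covariates : dict
        name -> :class:`ProxySeries` on native sampling.
    tolerance_years : float
        Maximum age gap to the nearest covariate observation; ``math.inf``
        disables filtering.
    zone_spans : dict, optional
        label -> (young, old) age span; when given, one matrix per span is
        returned as a dict, with rows restricted to isotope ages inside it.
    exempt : tuple of str
        Covariate names exempt from the gap rule (coarse series); they are
        interpolated regardless and reported in ``flagged_variables``.
    joint : bool
        Drop a row when ANY non-exempt covariate over-gaps (default); with
        ``False`` each covariate only logs its own exclusions and offending
        cells are set to NaN instead of dropping the row.

    Returns
    -------
    AlignedMatrix or dict[str, AlignedMatrix]
    """
    ages = np.asarray(isotope_ages, dtype=float)
    util = np.asarray(utilization, dtype=float)
    if ages.shape != util.shape:
        raise ValueError("isotope_ages and utilization must match in length")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("isotope ages must be strictly increasing")

    cols = {"utilization": util}
    keep_joint = np.ones(ages.size, dtype=bool)
    log_rows = []
    cell_bad = {}
    for name, series in covariates.items():
        vals, in_span = interpolate_to_ages(series, ages)
        cols[name] = vals
        if name in exempt:
            # interpolated without the gap rule; span is still respected
            bad = ~in_span
            for i in np.flatnonzero(bad):
                log_rows.append(
                    {"age_kyr": float(ages[i]), "variable": name, "gap_years": np.inf}
                )
        else:
            if math.isfinite(tolerance_years):
                keep, gaps = age_gap_filter(series, ages, tolerance_years, rule=gap_rule)
            else:
                keep = in_span.copy()
                gaps = np.where(in_span, 0.0, np.inf)
            bad = ~keep
            for i in np.flatnonzero(bad):
                log_rows.append(
                    {"age_kyr": float(ages[i]), "variable": name,
                     "gap_years": float(gaps[i])}
                )
            keep_joint &= keep
        cell_bad[name] = bad

    log = pd.DataFrame(log_rows, columns=["age_kyr", "variable", "gap_years"])

    def _assemble(row_mask) -> AlignedMatrix:
        df = pd.DataFrame(cols, index=pd.Index(ages, name="age_kyr"))
        sel = row_mask & keep_joint if joint else row_mask
        df = df.loc[sel].copy()
        if not joint:
            for name, bad in cell_bad.items():
                df.loc[bad[sel], name] = np.nan
        sub_log = log[log["age_kyr"].isin(ages[row_mask])] if not log.empty else log
        if len(df) < 3:
            logger.warning("aligned matrix has %d retained rows (<3); "
                           "ordination will refuse it", len(df))
        return AlignedMatrix(data=df, exclusion_log=sub_log.reset_index(drop=True),
                             flagged_variables=tuple(n for n in covariates if n in exempt))

    if zone_spans is None:
        return _assemble(np.ones(ages.size, dtype=bool))
    out = {}
    for label, (young, old) in zone_spans.items():
        lo, hi = min(young, old), max(young, old)
        out[label] = _assemble((ages >= lo) & (ages <= hi))
    return out
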