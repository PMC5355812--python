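"""End-to-end pipeline: convert -> zones -> align -> ordinate.

Orchestrates the stage functions into one reproducible run and writes a
machine-readable JSON report plus per-stage CSVs.  Every number in the
report is computed by a stage and persisted alongside it; the report also
records the exact fractionation constants used so it is self-describing.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import ProxySeries, build_matrix
from .fractionation import convert_dataframe
from .io import RunConfig, read_isotope_csv, read_proxy_csv, write_json_report
from .ordination import dca_gradient_length, pca_with_scaling, trend_test
from .zonation import coniss_cluster, zone_difference_test, zone_stats

logger = logging.getLogger("silutil")

__all__ = ["run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(
    config: RunConfig,
    isotopes: pd.DataFrame | None = None,
    covariates: dict[str, ProxySeries] | None = None,
) -> dict:
    """Run the full chain and return (and persist) the report dict.

    Inputs may be passed in-memory (``isotopes`` dataframe with the
    standard isotope columns, ``covariates`` name -> series) or read from
    the paths in ``config``.  Outputs land in ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "fractionation_system": {
            "delta_source_permil": config.delta_source,
            "epsilon_permil": config.epsilon,
            "epsilon_sd_permil": config.epsilon_sd,
            "delta_source_sd_permil": config.delta_source_sd,
        },
        "config": {
            "tolerance_years": config.tolerance_years,
            "transform": config.transform,
            "max_zones": config.max_zones,
            "dca_threshold": config.dca_threshold,
            "seed": config.seed,
        },
        "status": "partial",
    }

    def _persist():
        write_json_report(report, out / "report.json")

    stage = "load"
    try:
        if isotopes is None:
            if config.isotope_csv is None:
                raise ValueError("no isotope input: pass a dataframe or set isotope_csv")
            isotopes = read_isotope_csv(config.isotope_csv)
        if covariates is None:
            covariates = {
                name: read_proxy_csv(path, name)
                for name, path in config.covariate_csvs.items()
            }

        stage = "convert"
        converted = convert_dataframe(isotopes, config.system, clamp=config.clamp)
        converted.to_csv(out / "utilization.csv", index=False)
        logger.info("convert: %d samples, delta_source=%+.2f, epsilon=%+.2f",
                    len(converted), config.delta_source, config.epsilon)

        stage = "zones"
        util = converted["utilization_pct"].to_numpy() / 100.0
        ages = converted["age_kyr"].to_numpy()
        zres = coniss_cluster(util, ages, transform=config.transform,
                              max_zones=config.max_zones)
        stats = zone_stats(util * 100.0, zres.zones)
        stats.to_csv(out / "zone_stats.csv", index=False)
        zres.broken_stick_table.to_csv(out / "broken_stick.csv", index=False)
        labels = np.empty(len(util), dtype=object)
        for z in zres.zones:
            labels[list(z.sample_indices)] = z.label
        converted.assign(zone=labels).to_csv(out / "zoned_samples.csv", index=False)
        report["zonation"] = {
            "n_significant": zres.n_significant,
            "boundary_ages_kyr": list(zres.boundary_ages.get(zres.n_significant, ())),
            "zones": stats.to_dict(orient="records"),
            "broken_stick": zres.broken_stick_table.to_dict(orient="records"),
        }
        if len(zres.zones) >= 2:
            a = util[list(zres.zones[0].sample_indices)]
            b = util[list(zres.zones[-1].sample_indices)]
            report["zonation"]["zone_difference_p"] = zone_difference_test(a, b)
        slope, p = trend_test(converted["d30si_permil"].to_numpy(), ages)
        report["trend"] = {"d30si_slope_permil_per_kyr": slope, "p_value": p}

        stage = "align"
        spans = {z.label: z.age_span for z in zres.zones}
        spans["all"] = (float(ages[0]), float(ages[-1]))
        matrices = build_matrix(
            ages, util * 100.0, covariates,
            tolerance_years=config.tolerance_years,
            zone_spans=spans, exempt=tuple(config.gap_exempt),
        )
        all_log = matrices["all"].exclusion_log
        all_log.to_csv(out / "exclusion_log.csv", index=False)
        report["alignment"] = {
            "n_excluded_rows": matrices["all"].n_excluded_rows,
            "exclusions": all_log.replace([np.inf], "out_of_span")
                                 .to_dict(orient="records"),
        }

        stage = "ordinate"
        report["ordination"] = {}
        for label, mat in matrices.items():
            if len(mat.data) < 3:
                logger.warning("skipping ordination for %s: only %d rows",
                               label, len(mat.data))
                continue
            screen = dca_gradient_length(mat.data, threshold=config.dca_threshold)
            entry = {
                "n_rows": len(mat.data),
                "dca_gradient_length_sd": screen.gradient_length_sd,
                "response": "linear" if screen.is_linear else "unimodal",
            }
            if screen.is_linear:
                pca = pca_with_scaling(mat.data)
                pca.sample_scores.to_csv(out / f"pca_scores_{label.replace(' ', '_')}.csv")
                pca.variable_loadings.to_csv(
                    out / f"pca_loadings_{label.replace(' ', '_')}.csv")
                entry["pca_eigenvalues"] = pca.eigenvalues.tolist()
                entry["pca_axis_variance_fractions"] = pca.axis_variance_fractions.tolist()
            report["ordination"][label] = entry

        report["status"] = "ok"
        _persist()
        return report
    except Exception as exc:  # persist partial results, then re-raise with stage
        report["failed_stage"] = stage
        _persist()
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
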