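"""End-to-end orchestration: calibrate -> fit -> QC -> aggregate -> call -> network.

The in-memory pipeline used by the command line, the simulator round trips,
and the tests. Every stage records how many records it received and how many
each filter removed ("filter ledger"), so a run is auditable and two runs on
identical inputs are comparable record by record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binfit, calibration, diffcall, network, replicates
from .data_io import BinSpec, LibraryAnnotation, VariantBinCounts

__all__ = ["PipelineResult", "fit_all", "analyze"]


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    aggregates: list[replicates.AggregatedActivity]
    calls: list[diffcall.DifferentialCall]
    edges: list[network.RegulatoryEdge]
    ledger: dict = field(default_factory=dict)

    @property
    def aggregates_frame(self) -> pd.DataFrame:
        return replicates.aggregates_to_frame(self.aggregates)

    @property
    def calls_frame(self) -> pd.DataFrame:
        return diffcall.calls_to_frame(self.calls)


def _bins_for(bins: Mapping[str, Sequence[BinSpec]] | Sequence[BinSpec], rep: str):
    if isinstance(bins, Mapping):
        if rep not in bins:
            raise KeyError(f"no bin spec for replicate {rep!r}")
        return bins[rep]
    return bins


def fit_all(
    bins: Mapping[str, Sequence[BinSpec]] | Sequence[BinSpec],
    counts: Sequence[VariantBinCounts],
    cal_config: calibration.CalibrationConfig | None = None,
    fit_config: binfit.FitConfig | None = None,
) -> pd.DataFrame:
    """Calibrate and fit every variant; one row per (variant, replicate)."""
    cal_config = cal_config or calibration.CalibrationConfig()
    fit_config = fit_config or binfit.FitConfig()
    rows = []
    for rec in counts:
        b = _bins_for(bins, rec.replicate_id)
        try:
            cells = calibration.estimate_cells(rec, b, cal_config)
            occ = calibration.occupancy(cells, cal_config)
            fit = binfit.fit_lognormal(occ, b, fit_config)
        except calibration.CalibrationError:
            fit = binfit.LogNormalFit(
                np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, {"degenerate_occupancy"}
            )
        binfit.apply_qc(fit, fit_config)
        rows.append(
            (
                rec.sgrna_id,
                rec.promoter_id,
                rec.replicate_id,
                fit.mu,
                fit.sigma,
                fit.mean_activity,
                fit.kl,
                fit.total_cells,
                ";".join(sorted(fit.qc_flags)),
                fit.usable,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sgrna_id", "promoter_id", "replicate_id", "mu", "sigma",
            "mean_activity", "kl", "total_cells", "qc_flags", "usable",
        ],
    )


def analyze(
    bins: Mapping[str, Sequence[BinSpec]] | Sequence[BinSpec],
    counts: Sequence[VariantBinCounts],
    library: LibraryAnnotation,
    cal_config: calibration.CalibrationConfig | None = None,
    fit_config: binfit.FitConfig | None = None,
    thresholds: diffcall.CallThresholds | None = None,
    reference_replicate: str | None = None,
    controls_exclude: Sequence[str] = (),
    s_max: float = 0.7,
    iqr_multiplier: float = 1.5,
    condition: str = "",
) -> PipelineResult:
    """Run the full analysis on one growth condition.

    ``reference_replicate`` defaults to the last replicate present (the
    screen's convention of rescaling earlier replicates onto the final
    sort's scale). The ledger counts records entering and leaving every
    filtering stage.
    """
    fits = fit_all(bins, counts, cal_config, fit_config)
    reps = sorted(fits["replicate_id"].unique())
    if reference_replicate is None:
        reference_replicate = reps[-1]

    ledger: dict = {"n_variant_replicates": int(len(fits))}
    flags = fits["qc_flags"].str.split(";")
    for flag in binfit.QC_FLAGS:
        ledger[f"qc_{flag}"] = int(sum(flag in fl for fl in flags))
    ledger["n_usable_fits"] = int(fits["usable"].sum())

    if len(reps) > 1:
        maps = replicates.fit_rescale(fits, reference_replicate)
    else:
        maps = {reps[0]: replicates.RescaleMap(reps[0], 1.0, 0.0, reps[0])}
    rescaled = replicates.apply_rescale(fits, maps)
    aggregates = replicates.aggregate(
        rescaled, library, controls_exclude, s_max=s_max, iqr_multiplier=iqr_multiplier
    )
    pert = [a for a in aggregates if a.role == "perturbation"]
    ledger["n_aggregates"] = len(pert)
    ledger["agg_high_S"] = sum(a.exclude_reason == "high_S" for a in pert)
    ledger["agg_insufficient_n"] = sum(a.exclude_reason == "insufficient_n" for a in pert)

    calls = diffcall.call_differential(aggregates, library, thresholds)
    ledger["n_calls_na"] = sum(c.call == "na" for c in calls)
    ledger["n_calls_up"] = sum(c.call == "up" for c in calls)
    ledger["n_calls_down"] = sum(c.call == "down" for c in calls)
    ledger["n_calls_ns"] = sum(c.call == "ns" for c in calls)

    edges = network.build_network(calls, condition)
    ledger["n_edges"] = len(edges)
    return PipelineResult(fits, aggregates, calls, edges, ledger)
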