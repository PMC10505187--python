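"""Cross-replicate harmonization and per-variant aggregation.

Independent sorts drift in absolute fluorescence calibration, so each
replicate's log promoter activities are mapped onto a reference replicate's
scale by ordinary least squares over the variants both replicates measured
cleanly. Aggregation then yields, per variant, the mean M_i, sample standard
deviation S_i (n-1 denominator) and sample count n_i of rescaled log
activity across replicates. For each promoter, a control reference (M_i0,
S_i0, n_i0) pools the non-targeting sgRNAs across replicates as independent
samples, after removing outliers by the interquartile-range rule
(fences Q1 - 1.5 IQR, Q3 + 1.5 IQR, linear-interpolation quantiles).
Variants with S_i above ``s_max`` (default 0.7) are excluded as
irreproducible; variants seen in a single replicate carry no S and are
excluded from Z-testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import LibraryAnnotation

__all__ = [
    "RescaleError",
    "RescaleMap",
    "AggregatedActivity",
    "fit_rescale",
    "apply_rescale",
    "aggregate",
    "iqr_filter",
]

MIN_SHARED_VARIANTS = 20


class RescaleError(ValueError):
    pass


@dataclass(frozen=True)
class RescaleMap:
    """Affine map taking one replicate's log activity onto the reference scale."""

    replicate_id: str
    slope: float
    intercept: float
    reference_replicate: str

    def __call__(self, log_activity: np.ndarray | float) -> np.ndarray | float:
        return self.slope * log_activity + self.intercept


@dataclass
class AggregatedActivity:
    """Per-variant (or per-promoter control) replicate summary.

    ``role`` is "perturbation" for TF-targeting variants and "control" for
    the pooled non-targeting reference of a promoter (whose ``sgrna_id`` is
    the sentinel "pooled_controls"). ``excluded`` carries the reason:
    high_S (S above the reproducibility cutoff), insufficient_n (a single
    qualifying sample, so S is undefined), or control_missing.
    """

    sgrna_id: str
    promoter_id: str
    role: str
    M: float
    S: float
    n: int
    excluded: bool = False
    exclude_reason: str = ""


def _usable_log_table(fits: pd.DataFrame) -> pd.DataFrame:
    need = {"sgrna_id", "promoter_id", "replicate_id", "mean_activity", "usable"}
    missing = need - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    out = fits.loc[fits["usable"].astype(bool)].copy()
    out["log_activity"] = np.log(out["mean_activity"].astype(float))
    return out


def fit_rescale(
    fits: pd.DataFrame, reference_replicate: str
) -> dict[str, RescaleMap]:
    """OLS rescale of every replicate's log activity onto the reference.

    For each non-reference replicate, regress the reference's log activity on
    the replicate's own, over variants usable in both; the fitted line maps
    that replicate onto the reference scale. Requires at least
    ``MIN_SHARED_VARIANTS`` shared usable variants per replicate.
    """
    usable = _usable_log_table(fits)
    reps = sorted(usable["replicate_id"].unique())
    if reference_replicate not in reps:
        raise RescaleError(f"reference replicate {reference_replicate!r} has no usable fits")
    key = ["sgrna_id", "promoter_id"]
    ref = usable.loc[usable["replicate_id"] == reference_replicate, key + ["log_activity"]]
    maps = {
        reference_replicate: RescaleMap(reference_replicate, 1.0, 0.0, reference_replicate)
    }
    for rep in reps:
        if rep == reference_replicate:
            continue
        other = usable.loc[usable["replicate_id"] == rep, key + ["log_activity"]]
        shared = ref.merge(other, on=key, suffixes=("_ref", "_rep"))
        if len(shared) < MIN_SHARED_VARIANTS:
            raise RescaleError(
                f"replicate {rep!r} shares only {len(shared)} usable variants "
                f"with the reference (need >= {MIN_SHARED_VARIANTS})"
            )
        slope, intercept = np.polyfit(
            shared["log_activity_rep"], shared["log_activity_ref"], deg=1
        )
        maps[rep] = RescaleMap(rep, float(slope), float(intercept), reference_replicate)
    return maps


def apply_rescale(fits: pd.DataFrame, maps: Mapping[str, RescaleMap]) -> pd.DataFrame:
    """Return usable fits with a ``rescaled_log_activity`` column added."""
    usable = _usable_log_table(fits)
    missing = set(usable["replicate_id"].unique()) - set(maps)
    if missing:
        raise RescaleError(f"no rescale map for replicate(s): {sorted(missing)}")
    usable["rescaled_log_activity"] = [
        maps[rep](x) for rep, x in zip(usable["replicate_id"], usable["log_activity"])
    ]
    return usable


def iqr_filter(values: np.ndarray, multiplier: float = 1.5) -> np.ndarray:
    """Boolean keep-mask under the Tukey fence rule."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return np.zeros(0, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return (values >= lo) & (values <= hi)


def aggregate(
    rescaled: pd.DataFrame,
    library: LibraryAnnotation,
    controls_exclude: Sequence[str] = (),
    s_max: float = 0.7,
    iqr_multiplier: float = 1.5,
) -> list[AggregatedActivity]:
    """Aggregate rescaled log activities into per-variant and control summaries.

    Perturbation variants are summarized across replicates; the control
    reference of each promoter pools all non-excluded control sgRNAs across
    replicates as independent samples, IQR-filtered before computing
    (M_i0, S_i0, n_i0). Promoters without any control sample get a
    control row flagged control_missing so downstream calls become NA.
    """
    controls = set(library.control_ids) - set(controls_exclude)
    is_ctrl = rescaled["sgrna_id"].isin(controls)
    dropped = rescaled["sgrna_id"].isin(set(controls_exclude))
    out: list[AggregatedActivity] = []

    pert = rescaled.loc[~is_ctrl & ~dropped]
    for (sg, pr), sub in pert.groupby(["sgrna_id", "promoter_id"], sort=True):
        vals = sub["rescaled_log_activity"].to_numpy(dtype=float)
        n = len(vals)
        m = float(np.mean(vals))
        if n >= 2:
            s = float(np.std(vals, ddof=1))
            excluded, reason = (s > s_max), ("high_S" if s > s_max else "")
        else:
            s = float("nan")
            excluded, reason = True, "insufficient_n"
        out.append(
            AggregatedActivity(str(sg), str(pr), "perturbation", m, s, n, excluded, reason)
        )

    ctrl = rescaled.loc[is_ctrl]
    for pr in sorted(rescaled["promoter_id"].unique()):
        vals = ctrl.loc[ctrl["promoter_id"] == pr, "rescaled_log_activity"].to_numpy(
            dtype=float
        )
        if len(vals) == 0:
            out.append(
                AggregatedActivity(
                    "pooled_controls", str(pr), "control",
                    float("nan"), float("nan"), 0, True, "control_missing",
                )
            )
            continue
        keep = iqr_filter(vals, iqr_multiplier)
        vals = vals[keep]
        n = len(vals)
        m = float(np.mean(vals))
        s = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        excluded = n < 2
        out.append(
            AggregatedActivity(
                "pooled_controls", str(pr), "control", m, s, n,
                excluded, "insufficient_n" if excluded else "",
            )
        )
    return out


def aggregates_to_frame(records: Iterable[AggregatedActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.sgrna_id, r.promoter_id, r.role, r.M, r.S, r.n, r.excluded, r.exclude_reason)
            for r in records
        ],
        columns=["sgrna_id", "promoter_id", "role", "M", "S", "n", "excluded", "exclude_reason"],
    )
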