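"""Differential promoter-activity calls under TF knockdown.

Because promoter activity is log-normal, comparing *means* of the activity
(not of its logarithm) between a knockdown variant and its promoter's
negative-control reference uses the log-normal mean-comparison Z statistic

    Z = [ M - M0 + (S^2 - S0^2)/2 ]
        / sqrt( S^2/n + S0^2/n0 + (S^4/(n-1) + S0^4/(n0-1))/2 )

where (M, S, n) summarize rescaled log activity across replicates for the
variant and (M0, S0, n0) for the pooled controls. Two-sided p-values come
from the standard normal reference; the false discovery rate over all
testable variant-promoter pairs in a condition is controlled either by
Storey's q-value procedure or Benjamini-Hochberg. A call additionally
requires a substantial effect: fold change above ``min_fold`` (default 1.7)
relative to *both* the control reference and the promoter's median activity
across all knockdown conditions — the latter guards against the handful of
promoters whose control level is itself atypical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .data_io import LibraryAnnotation
from .replicates import AggregatedActivity

__all__ = [
    "CallThresholds",
    "DifferentialCall",
    "z_score",
    "fdr_adjust",
    "storey_qvalues",
    "call_differential",
    "promoter_median_M",
]


@dataclass(frozen=True)
class CallThresholds:
    min_fold: float = 1.7
    max_q: float = 0.01
    fdr_method: str = "qvalue"  # or "bh"

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")
        if not 0 < self.max_q < 1:
            raise ValueError("max_q must be in (0, 1)")
        if self.fdr_method not in {"qvalue", "bh"}:
            raise ValueError("fdr_method must be 'qvalue' or 'bh'")


@dataclass
class DifferentialCall:
    sgrna_id: str
    promoter_id: str
    target_tf: str
    Z: float
    p: float
    q: float
    fold_vs_control: float
    fold_vs_median: float
    call: str  # up | down | ns | na


def z_score(perturbed: AggregatedActivity, control: AggregatedActivity) -> float:
    """Log-normal mean-comparison Z statistic (see module docstring).

    Both sides need n >= 2 so the sample standard deviations exist.
    """
    for side in (perturbed, control):
        if side.n < 2 or not math.isfinite(side.S):
            raise ValueError("z_score needs n >= 2 and a defined S on both sides")
    m, s, n = perturbed.M, perturbed.S, perturbed.n
    m0, s0, n0 = control.M, control.S, control.n
    num = m - m0 + 0.5 * (s * s - s0 * s0)
    var = s * s / n + s0 * s0 / n0 + 0.5 * (s**4 / (n - 1) + s0**4 / (n0 - 1))
    return num / math.sqrt(var)


def storey_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95 as
    #{p > lambda} / (m (1 - lambda)), smoothed by a cubic polynomial in
    lambda and evaluated at the largest lambda, clipped to (0, 1]. q-values
    are the pi0-scaled step-up minima, monotone nondecreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0)
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m < 100 or np.all(pi0_lam == 0):
        pi0 = 1.0  # too few tests to estimate pi0 stably
    else:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam[-1]))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * ranked * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def fdr_adjust(p_values: Sequence[float], method: str = "qvalue") -> np.ndarray:
    """Adjust a family of p-values for multiple testing.

    ``method="qvalue"`` runs the Storey procedure; ``method="bh"`` the
    Benjamini-Hochberg step-up (equivalent to Storey with pi0 fixed at 1).
    """
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        return storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def promoter_median_M(aggregates: Iterable[AggregatedActivity]) -> dict[str, float]:
    """Median rescaled log activity per promoter over usable knockdown variants."""
    df = pd.DataFrame(
        [
            (a.promoter_id, a.M)
            for a in aggregates
            if a.role == "perturbation" and not a.excluded
        ],
        columns=["promoter_id", "M"],
    )
    if df.empty:
        return {}
    return df.groupby("promoter_id")["M"].median().to_dict()


def call_differential(
    aggregates: Sequence[AggregatedActivity],
    library: LibraryAnnotation,
    thresholds: CallThresholds | None = None,
) -> list[DifferentialCall]:
    """Run the full Z-test / FDR / dual-fold-change calling over one condition.

    Testable pairs are non-excluded perturbation aggregates whose promoter
    has a usable control reference; everything else is reported with call
    "na". The FDR family is the set of testable pairs in this condition.
    """
    thresholds = thresholds or CallThresholds()
    controls = {
        a.promoter_id: a for a in aggregates if a.role == "control"
    }
    medians = promoter_median_M(aggregates)
    tf_of = dict(
        zip(library.sgrnas["sgrna_id"], library.sgrnas["target_tf"].fillna(""))
    )

    testable: list[tuple[AggregatedActivity, AggregatedActivity]] = []
    calls: list[DifferentialCall] = []
    for agg in aggregates:
        if agg.role != "perturbation":
            continue
        ctrl = controls.get(agg.promoter_id)
        tf = str(tf_of.get(agg.sgrna_id, ""))
        if agg.excluded or ctrl is None or ctrl.excluded or agg.promoter_id not in medians:
            calls.append(
                DifferentialCall(
                    agg.sgrna_id, agg.promoter_id, tf,
                    float("nan"), float("nan"), float("nan"),
                    float("nan"), float("nan"), "na",
                )
            )
            continue
        z = z_score(agg, ctrl)
        p = 2.0 * norm.sf(abs(z))
        fold_ctrl = math.exp(agg.M - ctrl.M)
        fold_med = math.exp(agg.M - medians[agg.promoter_id])
        calls.append(
            DifferentialCall(
                agg.sgrna_id, agg.promoter_id, tf, z, p, float("nan"),
                fold_ctrl, fold_med, "ns",
            )
        )
        testable.append(calls[-1])

    q = fdr_adjust([c.p for c in testable], thresholds.fdr_method)
    for c, qv in zip(testable, q):
        c.q = float(qv)
        f = thresholds.min_fold
        if qv <= thresholds.max_q and c.fold_vs_control >= f and c.fold_vs_median >= f:
            c.call = "up"
        elif (
            qv <= thresholds.max_q
            and c.fold_vs_control <= 1.0 / f
            and c.fold_vs_median <= 1.0 / f
        ):
            c.call = "down"
    return calls


def calls_to_frame(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sgrna_id, c.promoter_id, c.target_tf, c.Z, c.p, c.q,
             c.fold_vs_control, c.fold_vs_median, c.call)
            for c in calls
        ],
        columns=[
            "sgrna_id", "promoter_id", "target_tf", "Z", "p", "q",
            "fold_vs_control", "fold_vs_median", "call",
        ],
    )
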