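"""Synthetic sort-seq experiments with known ground truth.

The generator emulates the statistical structure of a pooled CRISPRi
promoter-reporter sort-seq screen: every sgRNA-promoter variant has
log-normal fluorescence (Normal(mu, sigma) on the natural-log scale); cells
are sorted into J contiguous log-scale gates (16 by default, equally sized
over a log10 window, outer gates open); a ``misallocation`` fraction of
cells lands in a uniformly random gate (the sorter-noise floor that the
eps-adjustment in calibration removes); per-bin sequencing reads are drawn
multinomially over variants proportional to their sorted cells, mirroring
proportional-time sorting followed by pooled library prep; and each
biological replicate redraws the experiment with the variant means jittered
on the log scale.

Regulatory effects live on (TF, promoter) pairs and are realized through
the sgRNA targeting that TF; non-targeting control sgRNAs always carry fold
exactly 1. Defaults reflect a minimal-medium screen: a 1.5..5.0 log10
sorting window, sigma between 0.3 and 0.8 natural-log units, a 5% noise
floor, 5% between-replicate spread, three replicates, and ~2% of TF-promoter
pairs carrying a true effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import BinSpec, LibraryAnnotation, VariantBinCounts, make_bins

__all__ = [
    "EffectModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "recovery_report",
]


@dataclass(frozen=True)
class EffectModel:
    """Distribution of true knockdown effects on promoter activity.

    A ``fraction_nonnull`` share of (TF, promoter) pairs is regulated. Each
    regulated pair's true natural-log fold change is either drawn
    Normal(0, ``log_fold_sd``) or fixed at magnitude ``fixed_log_fold`` with
    sign positive (activity up under knockdown) with probability
    ``up_fraction``.
    """

    fraction_nonnull: float = 0.02
    log_fold_sd: float = 1.0
    fixed_log_fold: float | None = None
    up_fraction: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    n_promoters: int = 20
    n_tfs: int = 20
    n_controls: int = 5
    n_replicates: int = 3
    n_bins: int = 16
    boundary_range_log10: tuple[float, float] = (1.5, 5.0)
    cells_per_variant: int = 1000
    reads_per_bin: int | None = None  # default: 2x expected cells per bin
    misallocation: float = 0.05
    effect_model: EffectModel = field(default_factory=EffectModel)
    replicate_cv: float = 0.05
    sigma_range: tuple[float, float] = (0.3, 0.8)
    mu_range_log10: tuple[float, float] = (2.0, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins")
        if not 0.0 <= self.misallocation <= 1.0:
            raise ValueError("misallocation must be a probability")


@dataclass
class GroundTruth:
    """Per-variant truth plus the per-replicate realized means.

    ``table`` has one row per (sgrna, promoter) with the base natural-log
    mean ``mu_true``, spread ``sigma_true``, the true activity fold under
    knockdown (exactly 1 for controls) and the regulated flag.
    ``replicate_mu`` records the jittered mean actually used for each
    replicate — the proper reference when scoring per-replicate fits.
    """

    table: pd.DataFrame
    replicate_mu: pd.DataFrame


LN10 = math.log(10.0)


def _make_library(config: SimulationConfig) -> LibraryAnnotation:
    tfs = [f"TF{k:03d}" for k in range(1, config.n_tfs + 1)]
    sg_rows = [(f"sg_{tf}", tf, False) for tf in tfs]
    sg_rows += [(f"NC_{k:02d}", "", True) for k in range(1, config.n_controls + 1)]
    sgrnas = pd.DataFrame(sg_rows, columns=["sgrna_id", "target_tf", "is_control"])
    pr_rows = []
    for k in range(1, config.n_promoters + 1):
        own_tf = tfs[k - 1] if k <= config.n_tfs else ""
        pr_rows.append((f"P{k:03d}", f"operon{k:03d}", [f"gene{k:03d}"], own_tf))
    promoters = pd.DataFrame(
        pr_rows, columns=["promoter_id", "operon", "genes", "tf_gene_of_promoter"]
    )
    return LibraryAnnotation(sgrnas=sgrnas, promoters=promoters)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, list[BinSpec]], list[VariantBinCounts], LibraryAnnotation, GroundTruth]:
    """Generate a full synthetic screen.

    Returns per-replicate bin specs (shared boundaries, replicate-specific
    sorted-cell and read totals), dense per-variant read counts, the library
    annotation, and the ground truth. Fixing ``config.seed`` makes the
    output deterministic.
    """
    rng = np.random.default_rng(config.seed)
    library = _make_library(config)
    lo, hi = config.boundary_range_log10
    interior = np.linspace(lo, hi, config.n_bins + 1)[1:-1]
    J = config.n_bins

    promoters = library.promoters["promoter_id"].tolist()
    sgrnas = library.sgrnas

    # baseline promoter means and spreads (natural-log scale)
    mu_base = rng.uniform(
        config.mu_range_log10[0] * LN10, config.mu_range_log10[1] * LN10,
        size=len(promoters),
    )
    sigma = rng.uniform(*config.sigma_range, size=len(promoters))

    # effects per (tf, promoter) pair
    em = config.effect_model
    tfs = [t for t in sgrnas["target_tf"] if t]
    effect: dict[tuple[str, str], float] = {}
    for tf in tfs:
        for pr in promoters:
            if rng.random() < em.fraction_nonnull:
                if em.fixed_log_fold is not None:
                    sign = 1.0 if rng.random() < em.up_fraction else -1.0
                    effect[(tf, pr)] = sign * em.fixed_log_fold
                else:
                    effect[(tf, pr)] = rng.normal(0.0, em.log_fold_sd)

    # per-variant truth
    truth_rows = []
    variant_mu = []
    variant_sigma = []
    variants: list[tuple[str, str]] = []
    for sg, tf in zip(sgrnas["sgrna_id"], sgrnas["target_tf"]):
        for k, pr in enumerate(promoters):
            dlog = effect.get((tf, pr), 0.0) if tf else 0.0
            mu = mu_base[k] + dlog
            variants.append((sg, pr))
            variant_mu.append(mu)
            variant_sigma.append(sigma[k])
            truth_rows.append((sg, pr, mu, sigma[k], math.exp(dlog), dlog != 0.0))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sgrna_id", "promoter_id", "mu_true", "sigma_true", "fold_true", "regulated"],
    )
    variant_mu = np.asarray(variant_mu)
    variant_sigma = np.asarray(variant_sigma)
    n_var = len(variants)

    edges_ln = np.concatenate(([-np.inf], interior * LN10, [np.inf]))
    reads_per_bin = config.reads_per_bin
    if reads_per_bin is None:
        reads_per_bin = max(1, 2 * config.cells_per_variant * n_var // J)

    bins_by_rep: dict[str, list[BinSpec]] = {}
    counts: list[VariantBinCounts] = []
    rep_mu_rows = []
    from scipy.special import ndtr

    for r in range(1, config.n_replicates + 1):
        rep = f"rep{r}"
        mu_rep = variant_mu + rng.normal(0.0, config.replicate_cv, size=n_var)
        for (sg, pr), m in zip(variants, mu_rep):
            rep_mu_rows.append((sg, pr, rep, m))
        # analytic gate probabilities per variant, with uniform misallocation
        z = (edges_ln[None, :] - mu_rep[:, None]) / variant_sigma[:, None]
        q = np.diff(ndtr(z), axis=1)
        probs = (1.0 - config.misallocation) * q + config.misallocation / J
        probs /= probs.sum(axis=1, keepdims=True)
        cells = np.vstack(
            [rng.multinomial(config.cells_per_variant, probs[i]) for i in range(n_var)]
        )
        C = cells.sum(axis=0)  # cells landing in each gate
        reads = np.zeros_like(cells)
        R = np.zeros(J, dtype=int)
        for j in range(J):
            if C[j] == 0:
                continue
            reads[:, j] = rng.multinomial(reads_per_bin, cells[:, j] / C[j])
            R[j] = reads_per_bin
        bins_by_rep[rep] = make_bins(
            interior, cells_sorted=C.astype(float), reads_total=R.astype(float)
        )
        for i, (sg, pr) in enumerate(variants):
            counts.append(VariantBinCounts(sg, pr, rep, reads[i].astype(float)))

    replicate_mu = pd.DataFrame(
        rep_mu_rows, columns=["sgrna_id", "promoter_id", "replicate_id", "mu_realized"]
    )
    return bins_by_rep, counts, library, GroundTruth(truth, replicate_mu)


def recovery_report(
    truth: GroundTruth, fits: pd.DataFrame, calls: pd.DataFrame | None = None
) -> dict:
    """Score estimation and calling accuracy against the ground truth.

    Parameter accuracy (bias and RMSE of mu against the per-replicate
    realized mean, RMSE of sigma) is computed over usable fits only. When
    calls are given, the up/down call rate is stratified by the true fold so
    sensitivity (fold != 1) and false-positive rate (fold == 1) fall out of
    the same table.
    """
    merged = fits.loc[fits["usable"].astype(bool)].merge(
        truth.replicate_mu, on=["sgrna_id", "promoter_id", "replicate_id"]
    )
    merged = merged.merge(
        truth.table[["sgrna_id", "promoter_id", "sigma_true"]],
        on=["sgrna_id", "promoter_id"],
    )
    err = merged["mu"] - merged["mu_realized"]
    report: dict = {
        "n_usable_fits": int(len(merged)),
        "mu_bias": float(err.mean()) if len(merged) else float("nan"),
        "mu_rmse": float(np.sqrt((err**2).mean())) if len(merged) else float("nan"),
        "sigma_rmse": float(np.sqrt(((merged["sigma"] - merged["sigma_true"]) ** 2).mean()))
        if len(merged)
        else float("nan"),
    }
    if calls is not None:
        joined = calls.merge(
            truth.table[["sgrna_id", "promoter_id", "fold_true", "regulated"]],
            on=["sgrna_id", "promoter_id"],
        )
        joined["called"] = joined["call"].isin(["up", "down"])
        strata = (
            joined.groupby(joined["fold_true"].round(6))
            .agg(n=("called", "size"), call_rate=("called", "mean"))
            .reset_index()
            .rename(columns={"fold_true": "fold_true"})
        )
        report["by_fold"] = strata
        null = joined.loc[~joined["regulated"]]
        alt = joined.loc[joined["regulated"]]
        report["false_positive_rate"] = (
            float(null["called"].mean()) if len(null) else float("nan")
        )
        report["sensitivity"] = float(alt["called"].mean()) if len(alt) else float("nan")
    return report
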