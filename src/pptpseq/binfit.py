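"""Censored log-normal maximum likelihood on binned sort-seq occupancies.

Each variant's fluorescence is modeled as log-normal: on the natural-log
scale, cell fluorescence is Normal(mu, sigma^2). Sorting into J contiguous
gates censors the observation to bin membership, so the log-likelihood given
noise-adjusted occupancies ``p_j`` is

    log L(mu, sigma | p) = sum_j p_j * log( F(B_j) - F(B_{j-1}) )

with F the Normal(mu, sigma) CDF evaluated at the natural-log bin edges,
F(B_0) = 0 and F(B_J) = 1 for the open outer gates. The reported promoter
activity is the log-normal mean exp(mu + sigma^2/2). Fit quality is scored
by the KL divergence between the occupancy and the fitted bin probabilities,

    K = sum_j p_j log p_j  -  log L(mu_hat, sigma_hat | p),

and four QC filters mark unusable fits: activity outside the sorter's
detection window, fewer than ``min_cells`` estimated cells, K above
``max_kl``, or all mass in a single gate (two parameters cannot be
identified from one occupied bin).

When some bins are excluded from analysis, the likelihood is the conditional
multinomial over the included bins: each model bin probability is divided by
the summed model probability of the included bins, keeping the objective a
proper likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .calibration import BinOccupancy
from .data_io import BinSpec, boundaries_ln

__all__ = [
    "FitConfig",
    "LogNormalFit",
    "fit_lognormal",
    "mean_activity",
    "kl_divergence",
    "apply_qc",
    "bin_log_probabilities",
]

QC_FLAGS = ("out_of_range", "low_cells", "poor_fit", "single_bin", "degenerate_occupancy")


@dataclass(frozen=True)
class FitConfig:
    """Fit and QC settings.

    The detection window is condition-specific: log10 1.5..5.0 for the
    glucose sorter configuration and 1.5..5.5 for rich-medium / glycerol
    runs. ``optimizer_tolerance`` is the Nelder-Mead simplex tolerance on
    the parameters; ``sigma_min`` keeps the spread away from the degenerate
    zero-variance optimum on near-point-mass occupancies.
    """

    detection_floor_log10: float = 1.5
    detection_ceiling_log10: float = 5.0
    sigma_min: float = 1e-3
    optimizer_tolerance: float = 1e-5
    max_kl: float = 1.0
    min_cells: float = 1.0

    def __post_init__(self) -> None:
        if self.detection_floor_log10 >= self.detection_ceiling_log10:
            raise ValueError("detection_floor must lie below detection_ceiling")
        if self.sigma_min <= 0:
            raise ValueError("sigma_min must be positive")


@dataclass
class LogNormalFit:
    """Fitted log-normal parameters and QC state for one variant.

    ``mu``/``sigma`` are on the natural-log fluorescence scale;
    ``mean_activity`` = exp(mu + sigma^2/2) is in the sorter's arbitrary
    fluorescence units. All numeric fields are NaN when the fit is flagged
    single-bin or degenerate.
    """

    mu: float
    sigma: float
    log_likelihood: float
    kl: float
    mean_activity: float
    total_cells: float
    qc_flags: set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return not self.qc_flags


def mean_activity(mu: float, sigma: float) -> float:
    """Log-normal mean exp(mu + sigma^2/2), the variant's promoter activity."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    with np.errstate(over="ignore"):
        return float(np.exp(mu + sigma * sigma / 2.0))  # inf on overflow


def bin_log_probabilities(
    mu: float, sigma: float, edges_ln: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Log model probability per bin, conditioned on the included bins.

    ``edges_ln`` are the J+1 natural-log bin edges (outer entries +-inf).
    With a mask, probabilities are renormalized over the included bins so the
    censored likelihood stays proper when bins are dropped.
    """
    z = (edges_ln - mu) / sigma
    cdf = ndtr(z)
    probs = np.diff(cdf)
    if mask is not None:
        probs = probs[mask]
        total = probs.sum()
        if total <= 0:
            return np.full(probs.shape, -np.inf)
        probs = probs / total
    with np.errstate(divide="ignore"):
        return np.log(probs)


def _loglik(mu: float, sigma: float, p: np.ndarray, edges_ln: np.ndarray, mask: np.ndarray) -> float:
    logq = bin_log_probabilities(mu, sigma, edges_ln, mask)
    nz = p > 0
    if np.any(np.isneginf(logq[nz])):
        return -np.inf
    return float(np.dot(p[nz], logq[nz]))


def _moment_start(p: np.ndarray, edges_ln: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Method-of-moments initialization on bin midpoints.

    Open outer bins get a pseudo-midpoint one interior-bin-width beyond the
    adjacent finite boundary.
    """
    lo, hi = edges_ln.copy(), edges_ln.copy()
    finite = edges_ln[np.isfinite(edges_ln)]
    width = np.median(np.diff(finite)) if len(finite) >= 2 else 1.0
    if np.isneginf(lo[0]):
        lo[0] = finite[0] - 2.0 * width
    if np.isposinf(hi[-1]):
        hi[-1] = finite[-1] + 2.0 * width
    mids = (lo[:-1] + hi[1:]) / 2.0
    mids = mids[mask]
    mu0 = float(np.dot(p, mids))
    var0 = float(np.dot(p, (mids - mu0) ** 2))
    sigma0 = math.sqrt(max(var0, 1e-6))
    return mu0, sigma0


def fit_lognormal(
    occupancy: BinOccupancy,
    bins: Sequence[BinSpec],
    config: FitConfig | None = None,
) -> LogNormalFit:
    """Maximize the censored log-normal likelihood for one variant.

    Nelder-Mead on (mu, log sigma) from a method-of-moments start, with one
    restart from a perturbed point on non-convergence; persistent failure is
    flagged ``poor_fit`` rather than raised. Single-bin occupancies are
    flagged and carry no numeric parameters.
    """
    config = config or FitConfig()
    total = occupancy.total_cells
    if occupancy.degenerate:
        return LogNormalFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, total,
            {"degenerate_occupancy"},
        )
    mask = occupancy.included
    p = occupancy.probability[mask]
    if np.count_nonzero(p > 0) < 2:
        return LogNormalFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, total, {"single_bin"}
        )

    edges_ln = boundaries_ln(bins)
    mu0, sigma0 = _moment_start(p, edges_ln, mask)
    sigma0 = max(sigma0, config.sigma_min)

    def neg_loglik(x: np.ndarray) -> float:
        mu, sigma = x[0], math.exp(x[1])
        ll = _loglik(mu, sigma, p, edges_ln, mask)
        return -ll if math.isfinite(ll) else 1e12

    tol = config.optimizer_tolerance
    starts = [(mu0, math.log(sigma0)), (mu0 + 0.5, math.log(sigma0 * 2.0))]
    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            neg_loglik,
            np.asarray(x0),
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol * tol, "maxiter": 4000, "maxfev": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            converged = True
            best = res if res.fun <= best.fun else best
            break

    mu_hat = float(best.x[0])
    sigma_hat = max(float(math.exp(best.x[1])), config.sigma_min)
    ll_hat = _loglik(mu_hat, sigma_hat, p, edges_ln, mask)
    # never report a point worse than the moment start
    ll_start = _loglik(mu0, sigma0, p, edges_ln, mask)
    if ll_start > ll_hat:
        mu_hat, sigma_hat, ll_hat = mu0, sigma0, ll_start

    plogp = float(np.sum(p[p > 0] * np.log(p[p > 0])))
    kl = plogp - ll_hat
    fit = LogNormalFit(
        mu=mu_hat,
        sigma=sigma_hat,
        log_likelihood=ll_hat,
        kl=kl,
        mean_activity=mean_activity(mu_hat, sigma_hat),
        total_cells=total,
    )
    if not converged:
        fit.qc_flags.add("poor_fit")
    return fit


def kl_divergence(
    occupancy: BinOccupancy, fit: LogNormalFit, bins: Sequence[BinSpec]
) -> float:
    """KL divergence between the occupancy and the fitted bin probabilities.

    Computed as sum p log p minus the log-likelihood at the fitted optimum,
    with the 0*log(0) := 0 convention.
    """
    if not (math.isfinite(fit.mu) and math.isfinite(fit.sigma)):
        raise ValueError("fit has no numeric parameters")
    mask = occupancy.included
    p = occupancy.probability[mask]
    edges_ln = boundaries_ln(bins)
    ll = _loglik(fit.mu, fit.sigma, p, edges_ln, mask)
    plogp = float(np.sum(p[p > 0] * np.log(p[p > 0])))
    return plogp - ll


def apply_qc(fit: LogNormalFit, config: FitConfig | None = None) -> LogNormalFit:
    """Flag fits that fail any of the four quality filters.

    Flags accumulate in ``fit.qc_flags``; a fit is usable iff the set stays
    empty. Flagged fits keep their numeric values so diagnostics can look at
    them, but downstream aggregation ignores non-usable fits.
    """
    config = config or FitConfig()
    if "single_bin" in fit.qc_flags or "degenerate_occupancy" in fit.qc_flags:
        return fit
    lo = 10.0 ** config.detection_floor_log10
    hi = 10.0 ** config.detection_ceiling_log10
    if not (lo <= fit.mean_activity <= hi):
        fit.qc_flags.add("out_of_range")
    if fit.total_cells < config.min_cells:
        fit.qc_flags.add("low_cells")
    if fit.kl > config.max_kl:
        fit.qc_flags.add("poor_fit")
    return fit
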