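"""Cell-count normalization and sorting-noise adjustment.

Reads sequenced from each bin are converted back to sorted-cell estimates
(``c_ij = r_ij * C_j / R_j``), then to cell fractions ``f_ij``. A uniform
noise background ``eps`` per bin — cells deposited in the wrong gate by the
sorter — is subtracted and the result renormalized:

    f_adj_ij = (f_ij - eps) / sum_j (f_ij - eps)
    p_ij     = max(0, f_adj_ij) / sum_j max(0, f_adj_ij)

``p_ij`` estimates the probability that a cell of variant i truly originated
from bin j before sorting noise; it is the input to the censored log-normal
fit. All sums run over *included* bins only, so a bin dropped from analysis
(e.g. a contaminated low-fluorescence gate) simply leaves the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import BinSpec, VariantBinCounts, included_mask

__all__ = ["CalibrationError", "CalibrationConfig", "BinOccupancy", "estimate_cells", "occupancy"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationConfig:
    """Noise-adjustment settings.

    ``noise_background`` (eps) is the uniform per-bin fraction attributed to
    sorter misallocation, default 0.05. It must stay below 1/J over the
    included bins or every adjusted fraction could turn nonpositive.
    """

    noise_background: float = 0.05
    included_bins: frozenset[int] | None = None

    def validate(self, n_included: int) -> None:
        if not 0.0 <= self.noise_background < 1.0 / n_included:
            raise CalibrationError(
                f"noise_background must be in [0, 1/{n_included}) for "
                f"{n_included} included bins, got {self.noise_background}"
            )


@dataclass
class BinOccupancy:
    """Derived per-bin vectors for one variant.

    Excluded bins hold NaN in every vector; sums and normalizations run over
    included bins. ``degenerate`` marks variants whose every adjusted
    fraction is nonpositive (the fit later reports them as NA).
    """

    cells: np.ndarray
    fraction: np.ndarray
    adjusted_fraction: np.ndarray
    probability: np.ndarray
    total_cells: float
    included: np.ndarray = field(repr=False)
    degenerate: bool = False


def _included(bins: Sequence[BinSpec], config: CalibrationConfig | None) -> np.ndarray:
    mask = included_mask(bins)
    if config is not None and config.included_bins is not None:
        cfg = np.array([b.bin_index in config.included_bins for b in bins])
        mask = mask & cfg
    return mask


def estimate_cells(
    counts: VariantBinCounts, bins: Sequence[BinSpec], config: CalibrationConfig | None = None
) -> np.ndarray:
    """Estimate sorted cells per bin: ``c_ij = r_ij * C_j / R_j``.

    The ratio C_j/R_j undoes the unequal sequencing effort per bin after
    post-sort growth and library prep. Excluded bins return NaN.
    """
    mask = _included(bins, config)
    reads = np.asarray(counts.reads, dtype=float)
    if len(reads) != len(bins):
        raise CalibrationError(
            f"variant ({counts.sgrna_id}, {counts.promoter_id}) has "
            f"{len(reads)} bins, design has {len(bins)}"
        )
    cells = np.full(len(bins), np.nan)
    for j, b in enumerate(bins):
        if not mask[j]:
            continue
        if reads[j] > 0 and b.reads_total == 0:
            raise CalibrationError(
                f"bin {b.bin_index} has reads but R_j = 0; cannot calibrate"
            )
        cells[j] = 0.0 if b.reads_total == 0 else reads[j] * b.cells_sorted / b.reads_total
    return cells


def occupancy(cells: np.ndarray, config: CalibrationConfig | None = None) -> BinOccupancy:
    """Noise-adjusted pre-sort bin probabilities from estimated cell counts.

    Implements the eps-subtraction and clamped renormalization described in
    the module docstring. Raises :class:`CalibrationError` when no included
    bin has cells; flags (not raises) the degenerate all-nonpositive case.
    """
    cells = np.asarray(cells, dtype=float)
    config = config or CalibrationConfig()
    mask = ~np.isnan(cells)
    n_inc = int(mask.sum())
    if n_inc == 0:
        raise CalibrationError("no included bins")
    config.validate(n_inc)
    eps = config.noise_background

    c = cells[mask]
    total = float(c.sum())
    if total <= 0:
        raise CalibrationError("all included bins have zero cells")

    f = c / total
    shifted = f - eps
    denom = shifted.sum()  # = 1 - J_inc * eps > 0 by the config guard
    f_adj = shifted / denom
    clipped = np.clip(f_adj, 0.0, None)
    clip_sum = clipped.sum()

    fraction = np.full_like(cells, np.nan)
    adjusted = np.full_like(cells, np.nan)
    prob = np.full_like(cells, np.nan)
    fraction[mask] = f
    adjusted[mask] = f_adj
    degenerate = clip_sum <= 0
    if not degenerate:
        prob[mask] = clipped / clip_sum
    return BinOccupancy(
        cells=cells,
        fraction=fraction,
        adjusted_fraction=adjusted,
        probability=prob,
        total_cells=total,
        included=mask,
        degenerate=degenerate,
    )
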