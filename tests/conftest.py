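import math

import numpy as np
import pytest
from scipy.special import ndtr

from pptpseq.calibration import BinOccupancy
from pptpseq.data_io import BinSpec, boundaries_ln, make_bins

LN10 = math.log(10.0)


@pytest.fixture
def glucose_bins() -> list[BinSpec]:
    """A 16-gate sorting design equally spaced over log10 1.5..5.0."""
    interior = np.linspace(1.5, 5.0, 17)[1:-1]
    return make_bins(
        interior,
        cells_sorted=[50_000.0] * 16,
        reads_total=[1_000_000.0] * 16,
    )


def analytic_occupancy(mu: float, sigma: float, bins: list[BinSpec]) -> BinOccupancy:
    """Exact model bin probabilities of Normal(mu, sigma) on the log grid.

    Serves as a noiseless occupancy whose maximum-likelihood fit must return
    (mu, sigma) itself.
    """
    edges = boundaries_ln(bins)
    probs = np.diff(ndtr((edges - mu) / sigma))
    probs = probs / probs.sum()
    mask = np.ones(len(bins), dtype=bool)
    return BinOccupancy(
        cells=probs.copy(),
        fraction=probs.copy(),
        adjusted_fraction=probs.copy(),
        probability=probs,
        total_cells=1000.0,
        included=mask,
    )


@pytest.fixture
def occupancy_factory():
    return analytic_occupancy
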