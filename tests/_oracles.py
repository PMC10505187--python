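"""Brute-force grid-search oracle for the censored log-normal likelihood.

Independent of the package's optimizer path: likelihood terms are assembled
directly from the normal CDF on a dense (mu, sigma) grid.
"""

import numpy as np
from scipy.special import ndtr, ndtri


def random_identifiable_three_bin_case(rng, sigma_range=(0.05, 2.5), mu_pad=1.8):
    """Random J=3 occupancy whose unique exact-fit optimum is grid-reachable.

    For an all-occupied 3-bin vector the censored-likelihood maximum is the
    exact quantile match: sigma* = (b-a)/(z2-z1), mu* = a - sigma* z1 with
    z1 = ndtri(p1), z2 = ndtri(p1+p2) on the natural-log edges (a, b). Cases
    whose optimum falls outside the oracle's search grid (sigma beyond
    ``sigma_range`` or mu beyond the mu pad) are rejected and redrawn.
    """
    while True:
        a10 = rng.uniform(1.8, 2.6)
        b10 = a10 + rng.uniform(0.2, 0.7)
        p = rng.dirichlet([2.0, 2.0, 2.0])
        a, b = a10 * np.log(10.0), b10 * np.log(10.0)
        z1, z2 = ndtri(p[0]), ndtri(p[0] + p[1])
        sigma_star = (b - a) / (z2 - z1)
        mu_star = a - sigma_star * z1
        if sigma_range[0] <= sigma_star <= sigma_range[1] and (
            a - mu_pad <= mu_star <= b + mu_pad
        ):
            return (a10, b10), p, (mu_star, sigma_star)


def grid_oracle_fit(
    p,
    edges_ln,
    mu_pad=2.0,
    mu_step=1e-3,
    sigma_range=(1e-3, 3.0),
    sigma_step=1e-3,
    sigma_chunk=250,
):
    """Exhaustive (mu, sigma) grid argmax of sum_j p_j log(F(B_j) - F(B_{j-1})).

    The mu grid spans [lowest finite occupied edge - mu_pad, highest finite
    occupied edge + mu_pad]. Returns (mu, sigma, loglik) at the grid optimum.
    """
    p = np.asarray(p, dtype=float)
    edges_ln = np.asarray(edges_ln, dtype=float)
    finite = edges_ln[np.isfinite(edges_ln)]
    mus = np.arange(finite.min() - mu_pad, finite.max() + mu_pad, mu_step)
    sigmas = np.arange(sigma_range[0], sigma_range[1], sigma_step)

    nz = np.flatnonzero(p > 0)
    best_ll, best_mu, best_sigma = -np.inf, np.nan, np.nan
    for start in range(0, len(sigmas), sigma_chunk):
        sig = sigmas[start : start + sigma_chunk][:, None]  # (S, 1)
        ll = np.zeros((sig.shape[0], len(mus)))
        cdf_cache = {}

        def cdf(j):
            if j not in cdf_cache:
                if np.isneginf(edges_ln[j]):
                    cdf_cache[j] = 0.0
                elif np.isposinf(edges_ln[j]):
                    cdf_cache[j] = 1.0
                else:
                    cdf_cache[j] = ndtr((edges_ln[j] - mus[None, :]) / sig)
            return cdf_cache[j]

        with np.errstate(divide="ignore", invalid="ignore"):
            for j in nz:
                q = cdf(j + 1) - cdf(j)
                ll = ll + p[j] * np.log(q)
        ll[~np.isfinite(ll)] = -np.inf
        k = int(np.argmax(ll))
        if ll.flat[k] > best_ll:
            si, mi = np.unravel_index(k, ll.shape)
            best_ll = float(ll.flat[k])
            best_mu = float(mus[mi])
            best_sigma = float(sigmas[start + si])
    return best_mu, best_sigma, best_ll
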