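"""Independent reference implementations used only to check the package.

These deliberately avoid the package's estimation code paths: probabilities
are computed with ``scipy.stats.norm``, the meta-d' likelihood is maximized
by a profiled grid search over meta-d' (criteria re-optimized at each fixed
grid value) rather than the package's joint multi-start optimization, and
quantile bins are derived by explicit sort-and-split enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm


def type2_loglik(table, meta_d, c_prime, crit_down, crit_up):
    """Log-likelihood of a padded type-2 count table at explicit criteria.

    ``crit_down`` are the S1-response criteria descending below the meta
    criterion, ``crit_up`` the S2-response criteria ascending above it.
    """
    meta_c = c_prime * meta_d
    hi = np.concatenate(([meta_c], crit_up, [np.inf]))
    lo = np.concatenate(([meta_c], crit_down, [-np.inf]))
    ll = 0.0
    cells = (
        (table.s1_correct, -meta_d / 2.0, "s1resp"),
        (table.s1_incorrect, meta_d / 2.0, "s1resp"),
        (table.s2_correct, meta_d / 2.0, "s2resp"),
        (table.s2_incorrect, -meta_d / 2.0, "s2resp"),
    )
    for counts, mu, side in cells:
        if side == "s2resp":
            cdf = norm.cdf(hi, loc=mu)
            p = np.diff(cdf) / max(1.0 - cdf[0], 1e-300)
        else:
            cdf = norm.cdf(lo, loc=mu)
            p = -np.diff(cdf) / max(cdf[0], 1e-300)
        ll += float(np.dot(counts, np.log(np.maximum(p, 1e-300))))
    return ll


def profiled_loglik(table, type1, meta_d, x0=None):
    """Maximize the type-2 likelihood over criteria at fixed meta-d'.

    Returns ``(loglik, x)`` where ``x`` are the optimized log-increments
    (reusable as a warm start for the neighbouring grid point).
    """
    k = table.nbins - 1
    c_prime = type1.criterion_c / type1.d_prime

    def nll(x):
        meta_c = c_prime * meta_d
        down = meta_c - np.cumsum(np.exp(x[:k]))
        up = meta_c + np.cumsum(np.exp(x[k:]))
        return -type2_loglik(table, meta_d, c_prime, down, up)

    if x0 is None:
        x0 = np.full(2 * k, np.log(0.5))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=[(-9.0, 3.0)] * (2 * k),
                   options={"ftol": 1e-12, "maxiter": 400})
    return -res.fun, res.x


def grid_search_meta_d(table, type1, lo=0.005, hi=5.0, coarse=0.05, fine=0.005):
    """Profiled grid-search maximum-likelihood meta-d'.

    Scans a coarse grid over ``[lo, hi]`` with warm-started criterion
    profiling, then refines with ``fine`` steps around the coarse maximum.
    """
    padded = table.padded()
    grid = np.arange(lo, hi + coarse / 2, coarse)
    best_md, best_ll, x = None, -np.inf, None
    lls = []
    for md in grid:
        ll, x = profiled_loglik(padded, type1, md, x0=x)
        lls.append(ll)
        if ll > best_ll:
            best_md, best_ll = md, ll
    fine_grid = np.arange(max(lo, best_md - coarse), min(hi, best_md + coarse) + fine / 2, fine)
    x = None
    for md in fine_grid:
        ll, x = profiled_loglik(padded, type1, md, x0=x)
        if ll > best_ll:
            best_md, best_ll = md, ll
    return float(best_md), float(best_ll)


def rank_split_bins(values, nbins):
    """Quantile bins by explicit sort-and-split enumeration.

    Sort the values, cut the sorted order into ``nbins`` contiguous chunks of
    near-equal size, then assign each distinct value to the lowest chunk any
    of its occurrences falls into (ties never straddle a boundary upward).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    chunk_of_position = np.minimum(np.arange(n) * nbins // n, nbins - 1) + 1
    provisional = np.empty(n, dtype=int)
    provisional[order] = chunk_of_position
    bins = np.empty(n, dtype=int)
    for v in np.unique(values):
        mask = values == v
        bins[mask] = provisional[mask].min()
    return bins
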