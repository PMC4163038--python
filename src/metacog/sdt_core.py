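"""Equal-variance Gaussian signal detection estimation for confidence-rated 2AFC data.

This module provides the estimation chain for metacognitive efficiency:

1. :func:`compute_type1` — type-1 sensitivity ``d'`` and criterion ``c`` from
   2AFC stimulus/response counts (the "right" alternative is treated as the
   signal class).
2. :func:`bin_confidence` — within-subject quantile binning of continuous
   confidence ratings into a small number of ordinal bins.
3. :func:`build_type2_counts` — the response x accuracy x confidence-bin count
   table, the sufficient statistic for all type-2 (confidence) modelling.
4. :func:`fit_meta_d` — maximum-likelihood estimation of meta-d', the type-1
   sensitivity that an SDT-ideal metacognitive observer would need in order to
   produce the observed confidence data.  meta-d' is expressed in the same
   units as d', so the ratio meta-d'/d' ("M-ratio", here ``efficiency``)
   directly indexes metacognitive efficiency: 1 is ideal, values below 1
   indicate information loss between the decision and the confidence report.

The meta-d' model assumes equal-variance Gaussian evidence distributions at
the meta level, with the type-1 criterion of the meta-level observer held at
the same *relative* position as the empirical one (meta-c = (c/d') * meta-d').
Response-conditional type-2 criteria fan outward from that criterion and are
fitted jointly with meta-d' by maximizing the multinomial likelihood of the
confidence counts, conditional on stimulus and response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

__all__ = [
    "S1",
    "S2",
    "Type1Summary",
    "Type2CountTable",
    "MetaDFit",
    "FitError",
    "compute_type1",
    "bin_confidence",
    "build_type2_counts",
    "fit_meta_d",
    "efficiency_from_trials",
]

#: Stimulus/response labels for the two alternatives.  ``S2`` ("right") plays
#: the role of the signal class in the d' convention d' = z(hit) - z(fa).
S1 = "left"
S2 = "right"

_TINY = 1e-300


class FitError(RuntimeError):
    """Raised when the meta-d' optimizer fails on every start point.

    Carries the per-start scipy results in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Type1Summary:
    """Type-1 (primary task) signal-detection summary of a 2AFC session."""

    d_prime: float
    criterion_c: float
    n_trials: int
    hit_rate: float
    fa_rate: float


@dataclass(frozen=True)
class Type2CountTable:
    """Confidence counts cross-classified by response x accuracy x bin.

    Each vector has length ``nbins`` and is indexed by confidence bin
    (ascending, bin 1 first).  This table is the sufficient statistic for
    meta-d' estimation.
    """

    nbins: int
    s1_correct: np.ndarray
    s1_incorrect: np.ndarray
    s2_correct: np.ndarray
    s2_incorrect: np.ndarray

    def __post_init__(self):
        for name in ("s1_correct", "s1_incorrect", "s2_correct", "s2_incorrect"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (self.nbins,):
                raise ValueError(f"{name} must have length nbins={self.nbins}")
            if np.any(vec < 0):
                raise ValueError(f"{name} contains negative counts")
            object.__setattr__(self, name, vec)

    @property
    def n_total(self) -> float:
        return float(
            self.s1_correct.sum()
            + self.s1_incorrect.sum()
            + self.s2_correct.sum()
            + self.s2_incorrect.sum()
        )

    def padded(self, pad: float | None = None) -> "Type2CountTable":
        """Return a copy with ``pad`` added to every cell.

        The default pad of ``1 / (2 * nbins)`` is the usual regularization for
        zero cells in type-2 count tables; it keeps the multinomial likelihood
        finite without noticeably moving the optimum on real data.
        """
        if pad is None:
            pad = 1.0 / (2.0 * self.nbins)
        return Type2CountTable(
            nbins=self.nbins,
            s1_correct=self.s1_correct + pad,
            s1_incorrect=self.s1_incorrect + pad,
            s2_correct=self.s2_correct + pad,
            s2_incorrect=self.s2_incorrect + pad,
        )


@dataclass(frozen=True)
class MetaDFit:
    """Result of a meta-d' maximum-likelihood fit.

    ``type2_criteria_s1`` are ordered outward (downward) from the meta-level
    type-1 criterion, ``type2_criteria_s2`` outward (upward); both have length
    ``nbins - 1``.  ``meta_criterion`` is the meta-level type-1 criterion
    c * meta_d / d' implied by the relative-criterion constraint.
    ``log_efficiency`` is only defined for positive efficiency; otherwise the
    fit is flagged ``excluded`` from log-scale analyses.
    """

    meta_d: float
    type2_criteria_s1: np.ndarray
    type2_criteria_s2: np.ndarray
    meta_criterion: float
    log_likelihood: float
    d_prime: float
    criterion_c: float
    efficiency: float
    log_efficiency: float | None
    excluded: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def type2_criteria(self) -> np.ndarray:
        """2 x (nbins-1) array: row 0 the S1-response side, row 1 the S2 side."""
        return np.vstack([self.type2_criteria_s1, self.type2_criteria_s2])


def _corrected_rate(count: int, n: int) -> float:
    """Proportion with the 1/(2N) correction for extreme (0 or 1) rates."""
    if n <= 0:
        raise ValueError("cannot compute a rate from zero trials")
    rate = count / n
    if rate <= 0.0:
        return 1.0 / (2.0 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return rate


def compute_type1(trials: pd.DataFrame) -> Type1Summary:
    """Estimate d' and criterion c from a 2AFC trial table.

    The "right" stimulus is treated as the signal class: the hit rate is
    P(respond right | stimulus right) and the false-alarm rate is
    P(respond right | stimulus left), giving d' = z(hit) - z(fa) and
    c = -(z(hit) + z(fa)) / 2.  Extreme rates are corrected by 1/(2N) per
    stimulus class so the estimates are always finite.

    Raises
    ------
    ValueError
        If the table is empty or one stimulus class is absent.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list: cannot estimate type-1 performance")
    stim = trials["stimulus_side"].to_numpy()
    resp = trials["response_side"].to_numpy()
    is_s2 = stim == S2
    n_s2 = int(is_s2.sum())
    n_s1 = int((~is_s2).sum())
    if n_s2 == 0:
        raise ValueError(f"no trials with stimulus_side={S2!r}")
    if n_s1 == 0:
        raise ValueError(f"no trials with stimulus_side={S1!r}")
    hits = int((is_s2 & (resp == S2)).sum())
    fas = int((~is_s2 & (resp == S2)).sum())
    hr = _corrected_rate(hits, n_s2)
    far = _corrected_rate(fas, n_s1)
    zh = float(ndtri(hr))
    zf = float(ndtri(far))
    return Type1Summary(
        d_prime=zh - zf,
        criterion_c=-0.5 * (zh + zf),
        n_trials=len(trials),
        hit_rate=hr,
        fa_rate=far,
    )


def bin_confidence(confidence_raw, nbins: int = 4) -> np.ndarray:
    """Assign each confidence rating to a within-session quantile bin.

    Ratings are ranked and split at rank quantile boundaries into ``nbins``
    near-equal groups.  Tied ratings are kept together: a tie group whose
    ranks straddle a boundary is assigned wholesale to the lower of the bins
    it straddles (implemented by binning on minimum ranks), which makes the
    mapping deterministic, order-invariant and monotone in the rating.

    Returns an integer array of bins in ``1..nbins``.
    """
    conf = np.asarray(confidence_raw, dtype=float)
    if conf.ndim != 1:
        raise ValueError("confidence_raw must be one-dimensional")
    n = conf.size
    if nbins < 2:
        raise ValueError("nbins must be at least 2")
    if n < nbins:
        raise ValueError(f"need at least nbins={nbins} trials to form quantile bins, got {n}")
    if np.unique(conf).size == 1:
        warnings.warn(
            "constant confidence vector: all trials assigned to bin 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.ones(n, dtype=int)
    min_ranks = rankdata(conf, method="min")  # 1..n
    bins = ((min_ranks - 1) * nbins) // n + 1
    return bins.astype(int)


def build_type2_counts(trials: pd.DataFrame, nbins: int = 4) -> Type2CountTable:
    """Tally trials into the response x accuracy x confidence-bin table."""
    if "confidence_bin" not in trials.columns:
        raise ValueError("trials must carry a confidence_bin column (run bin_confidence first)")
    bins = trials["confidence_bin"].to_numpy()
    if np.any(pd.isna(bins)):
        raise ValueError("confidence_bin contains missing values")
    bins = bins.astype(int)
    if bins.min() < 1 or bins.max() > nbins:
        raise ValueError(f"confidence_bin outside 1..{nbins}")
    resp = trials["response_side"].to_numpy()
    acc = trials["accuracy"].to_numpy().astype(int)
    vectors = {}
    for key, mask in (
        ("s1_correct", (resp == S1) & (acc == 1)),
        ("s1_incorrect", (resp == S1) & (acc == 0)),
        ("s2_correct", (resp == S2) & (acc == 1)),
        ("s2_incorrect", (resp == S2) & (acc == 0)),
    ):
        counts = np.zeros(nbins, dtype=float)
        np.add.at(counts, bins[mask] - 1, 1.0)
        vectors[key] = counts
    return Type2CountTable(nbins=nbins, **vectors)


def _conditional_probs(meta_d, c_prime, log_inc_s1, log_inc_s2, nbins):
    """Response-conditional rating probabilities under the meta-level model.

    Returns four length-``nbins`` probability vectors (ascending confidence)
    keyed by the (stimulus, response) cell, plus the fitted criteria.
    """
    meta_c = c_prime * meta_d
    up = meta_c + np.cumsum(np.exp(log_inc_s2))
    down = meta_c - np.cumsum(np.exp(log_inc_s1))
    edges_hi = np.concatenate(([meta_c], up, [np.inf]))
    edges_lo = np.concatenate(([meta_c], down, [-np.inf]))
    probs = {}
    for stim, mu in ((S1, -meta_d / 2.0), (S2, meta_d / 2.0)):
        f_hi = ndtr(edges_hi - mu)
        p_resp2 = max(1.0 - f_hi[0], _TINY)
        probs[(stim, S2)] = np.diff(f_hi) / p_resp2
        f_lo = ndtr(edges_lo - mu)
        p_resp1 = max(f_lo[0], _TINY)
        probs[(stim, S1)] = -np.diff(f_lo) / p_resp1
    return probs, down, up


def _table_log_likelihood(table: Type2CountTable, probs) -> float:
    """Multinomial log-likelihood of a count table at given cell probabilities."""
    ll = 0.0
    # response S1 correct => stimulus S1; response S1 incorrect => stimulus S2, etc.
    for counts, cell in (
        (table.s1_correct, (S1, S1)),
        (table.s1_incorrect, (S2, S1)),
        (table.s2_correct, (S2, S2)),
        (table.s2_incorrect, (S1, S2)),
    ):
        ll += float(np.dot(counts, np.log(np.maximum(probs[cell], _TINY))))
    return ll


def fit_meta_d(
    table: Type2CountTable,
    type1: Type1Summary,
    *,
    meta_d_bounds: tuple[float, float] = (-5.0, 5.0),
    pad: float | None = None,
) -> MetaDFit:
    """Fit meta-d' by maximum likelihood to a type-2 count table.

    The likelihood is the multinomial probability of the confidence-bin counts
    conditional on stimulus and response, under equal-variance Gaussian
    evidence distributions separated by ``meta_d`` and a type-1 criterion held
    at the relative position ``(c / d') * meta_d``.  Type-2 criteria are
    parameterized as ordered log-increments away from that criterion, which
    enforces the mirror ordering by construction; the joint optimization is
    restarted from three fixed initial points to avoid local optima.

    Counts are padded by ``1 / (2 * nbins)`` per cell before fitting (see
    :meth:`Type2CountTable.padded`); the reported ``log_likelihood`` is
    evaluated on the *unpadded* counts at the fitted parameters.

    Degenerate inputs (non-positive d', or confidence concentrated in a single
    bin for every response) yield a flagged fit with undefined efficiency
    rather than an exception; a fit ending on the ``meta_d`` search bound is
    flagged ``"at_bound"``.
    """
    nbins = table.nbins
    k = nbins - 1
    flags: list[str] = []

    d = type1.d_prime
    c = type1.criterion_c
    if d <= 0:
        return MetaDFit(
            meta_d=np.nan,
            type2_criteria_s1=np.full(k, np.nan),
            type2_criteria_s2=np.full(k, np.nan),
            meta_criterion=np.nan,
            log_likelihood=np.nan,
            d_prime=d,
            criterion_c=c,
            efficiency=np.nan,
            log_efficiency=None,
            excluded=True,
            flags=("nonpositive_d_prime",),
        )

    degenerate = _single_bin(table.s1_correct + table.s1_incorrect) and _single_bin(
        table.s2_correct + table.s2_incorrect
    )
    if degenerate:
        flags.append("degenerate_counts")

    work = table.padded(pad)
    c_prime = c / d

    def neg_ll(theta):
        probs, _, _ = _conditional_probs(theta[0], c_prime, theta[1 : 1 + k], theta[1 + k :], nbins)
        return -_table_log_likelihood(work, probs)

    lo, hi = meta_d_bounds
    bounds = [(lo, hi)] + [(-9.0, 3.0)] * (2 * k)
    starts = [np.clip(m, lo + 1e-3, hi - 1e-3) for m in (0.3 * d, d, 2.0 * d)]
    results = []
    best = None
    for md0 in starts:
        theta0 = np.concatenate(([md0], np.full(2 * k, np.log(0.5))))
        res = minimize(
            neg_ll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
        )
        results.append(res)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError("meta-d' optimization failed from every start point", diagnostics=results)

    meta_d = float(best.x[0])
    if min(meta_d - lo, hi - meta_d) < 1e-4:
        flags.append("at_bound")

    probs, crit_s1, crit_s2 = _conditional_probs(
        meta_d, c_prime, best.x[1 : 1 + k], best.x[1 + k :], nbins
    )
    log_lik = _table_log_likelihood(table, probs)

    if degenerate:
        efficiency = np.nan
        log_eff = None
    else:
        efficiency = meta_d / d
        log_eff = float(np.log(efficiency)) if efficiency > 0 else None
    excluded = log_eff is None

    return MetaDFit(
        meta_d=meta_d,
        type2_criteria_s1=crit_s1,
        type2_criteria_s2=crit_s2,
        meta_criterion=c_prime * meta_d,
        log_likelihood=log_lik,
        d_prime=d,
        criterion_c=c,
        efficiency=efficiency,
        log_efficiency=log_eff,
        excluded=excluded,
        flags=tuple(flags),
    )


def _single_bin(counts: np.ndarray) -> bool:
    return int(np.count_nonzero(counts)) <= 1


def efficiency_from_trials(trials: pd.DataFrame, nbins: int = 4) -> MetaDFit:
    """Per-session entry point: type-1 fit, quantile binning, meta-d' fit.

    Equivalent to running :func:`compute_type1`, :func:`bin_confidence`,
    :func:`build_type2_counts` and :func:`fit_meta_d` in sequence on the same
    trials.
    """
    type1 = compute_type1(trials)
    trials = trials.copy()
    trials["confidence_bin"] = bin_confidence(trials["confidence_raw"].to_numpy(), nbins)
    table = build_type2_counts(trials, nbins)
    return fit_meta_d(table, type1)
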