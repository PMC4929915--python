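"""Fragment-length distributions, lognormal summaries and the decay tail fit.

Post-mortem fragmentation by i.i.d. per-bond breakage makes the frequency
of fragments of length L decline exponentially, F(L) = F0 * exp(-lambda*L),
so log F(L) is linear in L with slope -lambda; lambda is the per-bond
damage (breakage) fraction of the sample. The short end of an empirical
library-length distribution is shaped by length-dependent recovery, so
lambda is fitted by ordinary least squares on log counts over a tail
window starting past the distribution's mode.

The whole-distribution summary is a lognormal fit: the count-weighted
maximum-likelihood mean and SD of ln(length), with median = exp(log_mean).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .alignments_io import ReadAlignment


@dataclass
class FragmentLengthDist:
    """Integer length -> read count histogram for one sample/compartment."""

    counts: dict[int, int]
    n_reads: int
    sample_id: str = ""
    compartment: str = "all"

    def lengths_array(self) -> tuple[np.ndarray, np.ndarray]:
        L = np.array(sorted(self.counts), dtype=np.int64)
        c = np.array([self.counts[x] for x in L], dtype=np.int64)
        return L, c

    @property
    def mode(self) -> int:
        L, c = self.lengths_array()
        return int(L[np.argmax(c)])


@dataclass
class LognormalFit:
    log_mean: float
    log_sd: float
    median: float
    n: int


@dataclass
class DecayFit:
    """Exponential-tail fit: log counts regressed on length over a window."""

    lambda_hat: float
    log_F0: float
    window: tuple[int, int]
    r_squared: float
    n_bins: int
    n_dropped_zero_bins: int = 0
    ok: bool = True  # False when the tail does not decay (slope >= 0)


def length_distribution(
    reads: Iterable[ReadAlignment], sample_id: str = "", compartment: str = "all"
) -> FragmentLengthDist:
    """Histogram of fragment lengths (end - start) over the given reads."""
    counts: dict[int, int] = {}
    n = 0
    for r in reads:
        counts[r.length] = counts.get(r.length, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("no reads: cannot build a length distribution")
    return FragmentLengthDist(counts=counts, n_reads=n,
                              sample_id=sample_id, compartment=compartment)


def distribution_from_lengths(
    lengths: Iterable[int], sample_id: str = "", compartment: str = "all"
) -> FragmentLengthDist:
    """Convenience constructor from raw integer lengths."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("no lengths given")
    vals, cnts = np.unique(arr, return_counts=True)
    return FragmentLengthDist(
        counts={int(v): int(c) for v, c in zip(vals, cnts)},
        n_reads=int(arr.size),
        sample_id=sample_id,
        compartment=compartment,
    )


def fit_lognormal(dist: FragmentLengthDist, min_n: int = 30) -> LognormalFit:
    """Closed-form lognormal MLE of the length distribution.

    log_mean and log_sd are the count-weighted mean and (uncorrected) SD of
    ln(length); the distribution median is exp(log_mean) exactly.
    """
    if dist.n_reads < min_n:
        raise ValueError(f"need >= {min_n} reads to fit a lognormal, got {dist.n_reads}")
    L, c = dist.lengths_array()
    if L[0] < 1:
        raise ValueError("lengths must be >= 1 for a lognormal fit")
    logs = np.log(L.astype(float))
    w = c / c.sum()
    mu = float(np.sum(w * logs))
    sd = float(math.sqrt(np.sum(w * (logs - mu) ** 2)))
    return LognormalFit(log_mean=mu, log_sd=sd, median=math.exp(mu), n=dist.n_reads)


def select_tail_window(
    dist: FragmentLengthDist, min_count: int = 10, mode_offset: int = 5
) -> tuple[int, int]:
    """Choose the exponential-tail fit window [L_lo, L_hi].

    L_lo is the global mode plus ``mode_offset`` (skipping the
    recovery-shaped body); L_hi is the largest length whose count still
    reaches ``min_count``. A multi-modal histogram uses the global mode and
    warns. Errors if fewer than 10 bins with data fall inside the window.
    """
    L, c = dist.lengths_array()
    cmax = c.max()
    modes = L[c == cmax]
    if modes.size > 1:
        warnings.warn(
            f"length histogram has {modes.size} tied modes; using the smallest",
            stacklevel=2,
        )
    lo = int(modes[0]) + mode_offset
    eligible = L[c >= min_count]
    if eligible.size == 0:
        raise ValueError("no length bin reaches min_count; set the window manually")
    hi = int(eligible.max())
    n_in = int(np.sum((L >= lo) & (L <= hi) & (c > 0)))
    if hi <= lo or n_in < 10:
        raise ValueError(
            f"tail window [{lo}, {hi}] holds only {n_in} populated bins; "
            "set the window manually"
        )
    return lo, hi


def fit_decay(
    dist: FragmentLengthDist,
    window: tuple[int, int] | None = None,
    weighting: str = "none",
    min_count: int = 10,
    mode_offset: int = 5,
) -> DecayFit:
    """OLS fit of ln(count) on length over the tail window; lambda = -slope.

    Zero-count bins inside the window are dropped (their log is undefined)
    and reported. ``weighting='count'`` uses per-bin counts as weights;
    the default is the plain unweighted linear fit.
    """
    if window is None:
        window = select_tail_window(dist, min_count=min_count, mode_offset=mode_offset)
    lo, hi = window
    if lo >= hi:
        raise ValueError("invalid window")
    L, c = dist.lengths_array()
    sel = (L >= lo) & (L <= hi)
    L, c = L[sel], c[sel]
    n_zero = int(np.sum(c == 0))
    L, c = L[c > 0], c[c > 0]
    if L.size < 10:
        raise ValueError(f"only {L.size} usable bins in window [{lo}, {hi}]")
    x = L.astype(float)
    y = np.log(c.astype(float))
    if weighting == "count":
        w = c.astype(float)
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    wsum = w.sum()
    xbar = np.sum(w * x) / wsum
    ybar = np.sum(w * y) / wsum
    sxx = np.sum(w * (x - xbar) ** 2)
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    ok = slope < 0
    if not ok:
        warnings.warn(
            "tail slope is non-negative: the length distribution does not "
            "decay over the selected window",
            stacklevel=2,
        )
    return DecayFit(
        lambda_hat=float(-slope),
        log_F0=float(intercept),
        window=(lo, hi),
        r_squared=float(r2),
        n_bins=int(L.size),
        n_dropped_zero_bins=n_zero,
        ok=ok,
    )


def fit_decay_mle(dist: FragmentLengthDist, window: tuple[int, int] | None = None,
                  min_count: int = 10, mode_offset: int = 5) -> float:
    """Truncated-geometric maximum-likelihood lambda over the tail window.

    Sensitivity-check alternative to the OLS log-count fit: maximises the
    geometric likelihood conditioned on the window via golden-section search.
    """
    from scipy.optimize import minimize_scalar

    if window is None:
        window = select_tail_window(dist, min_count=min_count, mode_offset=mode_offset)
    lo, hi = window
    L, c = dist.lengths_array()
    sel = (L >= lo) & (L <= hi) & (c > 0)
    L, c = L[sel].astype(float), c[sel].astype(float)

    grid = np.arange(lo, hi + 1, dtype=float)

    def nll(lam: float) -> float:
        logq = math.log1p(-lam)
        norm = np.log(np.sum(np.exp((grid - lo) * logq)))
        return -(np.sum(c * (L - lo) * logq) - c.sum() * norm)

    res = minimize_scalar(nll, bounds=(1e-8, 0.5), method="bounded")
    return float(res.x)
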