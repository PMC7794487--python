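"""Test-only unimodality oracle: Silverman's critical-bandwidth bootstrap.

For a Gaussian kernel the number of KDE modes is non-increasing in the
bandwidth, so the smallest bandwidth giving a unimodal estimate (h_crit) is
well defined; multimodal data need a large h_crit.  Significance comes from a
smoothed bootstrap under the unimodal fit: p = P(h_crit* >= h_crit).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde


def _n_modes(x: np.ndarray, h: float, grid: np.ndarray) -> int:
    kde = gaussian_kde(x, bw_method=h / x.std(ddof=1))
    dens = kde(grid)
    d = np.diff(dens)
    signs = np.sign(d[np.abs(d) > 1e-30])
    return int(max(1, (np.diff(signs) < 0).sum()))


def critical_bandwidth(x: np.ndarray, k: int = 1, tol: float = 1e-3) -> float:
    """Smallest bandwidth at which the Gaussian KDE has at most ``k`` modes."""
    x = np.asarray(x, dtype=float)
    grid = np.linspace(x.min() - x.std(), x.max() + x.std(), 512)
    lo, hi = 1e-3 * x.std(), 2.0 * x.std()
    while _n_modes(x, hi, grid) > k:
        hi *= 2
    while hi / lo > 1 + tol:
        mid = np.sqrt(lo * hi)
        if _n_modes(x, mid, grid) <= k:
            hi = mid
        else:
            lo = mid
    return hi


def quasiconcavity_test(x: np.ndarray, peak_a: tuple[float, float],
                        valley: tuple[float, float],
                        peak_b: tuple[float, float]) -> float:
    """Exact one-sided p-value against unimodality via window counts.

    A unimodal (quasi-concave) density satisfies f(x) >= min(f(a), f(b)) for
    x between a and b, so the expected count density in a valley window lying
    between two flanking windows cannot fall below that of *both* flanks.
    Conditional on the window totals the valley count is binomial; the
    reported p is the larger of the two one-sided binomial tails (valid for
    the composite null).  Windows must be disjoint and ordered a < v < b.
    """
    from scipy.stats import binom

    x = np.asarray(x, dtype=float)
    if not (peak_a[1] <= valley[0] and valley[1] <= peak_b[0]):
        raise ValueError("windows must be ordered and disjoint")
    counts = {}
    widths = {}
    for name, (lo, hi) in (("a", peak_a), ("v", valley), ("b", peak_b)):
        counts[name] = int(((x >= lo) & (x < hi)).sum())
        widths[name] = hi - lo
    ps = []
    for flank in ("a", "b"):
        m = counts["v"] + counts[flank]
        p0 = widths["v"] / (widths["v"] + widths[flank])
        ps.append(binom.cdf(counts["v"], m, p0) if m else 1.0)
    return float(max(ps))


def silverman_test(x: np.ndarray, n_boot: int = 100, seed: int = 0,
                   max_n: int = 1000) -> tuple[float, float]:
    """(h_crit, p) for the null hypothesis that the density is unimodal."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    if x.size > max_n:
        x = rng.choice(x, size=max_n, replace=False)
    h = critical_bandwidth(x)
    sd = x.std(ddof=1)
    scale = 1.0 / np.sqrt(1.0 + h * h / (sd * sd))  # variance-corrected
    xbar = x.mean()
    count = 0
    for _ in range(n_boot):
        y = x[rng.integers(0, x.size, x.size)]
        y = xbar + scale * (y - xbar + h * rng.normal(size=x.size))
        if critical_bandwidth(y) >= h:
            count += 1
    return h, (1 + count) / (n_boot + 1)
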