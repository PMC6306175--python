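"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's vectorised code paths: histograms
by explicit tallying, connected components by breadth-first search,
quantiles by bisection, and printed-table checks by propagating the
half-ulp rounding interval of the printed inputs.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_histogram(intensities: np.ndarray) -> dict[int, int]:
    counts: dict[int, int] = {}
    for v in intensities.ravel().tolist():
        counts[int(v)] = counts.get(int(v), 0) + 1
    return counts


def brute_contribution_cdf(intensities: np.ndarray) -> dict[int, float]:
    counts = brute_histogram(intensities)
    total = sum(x * n for x, n in counts.items())
    cdf = {}
    running = 0
    for x in range(max(counts) + 1):
        running += x * counts.get(x, 0)
        cdf[x] = running / total
    return cdf


def brute_fraction_above(intensities: np.ndarray, threshold: float) -> float:
    flat = intensities.ravel().tolist()
    total = sum(flat)
    return sum(v for v in flat if v >= threshold) / total


def _neighbors(idx, shape, connectivity):
    r, c, k = idx
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (dr, dc, dk) == (0, 0, 0):
                    continue
                if connectivity == 6 and abs(dr) + abs(dc) + abs(dk) != 1:
                    continue
                rr, cc, kk = r + dr, c + dc, k + dk
                if 0 <= rr < shape[0] and 0 <= cc < shape[1] and 0 <= kk < shape[2]:
                    out.append((rr, cc, kk))
    return out


def brute_components(mask: np.ndarray, connectivity: int = 26) -> list[frozenset]:
    """Connected components of a boolean 3-D mask via BFS."""
    seen = np.zeros(mask.shape, dtype=bool)
    components = []
    for idx in zip(*np.nonzero(mask)):
        if seen[idx]:
            continue
        queue = deque([idx])
        seen[idx] = True
        comp = set()
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for nb in _neighbors(cur, mask.shape, connectivity):
                if mask[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        components.append(frozenset(comp))
    return components


def bisect_quantile(a: float, x0: float, b: float, q: float, normalized: bool = True,
                    lo: float = 1e-12, hi: float = 1e12, tol: float = 1e-12) -> float:
    """Solve y(x)/a = q (or y(x) = q) for the log-logistic by bisection."""

    def f(x):
        y = a / (1.0 + (x / x0) ** (-b))
        return (y / a if normalized else y) - q

    assert f(lo) < 0 < f(hi)
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def printed_interval(value: float, decimals: int) -> tuple[float, float]:
    """Half-ulp interval of a value printed with the given decimals."""
    h = 0.5 * 10.0 ** (-decimals)
    return value - h, value + h


def in_printed_bounds(printed: float, lo: float, hi: float, decimals: int) -> bool:
    """Is the printed value consistent with a true value in [lo, hi]?"""
    h = 0.5 * 10.0 ** (-decimals)
    return (lo - h) <= printed <= (hi + h)
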