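"""Independent brute-force reference implementations.

Everything here is deliberately naive and coded from the definitions
only — per-candidate boolean masks, explicit loops, no shared helpers
with the package — so it can serve as an oracle for the optimised
threshold scan.
"""

from __future__ import annotations

import math

import numpy as np


def naive_z(p_out: float, n_out: int, p_iqr: float, n_iqr: int) -> float:
    """Pooled-variance two-proportion Z, straight from the formula."""
    p_wa = (p_iqr * n_iqr + p_out * n_out) / (n_iqr + n_out)
    if p_wa <= 0 or p_wa >= 1:
        return 0.0
    return (p_out - p_iqr) / math.sqrt(
        p_wa * (1 - p_wa) * (1 / n_iqr + 1 / n_out)
    )


def naive_scan(
    x: np.ndarray,
    y: np.ndarray,
    side: str,
    n_segments: int = 50,
    min_support_excluded: int = 5,
):
    """Brute-force optimal-threshold search for one variable and side.

    Recomputes the IQR baseline, the candidate grid and every tail count
    from scratch with boolean masks. Returns (cut, z, n_out, p_out) or
    None. Tie in |z| goes to the candidate nearest the median.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    if x.size < 4 or np.all(y == y[0]):
        return None
    p25 = np.percentile(x, 25)
    p75 = np.percentile(x, 75)
    med = np.percentile(x, 50)
    in_iqr = (x >= p25) & (x <= p75)
    n_iqr = int(in_iqr.sum())
    p_iqr = float(y[in_iqr].mean())
    xs = np.sort(x)
    k = min_support_excluded
    if xs.size <= k:
        return None
    if side == "below":
        lo, hi = xs[k], med
    else:
        lo, hi = med, xs[-1 - k]
    if not hi > lo:
        return None
    grid = np.linspace(lo, hi, n_segments + 1)[1:-1]
    best = None
    candidates = list(grid) if side == "above" else list(grid)[::-1]
    # iterate starting from the median side so that the first strict
    # improvement rule reproduces "closest to the median wins ties"
    for cut in candidates:
        tail = x < cut if side == "below" else x > cut
        n_out = int(tail.sum())
        if n_out < 1:
            continue
        p_out = float(y[tail].mean())
        z = naive_z(p_out, n_out, p_iqr, n_iqr)
        if best is None or abs(z) > abs(best[1]):
            best = (float(cut), z, n_out, p_out)
    return best


def null_detection_rate(
    n_vars: int,
    n_obs: int,
    critical: float,
    seed: int,
    sides: tuple[str, ...] = ("below", "above"),
) -> float:
    """Monte-Carlo rate of spuriously significant variable-sides.

    Draws independent x ~ U(0,1) and y ~ Bernoulli(0.3) (independent of
    x) and counts, via the brute-force scan, the fraction of
    variable-side searches whose best |Z| clears ``critical``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for _ in range(n_vars):
        x = rng.uniform(size=n_obs)
        y = rng.binomial(1, 0.3, size=n_obs).astype(float)
        for side in sides:
            res = naive_scan(x, y, side)
            total += 1
            if res is not None and abs(res[1]) >= critical:
                hits += 1
    return hits / total
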