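"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — flood fill by BFS, exact rational
hypergeometric enumeration, exhaustive threshold sweeps — and shares no code
with the package under test.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """All connected components of a binary mask as sets of (r, c) tuples."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        comp = set()
        q = deque([(int(r0), int(c0))])
        seen[r0, c0] = True
        while q:
            r, c = q.popleft()
            comp.add((r, c))
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                    if mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        q.append((rr, cc))
        comps.append(frozenset(comp))
    return comps


def band_filter_components(comps, pixel_size_um, lo_um2, hi_um2):
    """Keep components whose area in µm² lies in the closed band."""
    out = []
    for comp in comps:
        area = len(comp) * pixel_size_um**2
        if lo_um2 <= area <= hi_um2:
            out.append(comp)
    return out


def brute_force_colocalized(query_sets, reference_sets, min_overlap_px=1):
    """Indices of query pixel-sets overlapping the union of reference sets."""
    ref_union = set().union(*reference_sets) if reference_sets else set()
    return [
        i for i, q in enumerate(query_sets)
        if len(set(q) & ref_union) >= min_overlap_px
    ]


def brute_force_assignment(punctum_pixels, red_pixels, green_pixels):
    """Largest-overlap channel assignment for one punctum pixel-set."""
    o_red = len(set(punctum_pixels) & set(red_pixels))
    o_green = len(set(punctum_pixels) & set(green_pixels))
    if o_red == 0 and o_green == 0:
        return "none"
    if o_red > o_green:
        return "red"
    if o_green > o_red:
        return "green"
    return "unknown"


def fisher_two_sided_exact(table) -> float:
    """Fisher's exact two-sided p by exact rational enumeration.

    Sums hypergeometric point probabilities (computed as Fractions, so no
    float comparisons are involved) of every table with the observed margins
    whose probability is <= the observed table's.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def otsu_exhaustive(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance by exhaustive sweep.

    Candidate thresholds are the midpoints of the 256-bin histogram used by
    the standard implementation; returns the best candidate.
    """
    v = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(v, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = centers[0], -1.0
    for t in centers:
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / v.size, hi.size / v.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(best_t)


def t_pdf_quadrature_sf(t_value: float, df: float) -> float:
    """Two-sided t tail by numerical integration of the density."""
    from scipy.integrate import quad
    from math import gamma, sqrt, pi

    def pdf(x):
        return (
            gamma((df + 1) / 2)
            / (sqrt(df * pi) * gamma(df / 2))
            * (1 + x * x / df) ** (-(df + 1) / 2)
        )

    tail, _ = quad(pdf, abs(t_value), np.inf)
    return 2 * tail
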