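"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by the most literal route available
(per-cell rule checking, dense lattices, scipy reference algorithms) and
share no code path with the functions they verify.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform


def interpolation_oracle(sp_range, env, depth_bins, lat_bins) -> np.ndarray:
    """Literal per-cell evaluation of the informed-interpolation rules.

    A latitude bin is occupied iff it holds an observation, or it is a
    candidate (inside the observed span and the catalogued latitudinal
    limits), not blocked (rule a: disjunction band; rule b: envelope/depth
    mismatch), and reachable from some observation without crossing a
    blocked, unobserved bin (rule c).  Depth bins are the catalogued interval
    clipped at the envelope maximum.
    """
    cat = sp_range.catalogue
    obs = set(int(b) for b in sp_range.observed_lat_bins)
    lo_obs, hi_obs = min(obs), max(obs)
    interval = sp_range.depth_interval()

    def blocked(b: int) -> bool:
        if any(g0 < b + 0.5 < g1 for g0, g1 in cat.exclusion_bands):
            return True
        if b not in env.index:
            return True
        row = env.loc[b]
        if not bool(row["has_sea"]):
            return True
        return not (row["min_depth_m"] <= interval[1]
                    and row["max_depth_m"] >= interval[0])

    def candidate(b: int) -> bool:
        return lo_obs <= b <= hi_obs and b < cat.lat_max and b + 1 > cat.lat_min

    def reachable(b: int) -> bool:
        for o in obs:
            lo, hi = sorted((b, o))
            if all((m in obs) or not blocked(m) for m in range(lo + 1, hi)):
                return True
        return False

    out = np.zeros((len(lat_bins), len(depth_bins)), dtype=bool)
    tops, bottoms = depth_bins.edges[:-1], depth_bins.edges[1:]
    for i, b in enumerate(int(x) for x in lat_bins):
        occupied = (b in obs) or (candidate(b) and not blocked(b) and reachable(b))
        if not occupied:
            continue
        emax = float(env.loc[b, "max_depth_m"]) if b in env.index else np.nan
        hi_eff = min(interval[1], emax) if np.isfinite(emax) else np.nan
        if not np.isfinite(hi_eff) or hi_eff < interval[0]:
            continue
        for d in range(len(depth_bins)):
            if tops[d] < hi_eff and bottoms[d] > interval[0]:
                out[i, d] = True
        if not out[i].any():  # degenerate point range: single containing bin
            d = int(np.searchsorted(depth_bins.edges, interval[0], side="right") - 1)
            if 0 <= d < len(depth_bins):
                out[i, d] = True
    return out


def upgma_cophenetic_oracle(D: np.ndarray) -> np.ndarray:
    """Cophenetic distance matrix from scipy's average-linkage clustering."""
    Z = linkage(squareform(D, checks=False), method="average")
    return squareform(cophenet(Z))


def dense_cell_envelope(grid, lat_bin, lon_bin, n: int = 32):
    """Cell envelope from an n x n interior lattice (reference for 10 x 10)."""
    off = (np.arange(n) + 0.5) / n
    la, lo = np.meshgrid(lat_bin + off, lon_bin + off, indexing="ij")
    d = grid.depth_at(la.ravel(), lo.ravel())
    sea = d[np.isfinite(d)]
    if sea.size == 0:
        return (np.nan, np.nan, False)
    return (float(sea.min()), float(sea.max()), True)
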