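"""Province assemblages, Sorenson similarity, and UPGMA clustering.

Shallow-water (<200 m) faunas are compared between eco-provinces with the
Sorenson coefficient, ``100 * 2a / (2a + b + c)`` where ``a`` is the number
of shared species and ``b``, ``c`` the counts unique to each side.  The
similarity matrix is converted to a dissimilarity (``100 - S``) and clustered
with UPGMA (average linkage with size-weighted updates), which yields an
ultrametric dendrogram of faunal provinces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProvinceDefinition:
    """A named province as a union of lat/lon rectangles."""

    province_id: str
    name: str = ""
    boxes: tuple = ()           # ((lat_lo, lat_hi, lon_lo, lon_hi), ...)
    realm: str = ""

    def __post_init__(self):
        if not self.boxes:
            raise ValueError(f"province {self.province_id} has empty geometry")

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        out = np.zeros(lat.shape, dtype=bool)
        for la0, la1, lo0, lo1 in self.boxes:
            out |= (lat >= la0) & (lat < la1) & (lon >= lo0) & (lon < lo1)
        return out


def assign_species(records: pd.DataFrame, provinces: list[ProvinceDefinition],
                   catalogue=None, depth_limit: float = 200.0
                   ) -> dict[str, set[str]]:
    """Province -> species set.

    A species joins a province when it has at least one record inside the
    province's geometry shallower than ``depth_limit``, or when the catalogue
    names the province (or its realm) among the species' regions.  Records
    matching no province are counted and logged.
    """
    shallow = records.loc[records["depth_m"] < depth_limit]
    lat = shallow["decimalLatitude"].to_numpy(float)
    lon = shallow["decimalLongitude"].to_numpy(float)
    sids = shallow["species_id"].to_numpy(object)
    assigned = np.zeros(len(shallow), dtype=bool)
    out: dict[str, set[str]] = {}
    for prov in provinces:
        inside = prov.contains(lat, lon)
        assigned |= inside
        out[prov.province_id] = set(sids[inside])
    if catalogue is not None:
        for prov in provinces:
            names = {prov.province_id, prov.name, prov.realm} - {""}
            for sid, entry in catalogue.items():
                if entry.regions & names:
                    out[prov.province_id].add(sid)
    n_un = int((~assigned).sum())
    if n_un:
        log.warning("%d shallow records fell in no province", n_un)
    return out


def sorenson(a: set, b: set) -> float:
    """Sorenson similarity, as a percentage, between two faunas."""
    if not a and not b:
        raise ValueError("Sorenson coefficient undefined for two empty faunas")
    shared = len(a & b)
    return 100.0 * (2 * shared) / (2 * shared + len(a - b) + len(b - a))


def similarity_matrix(assemblages: dict[str, set]) -> pd.DataFrame:
    """All-pairs Sorenson matrix (symmetric, diagonal 100)."""
    if len(assemblages) < 2:
        raise ValueError("need at least two provinces")
    labels = list(assemblages)
    n = len(labels)
    S = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = sorenson(assemblages[labels[i]], assemblages[labels[j]])
    return pd.DataFrame(S, index=labels, columns=labels)


def exclude_sparse(assemblages: dict[str, set], min_species: int
                   ) -> dict[str, set]:
    """Drop provinces with fewer than ``min_species`` species (endemic islets
    that cannot be resolved in the dendrogram)."""
    dropped = [k for k, v in assemblages.items() if len(v) < min_species]
    if dropped:
        log.info("excluded %d sparse provinces: %s", len(dropped), dropped)
    return {k: v for k, v in assemblages.items() if len(v) >= min_species}


# --------------------------------------------------------------------------- #
# UPGMA
# --------------------------------------------------------------------------- #
@dataclass
class DendrogramNode:
    """A node of the ultrametric UPGMA tree (height in dissimilarity units)."""

    height: float = 0.0
    label: str | None = None
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]


def upgma(D, labels=None) -> DendrogramNode:
    """UPGMA tree from a symmetric dissimilarity matrix with zero diagonal.

    Pairs merge at height D/2 with size-weighted average-linkage updates;
    distance ties break on the lowest (row, col) index pair, which makes the
    result deterministic.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index) if labels is None else list(labels)
        D = D.to_numpy(dtype=float)
    else:
        D = np.asarray(D, dtype=float)
        labels = [str(i) for i in range(D.shape[0])] if labels is None else list(labels)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    if n == 1:
        return DendrogramNode(0.0, labels[0])
    D = D.copy()
    nodes = [DendrogramNode(0.0, lab) for lab in labels]
    sizes = [1] * n
    active = list(range(n))
    while len(active) > 1:
        best, bi, bj = np.inf, -1, -1
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                if D[i, j] < best - 1e-12:
                    best, bi, bj = D[i, j], i, j
        new = DendrogramNode(best / 2.0, None, (nodes[bi], nodes[bj]))
        wi, wj = sizes[bi], sizes[bj]
        for k in active:
            if k in (bi, bj):
                continue
            D[bi, k] = D[k, bi] = (wi * D[bi, k] + wj * D[bj, k]) / (wi + wj)
        nodes[bi] = new
        sizes[bi] = wi + wj
        active.remove(bj)
    return nodes[active[0]]


def cophenetic_matrix(tree: DendrogramNode) -> pd.DataFrame:
    """Pairwise cophenetic distances (2 x merge height) between leaves."""
    labels = tree.leaves()
    idx = {l: i for i, l in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))

    def walk(node):
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        M[idx[a], idx[b]] = M[idx[b], idx[a]] = 2 * node.height
        return [l for g in groups for l in g]

    walk(tree)
    return pd.DataFrame(M, index=labels, columns=labels)


def to_newick(tree: DendrogramNode) -> str:
    """Newick text with branch lengths equal to height differences."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            if any(ch in (node.label or "") for ch in "(),:;"):
                raise ValueError(f"leaf label not Newick-safe: {node.label!r}")
            core = node.label
        else:
            core = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        return f"{core}:{bl:.12g}" if np.isfinite(bl) else core

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"
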