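"""Per-plate signed co-occurrence network inference.

For each effective plate: drop non-growing wells, keep Zotus present in at
least ``min_frac`` of the growing wells, compute tie-corrected Spearman rank
correlations between all Zotu pairs (on per-well relative abundances by
default), adjust p-values with Benjamini-Hochberg within the plate, keep
edges with |rho| > rho_min and q < q_max (strict), then restrict to the
low-degree sub-network (degree centrality < max_degree, single pass).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import PlateDesign, PlateTable, WellGrowth, detect_growth

__all__ = [
    "Edge",
    "Network",
    "NetworkSummary",
    "EmptyPlateError",
    "prevalence_filter",
    "spearman_rho",
    "bh_fdr",
    "build_network",
    "degree_filter",
    "summarize",
    "write_edge_list",
    "write_graphml",
    "infer_subnetwork",
]

logger = logging.getLogger(__name__)


class EmptyPlateError(ValueError):
    """Raised when a plate has no growing wells (or nothing left to correlate)."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically sorted endpoints."""
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Edge:
    zotu_a: str
    zotu_b: str
    rho: float
    p_raw: float
    q_fdr: float

    def __post_init__(self) -> None:
        if self.zotu_a == self.zotu_b:
            raise ValueError("self-edge")
        if self.zotu_a > self.zotu_b:
            a, b = self.zotu_b, self.zotu_a
            object.__setattr__(self, "zotu_a", a)
            object.__setattr__(self, "zotu_b", b)
        if not np.isfinite(self.rho) or not -1 <= self.rho <= 1:
            raise ValueError(f"rho out of range: {self.rho}")

    @property
    def sign(self) -> int:
        return 1 if self.rho >= 0 else -1

    @property
    def key(self) -> tuple[str, str]:
        return (self.zotu_a, self.zotu_b)


@dataclass(frozen=True)
class Network:
    """Thresholded signed co-occurrence graph for one plate."""

    plate_id: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    rho_min: float
    q_max: float
    design: PlateDesign | None = None
    skipped_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.zotu_a not in node_set or e.zotu_b not in node_set:
                raise ValueError(f"edge {e.key} endpoint not in nodes")
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))

    @property
    def degrees(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.zotu_a] += 1
            deg[e.zotu_b] += 1
        return deg

    @property
    def edge_keys(self) -> set[tuple[str, str]]:
        return {e.key for e in self.edges}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(plate_id=self.plate_id)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.zotu_a, e.zotu_b, rho=e.rho, p_raw=e.p_raw, q_fdr=e.q_fdr, sign=e.sign)
        return g


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    density: float
    mean_degree: float
    max_degree: int


def prevalence_filter(
    plate: PlateTable,
    min_frac: float = 0.30,
    growing_wells: list[WellGrowth] | None = None,
    min_reads: int = 100,
    denominator: str = "growing",
) -> PlateTable:
    """Restrict to growing wells and Zotus present in >= ``min_frac`` of them.

    Zotus with occurrence frequency below 30% of wells are filtered before
    correlation. ``denominator`` selects whether prevalence is computed over
    growing wells (default) or over all wells of the plate.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must be in [0, 1]")
    if denominator not in ("growing", "all"):
        raise ValueError("denominator must be 'growing' or 'all'")
    if growing_wells is None:
        growing_wells = detect_growth(plate, min_reads=min_reads)
    grown_ids = [g.well_id for g in growing_wells if g.grew]
    if not grown_ids:
        raise EmptyPlateError(f"plate {plate.plate_id}: zero growing wells")
    sub = plate.subset(wells=grown_ids)
    denom = len(grown_ids) if denominator == "growing" else plate.n_wells
    presence_frac = (sub.counts > 0).sum(axis=0) / denom
    keep = [z for z, f in zip(sub.zotu_ids, presence_frac) if f >= min_frac]
    return sub.subset(zotu_ids=keep)


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho and its two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks; p comes from
    t = rho*sqrt((n-2)/(1-rho^2)) with n-2 df (p = 0 at |rho| = 1). A
    zero-variance input after ranking is undefined and raises ValueError
    (callers skip and record such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need n >= 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input: Spearman correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order-preserving.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p's, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def build_network(
    filtered_plate: PlateTable,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    relative_abundance: bool = True,
) -> Network:
    """All-pairs Spearman + BH-FDR, thresholded at |rho| > rho_min and q < q_max.

    Correlations are computed on per-well total-sum-scaled abundances by
    default (``relative_abundance=False`` correlates raw counts). FDR is
    adjusted over all testable pairs within this plate. Pairs whose ranks
    are constant are skipped and recorded, not assigned rho = 0.
    """
    n_wells, n_zotus = filtered_plate.counts.shape
    if n_zotus < 2:
        return Network(
            plate_id=filtered_plate.plate_id,
            nodes=filtered_plate.zotu_ids,
            edges=(),
            rho_min=rho_min,
            q_max=q_max,
            design=filtered_plate.design,
        )
    if n_wells < 4:
        raise EmptyPlateError(f"plate {filtered_plate.plate_id}: need >= 4 wells, have {n_wells}")

    data = filtered_plate.counts.astype(float)
    if relative_abundance:
        totals = data.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.nan_to_num(data / totals)

    zotus = filtered_plate.zotu_ids
    constant = np.ptp(data, axis=0) == 0
    testable = [i for i in range(n_zotus) if not constant[i]]
    skipped = [
        pair_key(zotus[i], zotus[j])
        for i, j in itertools.combinations(range(n_zotus), 2)
        if constant[i] or constant[j]
    ]
    if skipped:
        logger.info("plate %s: skipped %d constant-rank pairs", filtered_plate.plate_id, len(skipped))

    pairs: list[tuple[int, int]] = list(itertools.combinations(testable, 2))
    edges: list[Edge] = []
    if pairs:
        # vectorized rank-Pearson over all testable columns at once
        ranks = np.apply_along_axis(stats.rankdata, 0, data[:, testable])
        corr = np.corrcoef(ranks, rowvar=False)
        corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
        pos = {col: k for k, col in enumerate(testable)}
        rhos = np.array([corr[pos[i], pos[j]] for i, j in pairs])
        n = n_wells
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rhos * np.sqrt((n - 2) / (1.0 - rhos**2))
        p_raw = np.where(np.abs(rhos) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2))
        q = bh_fdr(p_raw)
        for (i, j), rho, p, qv in zip(pairs, rhos, p_raw, q):
            if abs(rho) > rho_min and qv < q_max:
                a, b = pair_key(zotus[i], zotus[j])
                edges.append(Edge(zotu_a=a, zotu_b=b, rho=float(rho), p_raw=float(p), q_fdr=float(qv)))
    edges.sort(key=lambda e: e.key)
    return Network(
        plate_id=filtered_plate.plate_id,
        nodes=zotus,
        edges=tuple(edges),
        rho_min=rho_min,
        q_max=q_max,
        design=filtered_plate.design,
        skipped_pairs=tuple(skipped),
    )


def degree_filter(network: Network, max_degree: int = 5) -> Network:
    """Low-degree sub-network: keep nodes with degree < max_degree (single pass).

    Degrees are taken from the input network and not recomputed after node
    removal; an edge survives iff both endpoints survive.
    """
    deg = network.degrees
    kept_nodes = tuple(n for n in network.nodes if deg[n] < max_degree)
    kept_set = set(kept_nodes)
    kept_edges = tuple(e for e in network.edges if e.zotu_a in kept_set and e.zotu_b in kept_set)
    return replace(network, nodes=kept_nodes, edges=kept_edges)


def summarize(network: Network) -> NetworkSummary:
    degs = list(network.degrees.values())
    n_nodes = len(network.nodes)
    n_edges = len(network.edges)
    n_pos = sum(1 for e in network.edges if e.sign > 0)
    density = 2 * n_edges / (n_nodes * (n_nodes - 1)) if n_nodes >= 2 else 0.0
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_pos,
        n_negative=n_edges - n_pos,
        density=density,
        mean_degree=float(np.mean(degs)) if degs else 0.0,
        max_degree=max(degs) if degs else 0,
    )


def infer_subnetwork(
    plate: PlateTable,
    min_reads: int = 100,
    prevalence_min_frac: float = 0.30,
    rho_min: float = 0.6,
    q_max: float = 0.01,
    max_degree: int = 5,
    relative_abundance: bool = True,
    prevalence_denominator: str = "growing",
) -> Network:
    """Full per-plate chain: growth filter -> prevalence filter -> correlate -> degree filter."""
    filtered = prevalence_filter(
        plate,
        min_frac=prevalence_min_frac,
        min_reads=min_reads,
        denominator=prevalence_denominator,
    )
    net = build_network(filtered, rho_min=rho_min, q_max=q_max, relative_abundance=relative_abundance)
    return degree_filter(net, max_degree=max_degree)


def write_edge_list(network: Network, path: str | Path) -> None:
    rows = [
        {
            "zotu_a": e.zotu_a,
            "zotu_b": e.zotu_b,
            "rho": e.rho,
            "p_raw": e.p_raw,
            "q_fdr": e.q_fdr,
            "sign": e.sign,
        }
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=["zotu_a", "zotu_b", "rho", "p_raw", "q_fdr", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(network: Network, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(network.to_networkx(), str(path))
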