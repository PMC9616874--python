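"""Cross-network pair prevalence: FO = Np/Ng, robust pairs, Jaccard similarity.

Each effective plate yields one sub-network. Within a group of networks that
share the same (sample_type, medium) — dilution level and replicate are
deliberately pooled — a Zotu pair's frequency of occurrence is

    FO = Np / Ng

where Np counts the group's networks containing the pair as an edge and Ng
is the group size. Pairs with FO strictly above ``fo_min`` (default 30%) are
the robust prevalent pairs; the top-k report mirrors the usual summary-table
layout and intentionally applies no FO cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "PairPrevalence",
    "JaccardMatrix",
    "pair_prevalence",
    "retain_robust_pairs",
    "top_pairs_report",
    "jaccard_matrix",
    "unique_pair_count",
    "write_pair_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairPrevalence:
    zotu_a: str
    zotu_b: str
    group: tuple[str, str]
    np_count: int
    ng_total: int
    mean_rho: float
    sign_consensus: int
    sign_conflict: bool

    def __post_init__(self) -> None:
        if not 0 <= self.np_count <= self.ng_total:
            raise ValueError("need 0 <= Np <= Ng")

    @property
    def fo(self) -> float:
        return self.np_count / self.ng_total

    @property
    def fo_exact(self) -> Fraction:
        return Fraction(self.np_count, self.ng_total)


@dataclass(frozen=True)
class JaccardMatrix:
    network_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.network_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape inconsistent with network ids")
        if not np.allclose(v, v.T):
            raise ValueError("Jaccard matrix must be symmetric")
        object.__setattr__(self, "values", v)


def _group_of(network: Network) -> tuple[str, str]:
    if network.design is None:
        raise ValueError(f"network {network.plate_id} carries no plate design; cannot group")
    return network.design.group


def pair_prevalence(subnetworks: Sequence[Network]) -> list[PairPrevalence]:
    """One record per (pair, group) with Np >= 1; groups keyed by (sample_type, medium).

    FO counts a pair whenever its edge passed the rho/q thresholds regardless
    of sign; the consensus sign (majority over occurrences, ties +1) and a
    conflict flag preserve the sign structure for reporting.
    """
    if not subnetworks:
        raise ValueError("empty network list")
    groups: dict[tuple[str, str], list[Network]] = {}
    for net in subnetworks:
        groups.setdefault(_group_of(net), []).append(net)

    out: list[PairPrevalence] = []
    for group, nets in sorted(groups.items()):
        ng = len(nets)
        occurrences: dict[tuple[str, str], list[float]] = {}
        for net in nets:
            for e in net.edges:
                occurrences.setdefault(e.key, []).append(e.rho)
        for (a, b), rhos in sorted(occurrences.items()):
            signs = [1 if r >= 0 else -1 for r in rhos]
            n_pos = sum(1 for s in signs if s > 0)
            consensus = 1 if n_pos * 2 >= len(signs) else -1
            out.append(
                PairPrevalence(
                    zotu_a=a,
                    zotu_b=b,
                    group=group,
                    np_count=len(rhos),
                    ng_total=ng,
                    mean_rho=float(np.mean(rhos)),
                    sign_consensus=consensus,
                    sign_conflict=len(set(signs)) > 1,
                )
            )
    return out


def retain_robust_pairs(prevalences: Sequence[PairPrevalence], fo_min: float = 0.30) -> list[PairPrevalence]:
    """Keep pairs with occurrence frequency strictly above ``fo_min``.

    The comparison is exact rational arithmetic, so FO = 3/10 is dropped at
    fo_min = 0.30 with no floating-point ambiguity.
    """
    threshold = Fraction(fo_min).limit_denominator(10**9)
    return [p for p in prevalences if p.fo_exact > threshold]


def top_pairs_report(prevalences: Sequence[PairPrevalence], k: int = 3) -> pd.DataFrame:
    """Per group, the k highest-FO pairs (ties: higher mean |rho|, then pair id)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    by_group: dict[tuple[str, str], list[PairPrevalence]] = {}
    for p in prevalences:
        by_group.setdefault(p.group, []).append(p)
    for group, items in sorted(by_group.items()):
        ranked = sorted(items, key=lambda p: (-p.fo_exact, -abs(p.mean_rho), p.zotu_a, p.zotu_b))
        for p in ranked[:k]:
            rows.append(
                {
                    "sample_type": group[0],
                    "medium": group[1],
                    "zotu_a": p.zotu_a,
                    "zotu_b": p.zotu_b,
                    "Np": p.np_count,
                    "Ng": p.ng_total,
                    "FO": p.fo,
                    "consensus_sign": p.sign_consensus,
                    "mean_rho": p.mean_rho,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_type", "medium", "zotu_a", "zotu_b", "Np", "Ng", "FO", "consensus_sign", "mean_rho"],
    )


def jaccard_matrix(networks: Sequence[Network]) -> JaccardMatrix:
    """Pairwise Jaccard similarity of edge sets; 0 when both sets are empty."""
    ids = tuple(n.plate_id for n in networks)
    edge_sets = [n.edge_keys for n in networks]
    n = len(networks)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            union = edge_sets[i] | edge_sets[j]
            if not union:
                if i != j:
                    logger.info("jaccard(%s, %s): both edge sets empty, defined as 0", ids[i], ids[j])
                values[i, j] = values[j, i] = 0.0
            else:
                inter = edge_sets[i] & edge_sets[j]
                values[i, j] = values[j, i] = len(inter) / len(union)
    return JaccardMatrix(network_ids=ids, values=values)


def unique_pair_count(subnetworks: Sequence[Network]) -> int:
    """Size of the union of edge sets over all networks."""
    seen: set[tuple[str, str]] = set()
    for net in subnetworks:
        seen |= net.edge_keys
    return len(seen)


def write_pair_report(prevalences: Sequence[PairPrevalence], path: str | Path) -> None:
    rows = [
        {
            "sample_type": p.group[0],
            "medium": p.group[1],
            "zotu_a": p.zotu_a,
            "zotu_b": p.zotu_b,
            "Np": p.np_count,
            "Ng": p.ng_total,
            "FO": p.fo,
            "consensus_sign": p.sign_consensus,
            "sign_conflict": p.sign_conflict,
            "mean_rho": p.mean_rho,
        }
        for p in prevalences
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sample_type", "medium", "zotu_a", "zotu_b", "Np", "Ng", "FO",
            "consensus_sign", "sign_conflict", "mean_rho",
        ],
    ).to_csv(path, sep="\t", index=False)
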