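"""Matching cultured isolates to network Zotus.

An isolate's near-full-length 16S sequence is reduced to its V4 amplicon
(the insert between the 515F/806R primer sites), compared to every Zotu
representative sequence by global-alignment identity, and placed on a
neighbor-joining tree of all V4 sequences. An isolate represents a Zotu if
their V4 regions are identical (identity >= threshold, default 1.0);
otherwise it falls back to the nearest Zotu leaf by tree path length,
accepted only below a distance cap so matches never cross genus-scale
divergence. Isolate pairs to co-culture for a Zotu pair are enumerated from
the representative sets.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values
from skbio import TreeNode

__all__ = [
    "SeqRecord",
    "DistanceMatrix",
    "IsolateMatch",
    "NoAmpliconError",
    "V4_FWD_PRIMER",
    "V4_REV_PRIMER",
    "extract_v4",
    "pairwise_identity",
    "p_distance_matrix",
    "nj_tree",
    "tree_tip_distances",
    "match_isolates",
    "unmatched_zotus",
    "enumerate_combinations",
    "write_matches",
]

logger = logging.getLogger(__name__)

# standard V4 primer pair (515F / 806R), 5'->3', configurable at every call site
V4_FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
V4_REV_PRIMER = "GGACTACNVGGGTWTCTAAT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_EXPAND = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}


class NoAmpliconError(ValueError):
    """Raised when a primer site is absent within the mismatch budget."""


@dataclass(frozen=True)
class SeqRecord:
    id: str
    sequence: str
    kind: str  # "zotu_v4" or "isolate_16s"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - set(_EXPAND)
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")
        if self.kind not in ("zotu_v4", "isolate_16s"):
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if v.min() < 0:
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class IsolateMatch:
    isolate_id: str
    zotu_id: str
    v4_identity: float
    tree_distance: float
    matched: bool


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _mismatches(primer: str, window: str) -> int:
    """Mismatch count respecting IUPAC degeneracy on both strings."""
    return sum(
        1
        for p, w in zip(primer, window)
        if not (_EXPAND.get(p, frozenset()) & _EXPAND.get(w, frozenset()))
    )


def _find_sites(seq: str, primer: str, max_mismatch: int, start: int = 0) -> list[int]:
    hits = []
    for i in range(start, len(seq) - len(primer) + 1):
        if _mismatches(primer, seq[i : i + len(primer)]) <= max_mismatch:
            hits.append(i)
    return hits


def extract_v4(
    sequence: str,
    fwd_primer: str = V4_FWD_PRIMER,
    rev_primer: str = V4_REV_PRIMER,
    max_mismatch: int = 1,
) -> str:
    """Insert between the forward primer site and the downstream reverse site.

    Primers are given 5'->3'; the reverse primer is matched as its reverse
    complement downstream of the forward hit. Primer sequences themselves
    are excluded from the returned insert. Multiple forward hits use the
    leftmost with a warning; a missing site raises :class:`NoAmpliconError`.
    """
    seq = sequence.upper()
    fwd_hits = _find_sites(seq, fwd_primer.upper(), max_mismatch)
    if not fwd_hits:
        raise NoAmpliconError("forward primer site not found within mismatch budget")
    if len(fwd_hits) > 1:
        warnings.warn(f"{len(fwd_hits)} forward primer sites; using leftmost", stacklevel=2)
    insert_start = fwd_hits[0] + len(fwd_primer)
    rev_site = revcomp(rev_primer)
    rev_hits = _find_sites(seq, rev_site, max_mismatch, start=insert_start)
    if not rev_hits:
        raise NoAmpliconError("reverse primer site not found downstream of forward site")
    return seq[insert_start : rev_hits[0]]


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Scoring: match +1, mismatch -1, gap -2. Symmetric by construction
    (arguments are canonically ordered before aligning).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if a == b:
        return 1.0
    x, y = sorted((a, b))
    alignment = _aligner.align(x, y)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def p_distance_matrix(seqs: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise distances 1 - identity over a set of sequences."""
    labels = tuple(seqs)
    n = len(labels)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = 1.0 - pairwise_identity(seqs[labels[i]], seqs[labels[j]])
        values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def _clamp_pair(li: float, lj: float, a: str, b: str) -> tuple[float, float]:
    """Clamp a negative branch to 0, shifting the deficit to the sister branch."""
    if li < 0:
        logger.info("negative branch length %.3g on %s clamped; shifted to %s", li, a, b)
        lj += li
        li = 0.0
    if lj < 0:
        logger.info("negative branch length %.3g on %s clamped; shifted to %s", lj, b, a)
        li += lj
        lj = 0.0
    return li, max(lj, 0.0)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; unrooted tree (trifurcating root node).

    Each iteration joins the pair minimizing
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); branch lengths
    follow the standard NJ formulas, with negative lengths clamped to zero
    and the deficit shifted to the sister branch (logged). Ties on Q break
    on the lexicographically first label pair, so the result is
    deterministic and input-order invariant.
    """
    if len(dist.labels) < 3:
        raise ValueError("need >= 3 labels for a neighbor-joining tree")
    labels = list(dist.labels)
    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i, j in itertools.combinations(range(r), 2):
            q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
            key = (q, *sorted((str(nodes[i].name or ""), str(nodes[j].name or ""))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, str(nodes[i].name), str(nodes[j].name))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = float(li), float(lj)
        parent = TreeNode(children=[child_i, child_j])

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-point join
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        if length < 0:
            logger.info("negative terminal branch %.3g on %s clamped to 0", length, node.name)
        node.length = float(max(length, 0.0))
    return TreeNode(children=[a, b, c])


def tree_tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length (patristic) distances between all tips."""
    skbio_dm = tree.tip_tip_distances()
    labels = tuple(str(x) for x in skbio_dm.ids)
    return DistanceMatrix(labels=labels, values=np.asarray(skbio_dm.data, dtype=float))


def match_isolates(
    zotu_v4: Mapping[str, str],
    isolate_v4: Mapping[str, str],
    identity_threshold: float = 1.0,
    distance_cap: float = 0.03,
) -> list[IsolateMatch]:
    """Assign each isolate to a Zotu by V4 identity, then tree proximity.

    An isolate matches the Zotu with maximal V4 identity when that identity
    reaches ``identity_threshold``; identity ties break on shorter tree path
    length and remain unmatched if still tied. Below the threshold the
    isolate falls back to the nearest Zotu leaf on the joint NJ tree,
    accepted only if the path length is within ``distance_cap``.
    Deterministic and invariant to input ordering.
    """
    if not zotu_v4 or not isolate_v4:
        raise ValueError("need at least one zotu and one isolate sequence")
    zotu_ids = sorted(zotu_v4)
    isolate_ids = sorted(isolate_v4)

    combined = {z: zotu_v4[z] for z in zotu_ids}
    combined.update({i: isolate_v4[i] for i in isolate_ids})
    tree_dist: DistanceMatrix | None = None
    if len(combined) >= 3:
        tree = nj_tree(p_distance_matrix(combined))
        tree_dist = tree_tip_distances(tree)

    def path_length(iso: str, zotu: str) -> float:
        if tree_dist is None:
            return float("nan")
        i = tree_dist.labels.index(iso)
        j = tree_dist.labels.index(zotu)
        return float(tree_dist.values[i, j])

    matches: list[IsolateMatch] = []
    for iso in isolate_ids:
        identities = {z: pairwise_identity(isolate_v4[iso], zotu_v4[z]) for z in zotu_ids}
        best_ident = max(identities.values())
        candidates = sorted(z for z, v in identities.items() if v == best_ident)

        if best_ident >= identity_threshold:
            chosen, ambiguous = _closest_by_tree(candidates, iso, path_length)
            if ambiguous:
                matches.append(IsolateMatch(iso, "", best_ident, float("nan"), False))
            else:
                matches.append(IsolateMatch(iso, chosen, best_ident, path_length(iso, chosen), True))
            continue

        # fallback: nearest Zotu leaf by tree path length, capped
        if tree_dist is None:
            matches.append(IsolateMatch(iso, "", best_ident, float("nan"), False))
            continue
        dists = {z: path_length(iso, z) for z in zotu_ids}
        best_d = min(dists.values())
        nearest = sorted(z for z, v in dists.items() if v == best_d)
        if best_d <= distance_cap and len(nearest) == 1:
            z = nearest[0]
            matches.append(IsolateMatch(iso, z, identities[z], best_d, True))
        else:
            matches.append(IsolateMatch(iso, "", best_ident, best_d, False))
    return matches


def _closest_by_tree(candidates: list[str], iso: str, path_length) -> tuple[str, bool]:
    if len(candidates) == 1:
        return candidates[0], False
    dists = [(path_length(iso, z), z) for z in candidates]
    finite = [(d, z) for d, z in dists if np.isfinite(d)]
    if not finite:
        return "", True
    best = min(d for d, _ in finite)
    nearest = [z for d, z in finite if d == best]
    if len(nearest) == 1:
        return nearest[0], False
    return "", True


def unmatched_zotus(zotu_ids: Sequence[str], matches: Sequence[IsolateMatch]) -> list[str]:
    """Zotus with no matched isolate — the uncultivated fraction of the network."""
    represented = {m.zotu_id for m in matches if m.matched}
    return [z for z in zotu_ids if z not in represented]


def enumerate_combinations(
    pair: tuple[str, str],
    matches: Sequence[IsolateMatch] | Mapping[str, Sequence[str]],
) -> list[tuple[str, str]]:
    """Unordered isolate pairs to co-culture for one Zotu pair.

    Representative sets R(x), R(y) come from the matches. Identical sets of
    size n give C(n, 2) combinations, disjoint sets the full Cartesian
    product, overlapping sets the deduplicated cross pairs minus self-pairs.
    """
    x, y = pair
    if isinstance(matches, Mapping):
        reps = {z: set(v) for z, v in matches.items()}
    else:
        reps = {}
        for m in matches:
            if m.matched:
                reps.setdefault(m.zotu_id, set()).add(m.isolate_id)
    rx = reps.get(x, set())
    ry = reps.get(y, set())
    if not rx:
        raise ValueError(f"no representative isolates for zotu {x!r}")
    if not ry:
        raise ValueError(f"no representative isolates for zotu {y!r}")
    combos = {tuple(sorted((i, j))) for i in rx for j in ry if i != j}
    return sorted(combos)


def write_matches(matches: Sequence[IsolateMatch], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "isolate_id": m.isolate_id,
                "zotu_id": m.zotu_id,
                "identity": m.v4_identity,
                "tree_distance": m.tree_distance,
                "matched": m.matched,
            }
            for m in matches
        ],
        columns=["isolate_id", "zotu_id", "identity", "tree_distance", "matched"],
    ).to_csv(path, sep="\t", index=False)
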