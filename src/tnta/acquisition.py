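"""Counting independent TA-acquisition events from toxin phylogenies.

Within one toxin family, transposon-associated toxins are placed on a
distance tree together with non-transposon "seed" relatives of the family.
Identical sequences are collapsed to one representative first. The number
of independent acquisition events is operationalised as the number of
maximal clades whose leaves are all transposon-associated, under a rooting
on the seed side — i.e. the minimum number of seed-to-transposon origin
transitions the tree supports.

Trees are neighbour-joining on pairwise p-distances: the event count needs
only a topology, and NJ is exact on additive distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "ToxinEntry",
    "ToxinSet",
    "dedupe_identical",
    "pairwise_distances",
    "build_nj_tree",
    "count_acquisition_events",
]

ORIGINS = {"tn_associated", "seed"}


@dataclass(frozen=True)
class ToxinEntry:
    id: str
    aa_sequence: str
    origin: str  # "tn_associated" or "seed"
    family: str


@dataclass
class ToxinSet:
    entries: list[ToxinEntry]
    family: str = ""

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entry ids in ToxinSet")
        families = {e.family for e in self.entries}
        if len(families) > 1:
            raise ValueError(f"ToxinSet mixes families: {sorted(families)}")
        if not self.family and families:
            self.family = next(iter(families))

    @property
    def origins(self) -> dict[str, str]:
        return {e.id: e.origin for e in self.entries}


def dedupe_identical(toxins: ToxinSet) -> tuple[list[ToxinEntry], dict[str, list[str]]]:
    """Collapse exact-string duplicates; the representative is the entry
    with the lexicographically smallest id. Returns (representatives,
    representative id -> all member ids)."""
    groups: dict[str, list[ToxinEntry]] = {}
    for entry in toxins.entries:
        groups.setdefault(entry.aa_sequence, []).append(entry)
    reps: list[ToxinEntry] = []
    members: dict[str, list[str]] = {}
    for entries in groups.values():
        rep = min(entries, key=lambda e: e.id)
        reps.append(rep)
        members[rep.id] = sorted(e.id for e in entries)
    reps.sort(key=lambda e: e.id)
    return reps, members


_GLOBAL = None


def _global_aligner() -> PairwiseAligner:
    global _GLOBAL
    if _GLOBAL is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        _GLOBAL = aligner
    return _GLOBAL


def _p_distance(a: str, b: str) -> float:
    """Mismatched columns / aligned (ungapped) columns on a global alignment."""
    best = _global_aligner().align(a, b)[0]
    qc, rc = best.coordinates[0], best.coordinates[1]
    aligned = 0
    mismatched = 0
    for k in range(len(qc) - 1):
        dq, dr = int(qc[k + 1] - qc[k]), int(rc[k + 1] - rc[k])
        if dq and dr:
            qs, rs = int(qc[k]), int(rc[k])
            aligned += dq
            mismatched += sum(1 for i in range(dq) if a[qs + i] != b[rs + i])
    return mismatched / aligned if aligned else 1.0


def pairwise_distances(representatives: list[ToxinEntry]) -> tuple[list[str], np.ndarray]:
    """Symmetric p-distance matrix over the representatives."""
    if len(representatives) < 2:
        raise ValueError("need at least 2 representatives")
    ids = [e.id for e in representatives]
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _p_distance(representatives[i].aa_sequence, representatives[j].aa_sequence)
            dist[i, j] = dist[j, i] = d
    return ids, dist


def build_nj_tree(ids: list[str], dist: np.ndarray,
                  origins: dict[str, str] | None = None) -> TreeNode:
    """Neighbour-joining tree, rooted on the seed side.

    With ``origins``, the tree is rooted above the lexicographically
    smallest seed leaf (outgroup rooting); otherwise, and when no seed
    exists, at the midpoint. Negative NJ branch lengths are clamped to 0.
    """
    n = len(ids)
    if n < 3:
        raise ValueError(f"neighbour joining needs at least 3 taxa, got {n}")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    tree = nj(DistanceMatrix(dist, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    seed_ids = sorted(i for i in ids if origins and origins.get(i) == "seed")
    if seed_ids:
        # root on the branch above the outgroup seed leaf: seed on one side
        # of the root, everything else on the other
        return tree.root_at(tree.find(seed_ids[0]), above=True)
    return tree.root_at_midpoint()


def count_acquisition_events(tree: TreeNode, origins: dict[str, str]) -> int:
    """Number of maximal clades whose leaves are all transposon-associated."""
    leaves = list(tree.tips())
    for leaf in leaves:
        if leaf.name not in origins:
            raise ValueError(f"leaf {leaf.name!r} has no origin label")
        if origins[leaf.name] not in ORIGINS:
            raise ValueError(f"leaf {leaf.name!r} has unknown origin {origins[leaf.name]!r}")
    all_tn: dict[int, bool] = {}

    def fill(node) -> bool:
        if node.is_tip():
            val = origins[node.name] == "tn_associated"
        else:
            child_vals = [fill(c) for c in node.children]
            val = bool(child_vals) and all(child_vals)
        all_tn[id(node)] = val
        return val

    fill(tree)
    count = 0
    for node in tree.traverse(include_self=True):
        if all_tn[id(node)] and (node.parent is None or not all_tn[id(node.parent)]):
            count += 1
    return count
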