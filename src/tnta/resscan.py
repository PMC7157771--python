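"""Prediction of res/irs resolution sites near the resolvase gene.

The canonical serine-resolvase res site is a ~100-150 bp segment of three
ordered subsites (I, II, III), each an inverted-repeat pair bound by the
resolvase dimer, with subsite III proximal to the resolvase gene and
strand exchange occurring at an AT dinucleotide at the centre of subsite I.
The scanner enumerates inverted-repeat motifs in the region upstream of the
resolvase and assembles the best-scoring non-overlapping triple.

Geometry defaults (arm 8-14 bp, loop <= 14 bp, inter-subsite gap <= 60 bp,
<= 3 arm mismatches) bracket the canonical architecture; they are
parameters, not constants of nature, and can be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import revcomp
from .loci import Locus
from .orf import Hit

__all__ = [
    "IRMotif",
    "ResSite",
    "extract_search_region",
    "find_inverted_repeats",
    "assemble_res_site",
    "locate_crossover",
    "annotate_ta_adjacency",
]

RESOLVASE_ROLES = ("resolvase_S", "resolvase_Y", "resolvase_Y_het")


def _gene_interval(hit: Hit) -> tuple[int, int]:
    """Genomic interval of the exemplar-aligned part of a hit's ORF.

    ORF calls may over-extend upstream to the first in-frame start codon in
    intergenic DNA; the aligned span tracks the real gene boundary, which
    matters when clipping the res search region at neighbouring genes.
    """
    q0, q1 = hit.alignment.query_interval
    if q1 <= q0:
        return hit.orf.interval
    if hit.orf.strand == "+":
        return (hit.orf.start + 3 * q0, hit.orf.start + 3 * q1)
    return (hit.orf.end - 3 * q1, hit.orf.end - 3 * q0)


@dataclass(frozen=True)
class IRMotif:
    """An inverted repeat: two equal arms separated by a loop."""

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    mismatches: int

    @property
    def arm_len(self) -> int:
        return self.left_arm[1] - self.left_arm[0]

    @property
    def loop_len(self) -> int:
        return self.right_arm[0] - self.left_arm[1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])

    @property
    def score(self) -> int:
        return self.arm_len - self.mismatches

    def shifted(self, offset: int) -> "IRMotif":
        return IRMotif(
            (self.left_arm[0] + offset, self.left_arm[1] + offset),
            (self.right_arm[0] + offset, self.right_arm[1] + offset),
            self.mismatches,
        )


@dataclass
class ResSite:
    subsites: dict[str, IRMotif]  # keys "I", "II", "III"
    region: tuple[int, int]
    orientation: str  # "right" if the resolvase lies right of the region
    crossover: int | None = None  # genomic start of the central AT in subsite I
    ta_adjacent: bool | None = None
    partial: bool = False
    notes: list[str] = field(default_factory=list)


def extract_search_region(locus: Locus, sequence: str, window: int = 400
                          ) -> tuple[str, int]:
    """Sub-sequence upstream of the resolvase gene, with its genomic offset.

    "Upstream" is relative to the resolvase's own reading direction; for
    divergent tnpR/tnpA this is exactly the intergenic region between them,
    for colinear genes a window of up to ``window`` bp, clipped at the
    neighbouring gene. For TnpS+TnpT systems the region lies between the
    divergent resolvase and helper genes.
    """
    res_hits = locus.members_with_role(*RESOLVASE_ROLES)
    if not res_hits:
        raise ValueError("locus has no resolvase-role hit")
    res_hit = res_hits[0]
    helper = locus.members_with_role("helper")
    if res_hit.role == "resolvase_Y_het" and helper:
        a, b = sorted([res_hit, helper[0]], key=lambda h: h.orf.start)
        start, end = _gene_interval(a)[1], _gene_interval(b)[0]
    elif res_hit.orf.strand == "+":
        end = _gene_interval(res_hit)[0]
        start = max(0, end - window)
        for h in locus.members:
            neighbour_end = _gene_interval(h)[1]
            if h is not res_hit and neighbour_end <= end:
                start = max(start, neighbour_end)
    else:
        start = _gene_interval(res_hit)[1]
        end = min(len(sequence), start + window)
        for h in locus.members:
            neighbour_start = _gene_interval(h)[0]
            if h is not res_hit and neighbour_start >= start:
                end = min(end, neighbour_start)
    if end <= start:
        raise ValueError("empty res search region")
    return sequence[start:end], start


_ENC = np.zeros(128, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _ENC[ord(base)] = i
_ENC[ord("N")] = 4
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G; N handled below


def find_inverted_repeats(seq: str, arm_min: int = 8, arm_max: int = 14,
                          loop_min: int = 0, loop_max: int = 14,
                          max_mismatch: int = 3) -> list[IRMotif]:
    """All inverted-repeat motifs within the geometry bounds.

    Overlapping motifs are allowed. Sorted best first: score descending,
    then smaller span, then leftmost.
    """
    n = len(seq)
    if n < 2 * arm_min:
        raise ValueError(f"sequence of length {n} is shorter than two minimal arms")
    s = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    comp_n = 4  # N never complements anything
    comp = np.where(s == comp_n, 5, _COMP[s])
    rc = comp[::-1]
    motifs: list[IRMotif] = []
    for arm in range(arm_min, arm_max + 1):
        if 2 * arm > n:
            break
        w1 = np.lib.stride_tricks.sliding_window_view(s, arm)
        w2 = np.lib.stride_tricks.sliding_window_view(rc, arm)
        for loop in range(loop_min, loop_max + 1):
            total = 2 * arm + loop
            if total > n:
                break
            m = n - total  # last valid left-arm start
            # right arm (reversed, complemented) of a motif starting at i is
            # the window of rc starting at n - i - total
            mism = np.count_nonzero(w1[: m + 1] != w2[m::-1][: m + 1], axis=1)
            for i in np.nonzero(mism <= max_mismatch)[0]:
                motifs.append(
                    IRMotif((int(i), int(i) + arm),
                            (int(i) + arm + loop, int(i) + total),
                            int(mism[i]))
                )
    motifs.sort(key=lambda m: (-m.score, m.span[1] - m.span[0], m.span[0], m.loop_len))
    return motifs


def assemble_res_site(motifs: list[IRMotif], resolvase_start: int,
                      region: tuple[int, int], max_subsite_gap: int = 60,
                      allow_partial: bool = False) -> ResSite | None:
    """Pick three mutually non-overlapping motifs with inter-subsite gaps in
    [0, ``max_subsite_gap``] maximising total score (ties: smaller total
    span, then leftmost). The resolvase-proximal subsite is labelled III,
    the distal one I. Returns None when no triple (or pair, with
    ``allow_partial``) exists. Deterministic under motif-list permutation.
    """
    if not motifs:
        return None
    ordered = sorted(set(motifs), key=lambda m: (m.span[0], m.span[1], m.mismatches))
    starts = [m.span[0] for m in ordered]
    import bisect

    def successors(m: IRMotif) -> list[IRMotif]:
        lo = bisect.bisect_left(starts, m.span[1])
        hi = bisect.bisect_right(starts, m.span[1] + max_subsite_gap)
        return ordered[lo:hi]

    def motif_len(m: IRMotif) -> int:
        return m.span[1] - m.span[0]

    best_key = None
    best_triple = None
    for a in ordered:
        for b in successors(a):
            for c in successors(b):
                key = (-(a.score + b.score + c.score),
                       motif_len(a) + motif_len(b) + motif_len(c),
                       a.span[0], b.span[0], c.span[0])
                if best_key is None or key < best_key:
                    best_key = key
                    best_triple = (a, b, c)
    partial = False
    if best_triple is None:
        if not allow_partial:
            return None
        best_pair = None
        best_key = None
        for a in ordered:
            for b in successors(a):
                key = (-(a.score + b.score), b.span[1] - a.span[0], a.span[0])
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        if best_pair is None:
            return None
        best_triple = best_pair
        partial = True

    region_mid = (region[0] + region[1]) / 2
    orientation = "right" if resolvase_start >= region_mid else "left"
    chain = list(best_triple)  # left-to-right within the region
    labels = ["I", "II", "III"] if orientation == "right" else ["III", "II", "I"]
    if partial:
        labels = ["I", "III"] if orientation == "right" else ["III", "I"]
    shifted = [m.shifted(region[0]) for m in chain]
    subsites = dict(zip(labels, shifted))
    site = ResSite(
        subsites=subsites,
        region=(shifted[0].span[0], shifted[-1].span[1]),
        orientation=orientation,
        partial=partial,
    )
    if partial:
        site.notes.append("two-subsite partial res site")
    return site


def locate_crossover(site_i: IRMotif, sequence: str) -> int | None:
    """Genomic start of the AT dinucleotide nearest the centre of subsite I
    (ties go left). None when the span contains no AT."""
    s, e = site_i.span
    if e - s < 4:
        raise ValueError("subsite I span shorter than 4 bp")
    window = sequence[s:e]
    center = (len(window) - 2) / 2
    best = None
    for i in range(len(window) - 1):
        if window[i : i + 2] == "AT":
            d = abs(i - center)
            if best is None or d < best[0]:
                best = (d, i)
    return None if best is None else s + best[1]


def annotate_ta_adjacency(res: ResSite, locus: Locus) -> bool:
    """True iff the nearest gene on the non-resolvase side of subsite I is
    the toxin or antitoxin gene."""
    if "I" not in res.subsites:
        raise ValueError("res site has no subsite I")
    if not locus.members_with_role("toxin", "antitoxin"):
        raise ValueError("locus has no TA genes")
    site_i = res.subsites["I"]
    if res.orientation == "right":  # resolvase right of the region: look left
        candidates = [h for h in locus.members if _gene_interval(h)[1] <= site_i.span[0] + 2]
        nearest = max(candidates, key=lambda h: _gene_interval(h)[1], default=None)
    else:
        candidates = [h for h in locus.members if _gene_interval(h)[0] >= site_i.span[1] - 2]
        nearest = min(candidates, key=lambda h: _gene_interval(h)[0], default=None)
    return nearest is not None and nearest.role in ("toxin", "antitoxin")
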