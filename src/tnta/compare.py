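"""Pairwise DNA comparison between transposons.

Three views of a pair of sequences:

* exact shared words of a fixed size (dot-plot matches, default word 10);
* a sliding-window identity profile along a global alignment;
* a two-segment change-point fit on that profile, the operational statistic
  for a recombination breakpoint — a junction between a near-identical
  segment and a diverged one, as produced by intertransposon recombination
  at res site I.

Global DNA alignments use edlib (unit-cost edit distance with traceback);
identity is the fraction of identical columns, all columns counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .io import revcomp
from .loci import Locus

__all__ = [
    "MatchList",
    "IdentityProfile",
    "Breakpoint",
    "dotplot_matches",
    "identity_profile",
    "detect_breakpoint",
    "breakpoint_in_interval",
    "ta_module_identity",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class MatchList:
    wordsize: int
    matches: list[tuple[int, int, str]]  # (posA, posB, strand)


@dataclass
class IdentityProfile:
    window: int
    step: int
    centers: np.ndarray  # positions on sequence A
    identity: np.ndarray  # fraction in [0, 1] per window


@dataclass
class Breakpoint:
    position: float  # coordinate on sequence A
    left_identity: float
    right_identity: float
    confidence_interval: tuple[float, float]
    in_res_site_I: bool | None = None


def dotplot_matches(seq_a: str, seq_b: str, wordsize: int = 10) -> MatchList:
    """Every exact shared word of length ``wordsize``, both orientations.

    A reverse-strand match (posA, posB, "-") means the word at posA in A
    equals the reverse complement of the word starting at posB in B.
    """
    if len(seq_a) < wordsize or len(seq_b) < wordsize:
        raise ValueError("sequences must be at least one word long")
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - wordsize + 1):
        index.setdefault(seq_b[j : j + wordsize], []).append(j)
    matches: list[tuple[int, int, str]] = []
    for i in range(len(seq_a) - wordsize + 1):
        word = seq_a[i : i + wordsize]
        for j in index.get(word, ()):
            matches.append((i, j, "+"))
        rc = revcomp(word)
        for j in index.get(rc, ()):
            matches.append((i, j, "-"))
    return MatchList(wordsize=wordsize, matches=matches)


def _global_alignment_columns(seq_a: str, seq_b: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (A coordinate, is-match) arrays of a global alignment."""
    result = edlib.align(seq_a, seq_b, mode="NW", task="path")
    a_pos: list[int] = []
    match: list[bool] = []
    ia = 0
    for count, op in _CIGAR_RE.findall(result["cigar"]):
        count = int(count)
        if op == "=":
            a_pos.extend(range(ia, ia + count))
            match.extend([True] * count)
            ia += count
        elif op == "X":
            a_pos.extend(range(ia, ia + count))
            match.extend([False] * count)
            ia += count
        elif op == "I":  # gap in B: advances A only
            a_pos.extend(range(ia, ia + count))
            match.extend([False] * count)
            ia += count
        else:  # "D", gap in A: columns charged to the current A position
            a_pos.extend([min(ia, len(seq_a) - 1)] * count)
            match.extend([False] * count)
    return np.asarray(a_pos), np.asarray(match, dtype=bool)


def identity_profile(seq_a: str, seq_b: str, window: int = 100, step: int = 10
                     ) -> IdentityProfile:
    """Fraction of identical alignment columns per window centred on
    A-coordinates (windows every ``step`` bp, ``window`` bp wide)."""
    if len(seq_a) < window:
        raise ValueError("sequence A shorter than one window")
    a_pos, match = _global_alignment_columns(seq_a, seq_b)
    n = len(seq_a)
    cols_at = np.bincount(a_pos, minlength=n).astype(float)
    match_at = np.bincount(a_pos, weights=match.astype(float), minlength=n)
    cum_cols = np.concatenate([[0.0], np.cumsum(cols_at)])
    cum_match = np.concatenate([[0.0], np.cumsum(match_at)])
    half = window // 2
    centers = np.arange(half, n - window + half + 1, step)
    if len(centers) == 0:
        raise ValueError("degenerate alignment: fewer than one window")
    lo = centers - half
    hi = lo + window
    cols = cum_cols[hi] - cum_cols[lo]
    matches = cum_match[hi] - cum_match[lo]
    with np.errstate(invalid="ignore"):
        identity = np.where(cols > 0, matches / np.maximum(cols, 1.0), 0.0)
    return IdentityProfile(window=window, step=step,
                           centers=centers.astype(float), identity=identity)


def detect_breakpoint(profile: IdentityProfile, high: float = 0.95,
                      low: float = 0.85) -> Breakpoint | None:
    """Least-squares two-segment change-point on the identity profile.

    The split minimising total squared deviation from per-segment means is
    reported only when one segment's mean identity is >= ``high`` and the
    other's <= ``low``. The confidence interval covers split positions whose
    fit cost is within 5% of the optimum.
    """
    y = np.asarray(profile.identity, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError(f"profile has {n} windows; need at least 10")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    ks = np.arange(1, n)
    left_n = ks.astype(float)
    right_n = (n - ks).astype(float)
    left_sum, left_sq = c1[ks], c2[ks]
    right_sum, right_sq = c1[n] - c1[ks], c2[n] - c2[ks]
    cost = (left_sq - left_sum**2 / left_n) + (right_sq - right_sum**2 / right_n)
    best = int(np.argmin(cost))
    k = ks[best]
    m_left = left_sum[best] / left_n[best]
    m_right = right_sum[best] / right_n[best]
    hi_mean, lo_mean = max(m_left, m_right), min(m_left, m_right)
    if not (hi_mean >= high and lo_mean <= low):
        return None
    opt = cost[best]
    tol = opt * 1.05 if opt > 0 else 1e-12
    ok = np.nonzero(cost <= tol)[0]
    positions = (profile.centers[ks - 1] + profile.centers[ks]) / 2.0
    return Breakpoint(
        position=float(positions[best]),
        left_identity=float(m_left),
        right_identity=float(m_right),
        confidence_interval=(float(positions[ok].min()), float(positions[ok].max())),
    )


def breakpoint_in_interval(bp: Breakpoint, interval: tuple[int, int],
                           window: int, step: int) -> bool:
    """Whether the breakpoint falls in a genomic interval (e.g. res subsite
    I), at the profile's intrinsic resolution of ±(window/2 + step)."""
    slack = window / 2 + step
    lo = min(bp.confidence_interval[0], bp.position - slack)
    hi = max(bp.confidence_interval[1], bp.position + slack)
    return lo <= interval[1] and interval[0] <= hi


def ta_module_identity(locus_a: Locus, seq_a: str, locus_b: Locus, seq_b: str) -> float:
    """Global percent DNA identity over the TA-module spans (toxin start to
    antitoxin end, or the reverse) of two loci."""
    spans = []
    for locus in (locus_a, locus_b):
        ta = locus.members_with_role("toxin", "antitoxin")
        if not any(h.role == "toxin" for h in ta) or not any(h.role == "antitoxin" for h in ta):
            raise ValueError(f"locus on {locus.seq_id} lacks a complete TA pair")
        spans.append((min(h.orf.start for h in ta), max(h.orf.end for h in ta)))
    sub_a = seq_a[spans[0][0] : spans[0][1]]
    sub_b = seq_b[spans[1][0] : spans[1][1]]
    _, match = _global_alignment_columns(sub_a, sub_b)
    return 100.0 * float(match.mean())
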