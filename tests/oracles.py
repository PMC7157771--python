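"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive (quadratic/cubic loops, no shared
code with the package) so it can serve as ground truth for the optimised
implementations.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def smith_waterman_affine(query: str, ref: str, score, gap_open: float,
                          gap_extend: float) -> float:
    """Exhaustive affine-gap local alignment score.

    A gap of length L costs gap_open + L * gap_extend (first gap residue
    charged gap_open + gap_extend).
    """
    n, m = len(query), len(ref)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes query)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes ref)
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            s = score(query[i - 1], ref[j - 1])
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def six_frame_orfs(seq: str, min_aa: int, starts=("ATG", "GTG", "TTG"),
                   stops=("TAA", "TAG", "TGA")) -> set[tuple[int, int, str]]:
    """Coordinates (start, end, strand) of ORFs: first start after each
    in-frame stop through the stop codon (complete ORFs only)."""
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            start_at = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon in stops:
                    if start_at is not None:
                        length_aa = (i - start_at) // 3
                        if length_aa >= min_aa and "N" not in s[start_at : i + 3]:
                            if strand == "+":
                                found.add((start_at, i + 3, "+"))
                            else:
                                found.add((n - (i + 3), n - start_at, "-"))
                    start_at = None
                elif start_at is None and codon in starts:
                    start_at = i
    return found


def inverted_repeats(seq: str, arm_min: int, arm_max: int, loop_min: int,
                     loop_max: int, max_mismatch: int) -> set[tuple]:
    """All (left_start, left_end, right_start, right_end, mismatches)."""
    out = set()
    n = len(seq)
    for arm in range(arm_min, arm_max + 1):
        for loop in range(loop_min, loop_max + 1):
            total = 2 * arm + loop
            for i in range(n - total + 1):
                left = seq[i : i + arm]
                right = seq[i + arm + loop : i + total]
                mm = sum(a != b for a, b in zip(left, revcomp(right)))
                if mm <= max_mismatch:
                    out.add((i, i + arm, i + arm + loop, i + total, mm))
    return out


def shared_words(seq_a: str, seq_b: str, w: int) -> set[tuple[int, int, str]]:
    out = set()
    for i in range(len(seq_a) - w + 1):
        wa = seq_a[i : i + w]
        for j in range(len(seq_b) - w + 1):
            wb = seq_b[j : j + w]
            if wa == wb:
                out.add((i, j, "+"))
            if wa == revcomp(wb):
                out.add((i, j, "-"))
    return out


def single_linkage_partition(intervals: list[tuple[int, int]], max_gap: int
                             ) -> list[set[int]]:
    """Union-find over intervals: i~j iff gap between them <= max_gap."""
    parent = list(range(len(intervals)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if i < j:
                gap = max(s2 - e1, s1 - e2)
                if gap <= max_gap:
                    union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: min(g))
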