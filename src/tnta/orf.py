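"""ORF calling and translated homology screening.

The screen follows the published detection rule: six-frame ORFs are aligned
(Smith-Waterman, BLOSUM62, gap open 11 / extend 1) against the exemplar
library, and a match is kept when percent identity exceeds 40 and alignment
coverage of the reference is at least 60% — the thresholds under which
candidate Tn3 transposition-module regions are retrieved.

Conventions, stated so the numbers are reproducible:

* identity denominator = all alignment columns, gap columns included;
* coverage = aligned reference span / reference length;
* a gap of length L costs ``gap_open + L * gap_extend``;
* "similarity above 40%" is a strict ``>``, coverage is ``>=``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import SeqRecord, revcomp
from .reference import RefLibrary, RefProtein

__all__ = [
    "Orf",
    "Alignment",
    "Hit",
    "find_orfs",
    "align_protein",
    "screen_sequence",
    "START_CODONS",
]

START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class Orf:
    seq_id: str
    start: int  # 0-based half-open nucleotide coords on the forward strand
    end: int
    strand: str
    frame: int  # 0..2, on the ORF's own strand
    aa_sequence: str  # stop excluded
    partial: bool = False  # runs off the contig end without a stop

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Alignment:
    score: float
    identity_pct: float
    coverage_pct: float
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]


@dataclass
class Hit:
    """A screened homology match between an ORF and a reference exemplar."""

    orf: Orf
    ref_id: str
    role: str
    alignment: Alignment
    family: str | None = None
    superfamily: str | None = None
    subgroup: str | None = None
    truncated: bool = False  # passed identity but not coverage (toxin rescue)
    attributes: dict = field(default_factory=dict)


def _scan_strand(seq: str, seq_id: str, strand: str, length: int, min_aa: int,
                 table: CodonTable.CodonTable) -> list[Orf]:
    stops = set(table.stop_codons)
    orfs = []
    n = len(seq)
    for frame in range(3):
        start_pos: int | None = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in stops:
                if start_pos is not None:
                    orfs.extend(
                        _make_orf(seq, seq_id, strand, length, start_pos, i + 3, frame,
                                  min_aa, partial=False)
                    )
                start_pos = None
            elif start_pos is None and codon in START_CODONS:
                start_pos = i
            i += 3
        if start_pos is not None:  # ran off the end without a stop
            end = start_pos + ((n - start_pos) // 3) * 3
            orfs.extend(
                _make_orf(seq, seq_id, strand, length, start_pos, end, frame,
                          min_aa, partial=True)
            )
    return orfs


def _make_orf(seq, seq_id, strand, length, s, e, frame, min_aa, partial):
    nt = seq[s:e]
    if "N" in nt:  # ambiguous codons are skipped, not guessed
        return []
    aa = str(Seq(nt[: e - s - (0 if partial else 3)]).translate(table=11))
    # the initiator is reported as Met regardless of start codon
    if aa:
        aa = "M" + aa[1:]
    if len(aa) < min_aa:
        return []
    if strand == "+":
        start, end = s, e
    else:
        start, end = length - e, length - s
    return [Orf(seq_id=seq_id, start=start, end=end, strand=strand, frame=frame,
                aa_sequence=aa, partial=partial)]


def find_orfs(record: SeqRecord, min_aa: int = 80, genetic_code: int = 11) -> list[Orf]:
    """Six-frame ORF scan: first start codon (ATG/GTG/TTG) after each in-frame
    stop, through the next stop (or the contig end, flagged partial).

    Nested ORFs sharing a stop report only the longest (the first start).
    ORFs whose span contains an N are skipped. Sorted by (start, strand).
    """
    if len(record) < 3:
        return []
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    length = len(record)
    orfs = _scan_strand(record.sequence, record.id, "+", length, min_aa, table)
    orfs += _scan_strand(revcomp(record.sequence), record.id, "-", length, min_aa, table)
    return sorted(orfs, key=lambda o: (o.start, o.strand))


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner's open score is charged to the first gap position, so a
    # gap of length L costs open + (L-1)*extend; shift to get open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_protein(query: str, ref: str, matrix: str = "BLOSUM62",
                  gap_open: float = 11.0, gap_extend: float = 1.0) -> Alignment:
    """Optimal local (Smith-Waterman) protein alignment.

    identity_pct = identities / alignment columns (gaps included) x 100;
    coverage_pct = aligned reference span / reference length x 100.
    """
    if not query or not ref:
        raise ValueError("align_protein requires non-empty sequences")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query, ref)
    try:
        best = alignments[0]
    except IndexError:
        return Alignment(0.0, 0.0, 0.0, (0, 0), (0, 0))
    score = float(best.score)
    if score <= 0:
        return Alignment(max(score, 0.0), 0.0, 0.0, (0, 0), (0, 0))
    coords = best.coordinates
    q_coords, r_coords = coords[0], coords[1]
    identities = 0
    columns = 0
    for k in range(len(q_coords) - 1):
        dq = int(q_coords[k + 1] - q_coords[k])
        dr = int(r_coords[k + 1] - r_coords[k])
        columns += max(dq, dr)
        if dq and dr:  # aligned block
            qs, rs = int(q_coords[k]), int(r_coords[k])
            identities += sum(
                1 for i in range(dq) if query[qs + i] == ref[rs + i]
            )
    ref_span = int(r_coords[-1] - r_coords[0])
    identity_pct = 100.0 * identities / columns if columns else 0.0
    coverage_pct = 100.0 * ref_span / len(ref)
    return Alignment(
        score=score,
        identity_pct=identity_pct,
        coverage_pct=coverage_pct,
        query_interval=(int(q_coords[0]), int(q_coords[-1])),
        ref_interval=(int(r_coords[0]), int(r_coords[-1])),
    )


def screen_sequence(record: SeqRecord, lib: RefLibrary, min_identity: float = 40.0,
                    min_coverage: float = 60.0, min_aa: int = 80,
                    rescue_truncated: bool = True,
                    truncated_min_coverage: float = 25.0) -> list[Hit]:
    """Screen one sequence against the exemplar library.

    Every (ORF, exemplar) pair with identity > ``min_identity`` and reference
    coverage >= ``min_coverage`` yields a Hit. With ``rescue_truncated``,
    toxin matches whose coverage lands in [truncated_min_coverage,
    min_coverage) are kept flagged ``truncated`` — interrupted toxin genes
    sit below the coverage cut but still mark a TA module.
    """
    orfs = find_orfs(record, min_aa=min_aa)
    hits: list[Hit] = []
    for orf in orfs:
        q_len = len(orf.aa_sequence)
        for ref in lib.proteins:
            floor = truncated_min_coverage if (rescue_truncated and ref.role == "toxin") \
                else min_coverage
            # a reference span can exceed the query length only through gaps;
            # 1.5x is a safe impossibility bound used purely to skip work
            if q_len * 1.5 < floor / 100.0 * len(ref.aa_sequence):
                continue
            aln = align_protein(orf.aa_sequence, ref.aa_sequence)
            if aln.identity_pct <= min_identity:
                continue
            if aln.coverage_pct >= min_coverage:
                hits.append(_hit(orf, ref, aln, truncated=False))
            elif (rescue_truncated and ref.role == "toxin"
                  and aln.coverage_pct >= truncated_min_coverage):
                hits.append(_hit(orf, ref, aln, truncated=True))
    return hits


def _hit(orf: Orf, ref: RefProtein, aln: Alignment, truncated: bool) -> Hit:
    return Hit(
        orf=orf,
        ref_id=ref.id,
        role=ref.role,
        alignment=aln,
        family=ref.family,
        superfamily=ref.superfamily,
        subgroup=ref.subgroup,
        truncated=truncated,
    )
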