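"""End-to-end genome scan: ORFs -> homology screen -> loci -> res sites.

`scan_genome` is the one-call surface behind the ``tnta scan`` command and
the basis of the recovery benchmarks: it returns each candidate
transposition module with its configuration string, completeness call,
subgroup, resolvase type, TA gene order and (when found) predicted res
site with crossover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import FeatureRow, SeqRecord
from .loci import (Locus, classify_configuration, classify_ta_order,
                   cluster_hits, select_best_hits)
from .orf import find_orfs, screen_sequence
from .reference import RefLibrary
from .resscan import (ResSite, annotate_ta_adjacency, assemble_res_site,
                      extract_search_region, find_inverted_repeats,
                      locate_crossover)

__all__ = ["ScanResult", "scan_genome", "loci_table_rows", "result_features"]

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    locus: Locus
    res_site: ResSite | None = None
    notes: list[str] = field(default_factory=list)


def scan_genome(record: SeqRecord, library: RefLibrary,
                min_identity: float = 40.0, min_coverage: float = 60.0,
                max_gap: int = 2000, min_aa: int = 80,
                scan_res: bool = True, allow_partial_res: bool = False
                ) -> list[ScanResult]:
    hits = screen_sequence(record, library, min_identity=min_identity,
                           min_coverage=min_coverage, min_aa=min_aa)
    if not hits:
        return []
    best = _filter_truncated(select_best_hits(hits))
    loci = cluster_hits(best, max_gap=max_gap)
    rescued = _rescue_short_truncated_toxins(record, loci, library, min_identity)
    if rescued:
        best = select_best_hits(best + rescued)
        loci = cluster_hits(best, max_gap=max_gap)
    orfs = find_orfs(record, min_aa=min_aa)
    results = []
    for locus in loci:
        result = ScanResult(locus=locus)
        if scan_res and locus.members_with_role(
            "resolvase_S", "resolvase_Y", "resolvase_Y_het"
        ):
            try:
                result.res_site = _scan_res(locus, record.sequence, allow_partial_res)
            except ValueError as exc:
                result.notes.append(f"res scan failed: {exc}")
        if result.res_site is not None and locus.members_with_role("toxin", "antitoxin"):
            result.res_site.ta_adjacent = annotate_ta_adjacency(result.res_site, locus)
        locus.configuration = classify_configuration(locus, res=result.res_site,
                                                     extra_orfs=orfs)
        locus.ta_order = classify_ta_order(locus.configuration)
        results.append(result)
    return results


#: a truncated toxin is only credible next to its intact antitoxin partner —
#: TA genes form an adjacent two-gene operon in every catalogued arrangement
TA_PARTNER_GAP = 1000


def _filter_truncated(hits):
    antitoxins = [h for h in hits if h.role == "antitoxin"]

    def near_antitoxin(hit):
        return any(
            hit.orf.start - a.orf.end <= TA_PARTNER_GAP
            and a.orf.start - hit.orf.end <= TA_PARTNER_GAP
            for a in antitoxins
        )

    return [h for h in hits if not h.truncated or near_antitoxin(h)]


def _rescue_short_truncated_toxins(record: SeqRecord, loci, library: RefLibrary,
                                   min_identity: float,
                                   min_aa: int = 25,
                                   min_coverage: float = 25.0):
    """Second-pass search for interrupted toxin genes.

    A toxin gene broken by an internal stop leaves a fragment too short for
    the main ORF floor. For loci that carry an antitoxin but no toxin, the
    neighbourhood of the antitoxin is re-scanned with a low ORF floor
    against toxin exemplars only; matches are flagged truncated.
    """
    from .orf import Hit, align_protein

    rescued: list[Hit] = []
    toxin_refs = library.by_role("toxin")
    for locus in loci:
        antitoxins = locus.members_with_role("antitoxin")
        if not antitoxins or locus.members_with_role("toxin"):
            continue
        lo = max(0, min(a.orf.start for a in antitoxins) - TA_PARTNER_GAP)
        hi = min(len(record.sequence), max(a.orf.end for a in antitoxins) + TA_PARTNER_GAP)
        sub = SeqRecord(id=record.id, sequence=record.sequence[lo:hi])
        candidates: list[Hit] = []
        for orf in find_orfs(sub, min_aa=min_aa):
            start, end = orf.start + lo, orf.end + lo
            if any(start < h.orf.end and h.orf.start < end for h in locus.members):
                continue
            shifted = replace_orf_coords(orf, start, end)
            for ref in toxin_refs:
                aln = align_protein(orf.aa_sequence, ref.aa_sequence)
                if aln.identity_pct > min_identity and aln.coverage_pct >= min_coverage:
                    candidates.append(Hit(orf=shifted, ref_id=ref.id, role="toxin",
                                          alignment=aln, family=ref.family,
                                          superfamily=ref.superfamily, truncated=True))
        if candidates:
            # one gene may shatter into several matching fragments; report
            # only the strongest as the interrupted toxin
            rescued.append(max(candidates, key=lambda h: h.alignment.score))
    return rescued


def replace_orf_coords(orf, start: int, end: int):
    from dataclasses import replace
    return replace(orf, start=start, end=end)


def _scan_res(locus: Locus, sequence: str, allow_partial: bool) -> ResSite | None:
    region_seq, offset = extract_search_region(locus, sequence)
    try:
        motifs = find_inverted_repeats(region_seq)
    except ValueError:
        return None
    from .resscan import _gene_interval

    resolvase = locus.members_with_role("resolvase_S", "resolvase_Y", "resolvase_Y_het")[0]
    site = assemble_res_site(motifs, _gene_interval(resolvase)[0],
                             (offset, offset + len(region_seq)),
                             allow_partial=allow_partial)
    if site is not None and "I" in site.subsites:
        site.crossover = locate_crossover(site.subsites["I"], sequence)
    return site


def loci_table_rows(results: list[ScanResult]) -> list[dict]:
    rows = []
    for r in results:
        locus = r.locus
        toxin = next(iter(locus.members_with_role("toxin")), None)
        antitoxin = next(iter(locus.members_with_role("antitoxin")), None)
        rows.append(
            {
                "seq_id": locus.seq_id,
                "start": locus.span[0],
                "end": locus.span[1],
                "configuration": str(locus.configuration),
                "completeness": locus.completeness,
                "subgroup": locus.subgroup or ".",
                "resolvase_type": locus.resolvase_type,
                "ta_order": locus.ta_order,
                "toxin_family": toxin.family if toxin else ".",
                "antitoxin_family": antitoxin.family if antitoxin else ".",
                "res_site": "yes" if r.res_site else "no",
                "notes": ";".join(locus.notes + r.notes) or ".",
            }
        )
    return rows


LOCI_COLUMNS = ["seq_id", "start", "end", "configuration", "completeness", "subgroup",
                "resolvase_type", "ta_order", "toxin_family", "antitoxin_family",
                "res_site", "notes"]


def result_features(results: list[ScanResult]) -> list[FeatureRow]:
    """GFF3-ready features: one per member gene, plus res subsites and the
    crossover AT."""
    features = []
    for r in results:
        locus = r.locus
        for hit in locus.members:
            features.append(
                FeatureRow(locus.seq_id, hit.orf.start, hit.orf.end, hit.orf.strand,
                           hit.role, {"ref_id": hit.ref_id,
                                      "identity": f"{hit.alignment.identity_pct:.1f}",
                                      "coverage": f"{hit.alignment.coverage_pct:.1f}"})
            )
        if r.res_site is not None:
            for label, motif in r.res_site.subsites.items():
                features.append(FeatureRow(locus.seq_id, motif.span[0], motif.span[1],
                                           "+", f"res_subsite_{label}", {}))
            features.append(FeatureRow(locus.seq_id, *r.res_site.region, "+",
                                       "res_site", {}))
            if r.res_site.crossover is not None:
                features.append(FeatureRow(locus.seq_id, r.res_site.crossover,
                                           r.res_site.crossover + 2, "+",
                                           "crossover_AT", {}))
    return features
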