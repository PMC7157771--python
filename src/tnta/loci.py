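"""Clustering hits into candidate transposition modules.

A locus is a single-linkage chain of screened hits whose consecutive
genomic gaps are at most 2,000 bp — the proximity rule under which
candidate regions are retrieved. Each locus is rendered as an arrow-notation
configuration string, e.g. ``<T <A tnpR> tnpA>``: tokens run left to right
in genomic order, ``NAME>`` is a gene on the plus strand, ``<NAME`` on the
minus strand, and ``!res!`` marks the resolution site when it falls between
genes. ``T``/``A`` are the toxin/antitoxin genes, ``X`` an unclassified ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .orf import Hit, Orf

__all__ = [
    "ConfigString",
    "Locus",
    "ROLE_TOKEN",
    "select_best_hits",
    "cluster_hits",
    "classify_configuration",
    "classify_ta_order",
    "assess_completeness",
    "assign_subgroup",
]

logger = logging.getLogger(__name__)

ROLE_TOKEN = {
    "toxin": "T",
    "antitoxin": "A",
    "transposase": "tnpA",
    "resolvase_S": "tnpR",
    "resolvase_Y": "tnpI",
    "resolvase_Y_het": "tnpS",
    "helper": "tnpT",
}
_GENE_NAMES = set(ROLE_TOKEN.values()) | {"T", "A", "X"}
RES_MARKER = "!res!"


@dataclass(frozen=True)
class ConfigString:
    """Parsed arrow-notation gene arrangement."""

    tokens: tuple[tuple[str, str | None], ...]  # (name, strand) — strand None for !res!

    @staticmethod
    def parse(text: str) -> "ConfigString":
        tokens = []
        for raw in text.split():
            if raw == RES_MARKER:
                tokens.append((RES_MARKER, None))
            elif raw.startswith("<") and not raw.endswith(">"):
                tokens.append((raw[1:], "-"))
            elif raw.endswith(">") and not raw.startswith("<"):
                tokens.append((raw[:-1], "+"))
            else:
                raise ValueError(f"malformed configuration token {raw!r} in {text!r}")
        for name, strand in tokens:
            if strand is not None and name not in _GENE_NAMES:
                raise ValueError(f"unknown gene name {name!r} in {text!r}")
        return ConfigString(tuple(tokens))

    def render(self) -> str:
        parts = []
        for name, strand in self.tokens:
            if strand is None:
                parts.append(RES_MARKER)
            elif strand == "-":
                parts.append(f"<{name}")
            else:
                parts.append(f"{name}>")
        return " ".join(parts)

    def mirror(self) -> "ConfigString":
        """Reverse token order and flip strands (reverse-complement view)."""
        flipped = []
        for name, strand in reversed(self.tokens):
            flipped.append((name, None if strand is None else ("+" if strand == "-" else "-")))
        return ConfigString(tuple(flipped))

    def gene_tokens(self) -> list[tuple[str, str]]:
        return [(n, s) for n, s in self.tokens if s is not None]

    def __str__(self) -> str:
        return self.render()


@dataclass
class Locus:
    seq_id: str
    members: list[Hit]  # one per ORF, sorted by start
    span: tuple[int, int] = (0, 0)
    configuration: ConfigString | None = None
    completeness: str = "partial"
    missing_roles: list[str] = field(default_factory=list)
    subgroup: str | None = None
    resolvase_type: str = "none"
    ta_order: str = "absent"
    notes: list[str] = field(default_factory=list)

    def members_with_role(self, *roles: str) -> list[Hit]:
        return [h for h in self.members if h.role in roles]


def select_best_hits(hits: list[Hit]) -> list[Hit]:
    """At most one hit per ORF: max score, ties by identity, then smallest
    ref_id. Deterministic under any input permutation."""
    best: dict[tuple, Hit] = {}
    for hit in hits:
        key = (hit.orf.seq_id, hit.orf.start, hit.orf.end, hit.orf.strand)
        cur = best.get(key)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[key] = hit
    return sorted(best.values(), key=lambda h: (h.orf.start, h.orf.strand, h.ref_id))


def _hit_rank(hit: Hit) -> tuple:
    return (-hit.alignment.score, -hit.alignment.identity_pct, hit.ref_id)


def cluster_hits(hits: list[Hit], max_gap: int = 2000) -> list[Locus]:
    """Single-linkage interval clustering: consecutive sorted hits join a
    locus iff the gap (next.start − running max end) is <= ``max_gap``."""
    if not hits:
        return []
    seq_ids = {h.orf.seq_id for h in hits}
    if len(seq_ids) != 1:
        raise ValueError(f"cluster_hits requires hits from one sequence, got {sorted(seq_ids)}")
    ordered = sorted(hits, key=lambda h: (h.orf.start, h.orf.end))
    loci: list[Locus] = []
    current: list[Hit] = [ordered[0]]
    reach = ordered[0].orf.end
    for hit in ordered[1:]:
        if hit.orf.start - reach <= max_gap:
            current.append(hit)
        else:
            loci.append(_build_locus(current))
            current = [hit]
        reach = max(reach, hit.orf.end)
    loci.append(_build_locus(current))
    return sorted(loci, key=lambda l: l.span[0])


def _build_locus(members: list[Hit]) -> Locus:
    members = sorted(members, key=lambda h: h.orf.start)
    locus = Locus(
        seq_id=members[0].orf.seq_id,
        members=members,
        span=(min(h.orf.start for h in members), max(h.orf.end for h in members)),
    )
    locus.subgroup = assign_subgroup(locus)
    locus.resolvase_type = _resolvase_type(locus)
    locus.configuration = classify_configuration(locus)
    locus.completeness, locus.missing_roles, notes = assess_completeness(locus)
    locus.notes.extend(notes)
    locus.ta_order = classify_ta_order(locus.configuration)
    return locus


def _resolvase_type(locus: Locus) -> str:
    roles = {h.role for h in locus.members}
    if {"resolvase_Y_het", "helper"} & roles:
        return "S/T"
    if "resolvase_S" in roles:
        return "R"
    if "resolvase_Y" in roles:
        return "I"
    return "none"


def classify_configuration(locus: Locus, res=None, extra_orfs: list[Orf] | None = None
                           ) -> ConfigString:
    """Render the locus as a configuration string.

    ``res`` (a ResSite) inserts a ``!res!`` marker when its region falls
    between member genes; ``extra_orfs`` are unclassified ORFs rendered as
    ``X`` tokens when they lie between classified members.
    """
    items: list[tuple[int, str, str | None]] = []
    for hit in locus.members:
        items.append((hit.orf.start, ROLE_TOKEN[hit.role], hit.orf.strand))
    if extra_orfs and len(locus.members) >= 2:
        lo = min(h.orf.start for h in locus.members)
        hi = max(h.orf.end for h in locus.members)
        member_keys = {(h.orf.start, h.orf.end, h.orf.strand) for h in locus.members}
        for orf in extra_orfs:
            if (orf.start, orf.end, orf.strand) in member_keys:
                continue
            if orf.start >= lo and orf.end <= hi and not any(
                orf.start < h.orf.end and h.orf.start < orf.end for h in locus.members
            ):
                items.append((orf.start, "X", orf.strand))
    items.sort(key=lambda t: t[0])
    if res is not None:
        res_start = res.region[0]
        insert_at = len(items)
        for i, (start, _, _) in enumerate(items):
            if res_start < start:
                insert_at = i
                break
        if 0 < insert_at < len(items):  # only marked when it falls between genes
            items.insert(insert_at, (res_start, RES_MARKER, None))
    return ConfigString(tuple((name, strand) for _, name, strand in items))


def classify_ta_order(config: ConfigString) -> str:
    """normal / reversed / undetermined / absent, by transcription order.

    Considering only the T and A tokens: co-oriented pairs are read in
    transcription order (leftmost first on +/+, rightmost first on −/−);
    antitoxin-first is the common ("normal") arrangement, toxin-first the
    reversed one. Opposite strands, single genes, or multiple copies are
    undetermined.
    """
    ta = [(n, s) for n, s in config.gene_tokens() if n in ("T", "A")]
    names = [n for n, _ in ta]
    if not ta:
        return "absent"
    if names.count("T") != 1 or names.count("A") != 1:
        return "undetermined"
    (n1, s1), (n2, s2) = ta
    if s1 != s2:
        return "undetermined"
    first = n1 if s1 == "+" else n2
    return "normal" if first == "A" else "reversed"


def assess_completeness(locus: Locus) -> tuple[str, list[str], list[str]]:
    """full_with_TA / full_no_TA / partial, plus missing roles and notes.

    A toxin matched only through the truncated-coverage rescue (or covering
    under half of its reference) is annotated ``truncated_toxin`` — the gene
    is interrupted but still marks a TA module.
    """
    roles = {h.role for h in locus.members}
    has_resolvase = bool(roles & {"resolvase_S", "resolvase_Y", "resolvase_Y_het"})
    has_tnpa = "transposase" in roles
    has_toxin = "toxin" in roles
    has_antitoxin = "antitoxin" in roles
    notes = []
    for hit in locus.members_with_role("toxin"):
        if hit.truncated or hit.alignment.coverage_pct < 50.0:
            notes.append("truncated_toxin")
            break
    missing = []
    if not has_tnpa:
        missing.append("transposase")
    if not has_resolvase:
        missing.append("resolvase")
    if not has_toxin:
        missing.append("toxin")
    if not has_antitoxin:
        missing.append("antitoxin")
    if has_tnpa and has_resolvase and has_toxin and has_antitoxin:
        return "full_with_TA", [], notes
    if has_tnpa and has_resolvase and not has_toxin and not has_antitoxin:
        return "full_no_TA", missing, notes
    return "partial", missing, notes


def assign_subgroup(locus: Locus) -> str | None:
    """Subgroup label propagated from the best-scoring transposase hit."""
    tnpa_hits = locus.members_with_role("transposase")
    if not tnpa_hits:
        return None
    return min(tnpa_hits, key=_hit_rank).subgroup
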