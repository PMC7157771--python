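"""The labeled exemplar-protein library used for homology screening.

A library is a protein FASTA plus a TSV metadata table mapping each id to a
role (transposase, resolvase, toxin, antitoxin, ...), a TA family and
superfamily, and — for transposases — a Tn3-family subgroup. Downstream
family assignment is best-hit against these exemplars, so everything the
pipeline reports is a pure function of the library content.

The bundled default library is a deterministic *synthetic* stand-in for the
curated exemplar sets (TADB toxins/antitoxins, ISfinder transposases and
resolvases) that seeded the original screens; see
``scripts/make_reference_library.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import io as tio

__all__ = [
    "RefProtein",
    "RefLibrary",
    "ROLES",
    "SUBGROUPS",
    "load_reference_library",
    "validate_reference_library",
    "bundled_library_path",
]

ROLES = {
    "transposase",
    "resolvase_S",  # serine resolvase, TnpR
    "resolvase_Y",  # tyrosine resolvase, TnpI
    "resolvase_Y_het",  # tyrosine recombinase of the heteromeric system, TnpS
    "helper",  # TnpT
    "toxin",
    "antitoxin",
}

#: TnpA-based clades of the Tn3 family.
SUBGROUPS = {"Tn3", "Tn21", "Tn163", "IS1071", "IS3000", "Tn4430", "Tn4651", "Tn3000"}

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class RefProtein:
    id: str
    role: str
    aa_sequence: str
    family: str | None = None
    superfamily: str | None = None
    subgroup: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)


@dataclass
class RefLibrary:
    proteins: list[RefProtein]
    version: str = "unversioned"

    def by_role(self, role: str) -> list[RefProtein]:
        return [p for p in self.proteins if p.role == role]

    def get(self, ref_id: str) -> RefProtein:
        for p in self.proteins:
            if p.id == ref_id:
                return p
        raise KeyError(ref_id)


def bundled_library_path() -> Path:
    """Directory of the packaged synthetic exemplar library."""
    return Path(resources.files("tnta").joinpath("data", "reference"))


def load_reference_library(path: str | Path | None = None) -> RefLibrary:
    """Load a library directory (protein FASTA files + ``metadata.tsv``).

    With ``path=None`` the bundled synthetic default library is loaded.
    Raises ValueError listing ids present in only one of FASTA/metadata.
    """
    path = Path(path) if path is not None else bundled_library_path()
    meta_path = path / "metadata.tsv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.tsv in library directory {path}")
    meta_rows = tio.read_table(meta_path)

    sequences: dict[str, str] = {}
    for fasta in sorted(path.glob("*.faa")) + sorted(path.glob("*.fasta")):
        for rec in tio.read_sequences(fasta, fmt="fasta"):
            sequences[rec.id] = rec.sequence

    meta_ids = {row["id"] for row in meta_rows}
    missing_seq = sorted(meta_ids - set(sequences))
    missing_meta = sorted(set(sequences) - meta_ids)
    if missing_seq or missing_meta:
        raise ValueError(
            "library FASTA/metadata mismatch; "
            f"metadata without sequence: {missing_seq}; sequence without metadata: {missing_meta}"
        )

    core = {"id", "role", "family", "superfamily", "subgroup"}
    proteins = []
    for row in meta_rows:
        extra = {k: v for k, v in row.items() if k not in core and v not in ("", ".")}
        proteins.append(
            RefProtein(
                id=row["id"],
                role=row["role"],
                aa_sequence=sequences[row["id"]],
                family=row.get("family") or None if row.get("family") not in (".", "") else None,
                superfamily=row.get("superfamily") or None
                if row.get("superfamily") not in (".", "")
                else None,
                subgroup=row.get("subgroup") or None
                if row.get("subgroup") not in (".", "")
                else None,
                attributes=extra,
            )
        )
    version = (path / "VERSION").read_text().strip() if (path / "VERSION").exists() else "unversioned"
    return RefLibrary(proteins=proteins, version=version)


def validate_reference_library(lib: RefLibrary) -> list[str]:
    """Check library invariants; returns a list of human-readable issues.

    An empty list means the library is valid. Reported rules: unique ids,
    known roles, role-consistent family/subgroup fields, protein alphabet,
    and presence of at least one exemplar per required role.
    """
    issues: list[str] = []
    seen: set[str] = set()
    for p in lib.proteins:
        if p.id in seen:
            issues.append(f"{p.id}: duplicate id")
        seen.add(p.id)
        if p.role not in ROLES:
            issues.append(f"{p.id}: unknown role {p.role!r}")
        if p.subgroup is not None and p.role != "transposase":
            issues.append(f"{p.id}: subgroup set but role is {p.role} (transposase only)")
        if p.subgroup is not None and p.subgroup not in SUBGROUPS:
            issues.append(f"{p.id}: unknown subgroup {p.subgroup!r}")
        if p.family is not None and p.role not in {"toxin", "antitoxin"}:
            issues.append(f"{p.id}: family set but role is {p.role} (toxin/antitoxin only)")
        if not p.aa_sequence:
            issues.append(f"{p.id}: empty protein sequence")
        elif not set(p.aa_sequence) <= _AA_ALPHABET:
            bad = sorted(set(p.aa_sequence) - _AA_ALPHABET)
            issues.append(f"{p.id}: non-amino-acid letters {bad}")
    for role in ("transposase", "resolvase_S", "toxin", "antitoxin"):
        if not any(p.role == role for p in lib.proteins):
            issues.append(f"library: no exemplar with required role {role}")
    return issues
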