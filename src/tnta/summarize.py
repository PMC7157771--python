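"""Aggregation of a TA-carrying transposon catalog.

The packaged fixture ``data/table1.tsv`` transcribes the published census
of Tn3-family transposons carrying type II toxin-antitoxin systems: one row
per (toxin family, antitoxin family, resolvase type, subgroup,
configuration) combination, with the transposon names/accessions and the
instance count Nb. ``aggregate_counts`` reproduces the headline numbers —
total instances, family counts, distinct TA pairs, per-pair and
per-subgroup totals, and the reversed-order (toxin-first) tally.

Antitoxin variant labels are merged into parent families through an
explicit, auditable map (default: the DNA-binding-domain-less ParD variant
into ParD, the structure-matched HTH into HTH_37), which is how "6
antitoxin families" is counted from 8 raw labels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import io as tio
from .loci import ConfigString, classify_ta_order

__all__ = [
    "CatalogRow",
    "Summary",
    "DEFAULT_ANTITOXIN_MERGE",
    "bundled_catalog_path",
    "load_catalog",
    "aggregate_counts",
]

logger = logging.getLogger(__name__)

DEFAULT_ANTITOXIN_MERGE = {"ParD-noDBD": "ParD", "HTH": "HTH_37"}

_COLUMNS = [
    "toxin_family", "toxin_xref", "toxin_superfamily",
    "antitoxin_family", "antitoxin_xref", "antitoxin_superfamily",
    "resolvase_type", "subgroup", "configuration", "transposons", "nb", "notes",
]


@dataclass
class CatalogRow:
    toxin_family: str
    toxin_xref: str
    toxin_superfamily: str
    antitoxin_family: str
    antitoxin_xref: str
    antitoxin_superfamily: str
    resolvase_type: str
    subgroup: str
    configuration: ConfigString
    transposon_names: list[str]
    nb: int
    notes: str = ""


@dataclass
class Summary:
    total_instances: int
    n_toxin_families: int
    n_antitoxin_families: int
    n_distinct_pairs: int
    pair_counts: dict[tuple[str, str], int]
    toxin_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    ta_order_counts: dict[str, int]
    reversed_by_subgroup: dict[str, int]
    pair_by_subgroup: dict[tuple[str, str, str], int] = field(default_factory=dict)


def bundled_catalog_path() -> Path:
    return Path(resources.files("tnta").joinpath("data", "table1.tsv"))


def load_catalog(path: str | Path | None = None) -> list[CatalogRow]:
    """Load and validate a catalog TSV. ``path=None`` loads the packaged
    fixture. Fails naming the row when Nb disagrees with the name list."""
    path = Path(path) if path is not None else bundled_catalog_path()
    rows = []
    for i, raw in enumerate(tio.read_table(path)):
        missing = [c for c in _COLUMNS[:-1] if c not in raw]
        if missing:
            raise ValueError(f"catalog row {i}: missing columns {missing}")
        names = [n.strip() for n in raw["transposons"].split(";") if n.strip()]
        nb = int(raw["nb"])
        if nb < 1:
            raise ValueError(f"catalog row {i}: nb must be >= 1")
        if nb != len(names):
            raise ValueError(
                f"catalog row {i} ({raw['toxin_family']}/{raw['antitoxin_family']}, "
                f"{raw['subgroup']}): nb={nb} but {len(names)} transposon names"
            )
        rows.append(
            CatalogRow(
                toxin_family=raw["toxin_family"],
                toxin_xref=raw["toxin_xref"],
                toxin_superfamily=raw["toxin_superfamily"],
                antitoxin_family=raw["antitoxin_family"],
                antitoxin_xref=raw["antitoxin_xref"],
                antitoxin_superfamily=raw["antitoxin_superfamily"],
                resolvase_type=raw["resolvase_type"],
                subgroup=raw["subgroup"],
                configuration=ConfigString.parse(raw["configuration"]),
                transposon_names=names,
                nb=nb,
                notes=raw.get("notes", ""),
            )
        )
    return rows


def aggregate_counts(rows: list[CatalogRow],
                     antitoxin_merge: dict[str, str] | None = None) -> Summary:
    """Nb-weighted aggregation of catalog rows (order-invariant)."""
    merge = DEFAULT_ANTITOXIN_MERGE if antitoxin_merge is None else antitoxin_merge
    pair_counts: Counter = Counter()
    toxin_counts: Counter = Counter()
    subgroup_counts: Counter = Counter()
    order_counts: Counter = Counter()
    reversed_by_subgroup: Counter = Counter()
    pair_by_subgroup: Counter = Counter()
    for row in rows:
        antitoxin = merge.get(row.antitoxin_family, row.antitoxin_family)
        pair = (row.toxin_family, antitoxin)
        pair_counts[pair] += row.nb
        toxin_counts[row.toxin_family] += row.nb
        subgroup_counts[row.subgroup] += row.nb
        pair_by_subgroup[(row.toxin_family, antitoxin, row.subgroup)] += row.nb
        order = classify_ta_order(row.configuration)
        order_counts[order] += row.nb
        if order == "reversed":
            reversed_by_subgroup[row.subgroup] += row.nb
        _warn_token_order(row, order)
    total = sum(r.nb for r in rows)
    return Summary(
        total_instances=total,
        n_toxin_families=len(toxin_counts),
        n_antitoxin_families=len({a for _, a in pair_counts}),
        n_distinct_pairs=len(pair_counts),
        pair_counts=dict(sorted(pair_counts.items())),
        toxin_counts=dict(sorted(toxin_counts.items())),
        subgroup_counts=dict(sorted(subgroup_counts.items())),
        ta_order_counts=dict(order_counts),
        reversed_by_subgroup=dict(sorted(reversed_by_subgroup.items())),
        pair_by_subgroup=dict(sorted(pair_by_subgroup.items())),
    )


def _warn_token_order(row: CatalogRow, order: str) -> None:
    """Surface normal-classified rows whose toxin gene sits adjacent to the
    resolvase gene — the arrangement a by-eye reading tends to call
    toxin-first, so the syntax-driven call deserves a second look."""
    if order != "normal":
        return
    genes = [n for n, _ in row.configuration.gene_tokens()]
    resolvases = {"tnpR", "tnpI", "tnpS"}
    for i, name in enumerate(genes):
        if name != "T":
            continue
        neighbours = {genes[j] for j in (i - 1, i + 1) if 0 <= j < len(genes)}
        if neighbours & resolvases:
            logger.warning(
                "catalog row %s/%s (%s): classified normal by transcription order "
                "but the toxin gene neighbours the resolvase (%s); by-eye readings "
                "may call this reversed",
                row.toxin_family, row.antitoxin_family, row.subgroup,
                row.configuration,
            )
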