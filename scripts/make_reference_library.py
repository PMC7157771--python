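"""Regenerate the bundled synthetic exemplar library.

The packaged library under ``src/tnta/data/reference/`` is a deterministic
synthetic stand-in for the curated exemplar proteins (transposases per Tn3
subgroup, the three resolvase systems, and the toxin/antitoxin families of
the catalog). Sequences are random proteins at realistic lengths; the second
exemplar of each TA family is a 65%-identity variant of the first, so
best-hit family assignment has within-family structure to resolve.

Run from the repository root:  python scripts/make_reference_library.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "tnta" / "data" / "reference"

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
SEED = 20200331
VERSION = "0.1.0-synthetic"

TRANSPOSASE_SUBGROUPS = ["Tn3", "Tn21", "Tn163", "IS1071", "IS3000", "Tn4430", "Tn4651", "Tn3000"]

RESOLVASES = [
    ("TNPR_SYN", "resolvase_S", 185),
    ("TNPI_SYN", "resolvase_Y", 305),
    ("TNPS_SYN", "resolvase_Y_het", 295),
    ("TNPT_SYN", "helper", 250),
]

TOXINS = [  # family, superfamily, length
    ("ParE", "RelE/ParE", 95),
    ("PIN_3", "PIN", 130),
    ("Gp49", "RelE/ParE", 90),
    ("PIN", "PIN", 135),
    ("HEPN", "HEPN", 150),
]

ANTITOXINS = [
    ("ParD", "RelB/ParD", 88),
    ("ParD-noDBD", "ParD-noDBD", 85),
    ("Phd/YeFM", "Phd/YeFM", 92),
    ("RHH_6", "VapB", 86),
    ("HTH_37", "HigA", 100),
    ("HTH", "HigA", 98),
    ("AbrB", "AbrB/MazE", 90),
    ("Mnt", "Mnt", 118),
]


def random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(AA, size=length - 1)
    return "M" + "".join(body)


def variant(rng: np.random.Generator, protein: str, identity: float) -> str:
    """Substitution-only mutant at the given identity, start Met preserved."""
    seq = list(protein)
    n_mut = round((1.0 - identity) * len(seq))
    positions = rng.choice(np.arange(1, len(seq)), size=n_mut, replace=False)
    for pos in positions:
        choices = [a for a in AA if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def main() -> None:
    rng = np.random.default_rng(SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    fasta = []

    def add(pid, role, seq, family=".", superfamily=".", subgroup=".", notes="."):
        fasta.append((pid, seq))
        rows.append((pid, role, family, superfamily, subgroup, notes))

    for sg in TRANSPOSASE_SUBGROUPS:
        pid = f"TNPA_{sg.upper().replace('.', '')}_SYN"
        add(pid, "transposase", random_protein(rng, 950), subgroup=sg,
            notes="synthetic exemplar")
    for pid, role, length in RESOLVASES:
        add(pid, role, random_protein(rng, length), notes="synthetic exemplar")
    for fam, superfam, length in TOXINS:
        base = random_protein(rng, length)
        tag = fam.upper().replace("/", "").replace("-", "")
        add(f"TOX_{tag}_1_SYN", "toxin", base, family=fam, superfamily=superfam,
            notes="synthetic exemplar")
        add(f"TOX_{tag}_2_SYN", "toxin", variant(rng, base, 0.65), family=fam,
            superfamily=superfam, notes="synthetic exemplar, 65% variant of _1")
    for fam, superfam, length in ANTITOXINS:
        base = random_protein(rng, length)
        tag = fam.upper().replace("/", "").replace("-", "")
        add(f"AT_{tag}_1_SYN", "antitoxin", base, family=fam, superfamily=superfam,
            notes="synthetic exemplar")
        add(f"AT_{tag}_2_SYN", "antitoxin", variant(rng, base, 0.65), family=fam,
            superfamily=superfam, notes="synthetic exemplar, 65% variant of _1")

    with (OUT / "synthetic_exemplars.faa").open("w") as fh:
        for pid, seq in fasta:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with (OUT / "metadata.tsv").open("w") as fh:
        fh.write("id\trole\tfamily\tsuperfamily\tsubgroup\tnotes\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    (OUT / "VERSION").write_text(VERSION + "\n")
    print(f"wrote {len(fasta)} synthetic exemplars to {OUT}")


if __name__ == "__main__":
    main()
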