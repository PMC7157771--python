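"""Synthetic genomes with planted Tn3 transposition modules.

Every simulator is seed-deterministic and returns a ground-truth feature
set alongside the sequence, so detection stages can be scored exactly:

* gene content and order follow a configuration string (``<T <A tnpR>
  tnpA>`` and relatives), with proteins derived from the bundled exemplars
  by substitution-only mutagenesis to a target percent identity and
  reverse-translated with uniform codon choice (genetic code 11);
* a res site of three inverted-repeat subsites is planted upstream of the
  resolvase (subsite III proximal), with the crossover AT dinucleotide at
  the centre of subsite I;
* chimeras join two parents at their res subsite I crossovers, emulating
  intertransposon recombination;
* toxin sets with a known number of independent origins exercise the
  acquisition-event counter.

Mutagenesis is substitution-only, so realized identity is exact under
ungapped comparison and coordinates never shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from .acquisition import ToxinEntry, ToxinSet
from .io import FeatureRow, SeqRecord, revcomp
from .loci import ConfigString
from .reference import RefLibrary, load_reference_library

__all__ = [
    "SimSpec",
    "ResGeometry",
    "TruthSet",
    "mutate_to_identity",
    "reverse_translate",
    "simulate_transposon",
    "simulate_genome",
    "simulate_chimera",
    "simulate_chimera_pair",
    "simulate_toxin_origins",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_DNA = np.array(list("ACGT"))

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[11].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()


@dataclass(frozen=True)
class ResGeometry:
    """Planted res-subsite geometry; defaults sit inside the scanner's
    default search bounds."""

    arm_len: int = 13
    loop_len: int = 4
    subsite_gap: int = 8  # between consecutive subsites
    crossover_offset: int | None = None  # within subsite I span; None = centre


@dataclass
class SimSpec:
    """Recipe for one planted transposition module."""

    configuration: str = "<T <A tnpR> tnpA>"
    seed: int = 0
    identity: float | dict[str, float] = 70.0  # percent vs exemplar, per token name
    toxin_family: str = "ParE"
    antitoxin_family: str = "ParD"
    subgroup: str = "Tn3000"
    gap_range: tuple[int, int] = (60, 150)
    # res subsites abut their neighbours (site III the resolvase promoter
    # region, site I the TA operon), so the block gets short flanks
    res_flank_range: tuple[int, int] = (12, 25)
    res_geometry: ResGeometry = field(default_factory=ResGeometry)
    plant_res: bool = True
    truncate_toxin: bool = False  # internal stop at 40% of the toxin gene

    def identity_for(self, token: str) -> float:
        if isinstance(self.identity, dict):
            return float(self.identity.get(token, 100.0))
        return float(self.identity)


@dataclass
class TruthSet:
    features: list[FeatureRow]
    realized_identity: dict[str, float] = field(default_factory=dict)
    junction: int | None = None

    def of_type(self, feature_type: str) -> list[FeatureRow]:
        return [f for f in self.features if f.feature_type == feature_type]

    def shifted(self, offset: int, seq_id: str) -> "TruthSet":
        feats = [
            FeatureRow(seq_id, f.start + offset, f.end + offset, f.strand,
                       f.feature_type, dict(f.attributes))
            for f in self.features
        ]
        return TruthSet(feats, dict(self.realized_identity),
                        None if self.junction is None else self.junction + offset)


def mutate_to_identity(sequence: str, target_identity: float, alphabet: str = "dna",
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       protect: frozenset[int] | set[int] = frozenset()) -> str:
    """Substitution-only mutagenesis to a target percent identity.

    Exactly round((1 - target/100) * L) positions (outside ``protect``) are
    substituted with a different letter, so the realized ungapped identity
    is within 1/L of the target. Deterministic per seed.
    """
    if not 20.0 <= target_identity <= 100.0:
        raise ValueError("target identity must be in [20, 100]")
    if rng is None:
        rng = np.random.default_rng(seed)
    letters = _DNA if alphabet == "dna" else _AA
    seq = list(sequence)
    n_mut = round((1.0 - target_identity / 100.0) * len(seq))
    allowed = [i for i in range(len(seq)) if i not in protect]
    n_mut = min(n_mut, len(allowed))
    if n_mut == 0:
        return sequence
    positions = rng.choice(len(allowed), size=n_mut, replace=False)
    for idx in positions:
        pos = allowed[idx]
        options = [c for c in letters if c != seq[pos]]
        seq[pos] = options[rng.integers(len(options))]
    return "".join(seq)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform-codon reverse translation (code 11) plus a TAA stop."""
    codons = []
    for aa in protein:
        choices = _CODONS_BY_AA.get(aa)
        if choices is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons) + "TAA"


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA, size=length, p=p))


def _exemplar(lib: RefLibrary, token: str, spec: SimSpec):
    role_by_token = {"tnpA": "transposase", "tnpR": "resolvase_S", "tnpI": "resolvase_Y",
                     "tnpS": "resolvase_Y_het", "tnpT": "helper"}
    if token == "T":
        pool = [p for p in lib.by_role("toxin") if p.family == spec.toxin_family]
    elif token == "A":
        pool = [p for p in lib.by_role("antitoxin") if p.family == spec.antitoxin_family]
    elif token == "tnpA":
        pool = [p for p in lib.by_role("transposase") if p.subgroup == spec.subgroup]
    else:
        pool = lib.by_role(role_by_token[token])
    if not pool:
        raise ValueError(f"no exemplar in library for token {token!r} "
                         f"(toxin={spec.toxin_family}, antitoxin={spec.antitoxin_family}, "
                         f"subgroup={spec.subgroup})")
    return min(pool, key=lambda p: p.id)


def _make_subsite(rng: np.random.Generator, geometry: ResGeometry,
                  with_crossover: bool) -> tuple[str, int | None]:
    """One perfect inverted repeat; optionally an AT dinucleotide embedded
    at the span centre (the recombination crossover of subsite I)."""
    arm = "".join(rng.choice(_DNA, size=geometry.arm_len))
    loop = "".join(rng.choice(_DNA, size=geometry.loop_len))
    site = list(arm + loop + revcomp(arm))
    total = len(site)
    if not with_crossover:
        return "".join(site), None
    offset = geometry.crossover_offset
    if offset is None:
        offset = (total - 2) // 2
    if not 0 <= offset <= total - 2:
        raise ValueError("crossover offset outside subsite I span")
    site[offset], site[offset + 1] = "A", "T"
    # repair arm symmetry where the forced AT landed inside an arm
    in_loop = range(geometry.arm_len, geometry.arm_len + geometry.loop_len)
    for i in (offset, offset + 1):
        j = total - 1 - i
        if i not in in_loop and j not in (offset, offset + 1):
            site[j] = revcomp(site[i])
    return "".join(site), offset


def _build_res_block(rng: np.random.Generator, geometry: ResGeometry,
                     resolvase_side: str) -> tuple[str, list[tuple[str, int, int]], int]:
    """Res block sequence, subsite intervals (block-local), crossover pos.

    ``resolvase_side`` is "right" when the resolvase gene follows the block
    in genome order (subsite III is then rightmost) and "left" otherwise.
    """
    labels = ["I", "II", "III"] if resolvase_side == "right" else ["III", "II", "I"]
    parts: list[str] = []
    intervals: list[tuple[str, int, int]] = []
    crossover = None
    pos = 0
    for i, label in enumerate(labels):
        site, cx = _make_subsite(rng, geometry, with_crossover=(label == "I"))
        parts.append(site)
        intervals.append((label, pos, pos + len(site)))
        if cx is not None:
            crossover = pos + cx
        pos += len(site)
        if i < 2:
            gap = "".join(rng.choice(_DNA, size=geometry.subsite_gap))
            parts.append(gap)
            pos += geometry.subsite_gap
    return "".join(parts), intervals, crossover


def simulate_transposon(spec: SimSpec, library: RefLibrary | None = None
                        ) -> tuple[SeqRecord, TruthSet]:
    """Build one transposition module from a configuration string.

    Genes are mutated exemplar proteins, reverse-translated and laid out
    left to right with random intergenic gaps; the res block is planted
    immediately upstream of the resolvase gene (or at an explicit ``!res!``
    token), subsite III proximal. Byte-identical output per (spec, seed).
    """
    lib = library if library is not None else load_reference_library()
    rng = np.random.default_rng(spec.seed)
    config = ConfigString.parse(spec.configuration)
    genes = config.gene_tokens()
    resolvase_tokens = [n for n, _ in genes if n in ("tnpR", "tnpI", "tnpS")]
    explicit_res = any(s is None for _, s in config.tokens)
    if spec.plant_res and not resolvase_tokens:
        raise ValueError("configuration has no resolvase gene but a res site was requested")

    gene_payloads = []  # (token, strand, dna, realized_identity)
    for token, strand in genes:
        if token == "X":
            length = int(rng.integers(90, 140))
            protein = "M" + "".join(rng.choice(_AA, size=length - 1))
            dna = reverse_translate(protein, rng)
            realized = float("nan")
        else:
            exemplar = _exemplar(lib, token, spec)
            target = spec.identity_for(token)
            protein = mutate_to_identity(exemplar.aa_sequence, target,
                                         alphabet="protein", rng=rng, protect={0})
            ungapped = sum(a == b for a, b in zip(protein, exemplar.aa_sequence))
            realized = 100.0 * ungapped / len(protein)
            dna = reverse_translate(protein, rng)
            if token == "T" and spec.truncate_toxin:
                stop_codon_index = max(1, int(0.4 * len(protein)))
                dna = dna[: stop_codon_index * 3] + "TAA" + dna[stop_codon_index * 3 + 3 :]
        if strand == "-":
            dna = revcomp(dna)
        gene_payloads.append((token, strand, dna, realized))

    # decide where the res block goes, as an index into the gene list
    res_index: int | None = None
    if explicit_res:
        gene_i = 0
        for name, strand in config.tokens:
            if strand is None:
                res_index = gene_i
                break
            gene_i += 1
    elif spec.plant_res:
        res_token = resolvase_tokens[0]
        for i, (token, strand) in enumerate(genes):
            if token == res_token:
                # upstream in reading direction: before the gene on "+",
                # after it on "-"
                res_index = i if strand == "+" else i + 1
                break

    features: list[FeatureRow] = []
    realized_map: dict[str, float] = {}
    parts: list[str] = []
    pos = 0
    seq_id = f"sim_tn_seed{spec.seed}"

    def emit_gap(gap_range: tuple[int, int] | None = None) -> None:
        nonlocal pos
        lo, hi = gap_range if gap_range is not None else spec.gap_range
        gap = "".join(rng.choice(_DNA, size=int(rng.integers(lo, hi + 1))))
        parts.append(gap)
        pos += len(gap)

    def emit_res() -> None:
        nonlocal pos
        resolvase_side = "right" if res_is_left_of_resolvase else "left"
        block, intervals, cx = _build_res_block(rng, spec.res_geometry, resolvase_side)
        start = pos
        parts.append(block)
        for label, s, e in intervals:
            features.append(FeatureRow(seq_id, start + s, start + e, "+",
                                       f"res_subsite_{label}", {}))
        features.append(FeatureRow(seq_id, start, start + len(block), "+", "res_site", {}))
        features.append(FeatureRow(seq_id, start + cx, start + cx + 2, "+",
                                   "crossover_AT", {}))
        pos += len(block)

    role_by_token = {"T": "toxin", "A": "antitoxin", "X": "unknown",
                     "tnpA": "transposase", "tnpR": "resolvase_S",
                     "tnpI": "resolvase_Y", "tnpS": "resolvase_Y_het",
                     "tnpT": "helper"}

    # orientation of the planted block relative to the resolvase gene
    res_is_left_of_resolvase = True
    if res_index is not None:
        for i, (token, strand) in enumerate(genes):
            if token in ("tnpR", "tnpI", "tnpS"):
                res_is_left_of_resolvase = res_index <= i
                break

    emit_gap()
    for i, (token, strand, dna, realized) in enumerate(gene_payloads):
        if res_index == i:
            emit_res()
            emit_gap(spec.res_flank_range)
        start = pos
        parts.append(dna)
        pos += len(dna)
        features.append(FeatureRow(seq_id, start, pos, strand, role_by_token[token],
                                   {"token": token}))
        if realized == realized:  # not NaN
            realized_map[token] = realized
        emit_gap(spec.res_flank_range if res_index == i + 1 else None)
    if res_index == len(gene_payloads):
        emit_res()
        emit_gap()

    sequence = "".join(parts)
    record = SeqRecord(id=seq_id, sequence=sequence, description="synthetic transposon")
    truth = TruthSet(features=features, realized_identity=realized_map)
    _guard_res_flanks(record, truth)
    return record, truth


def _guard_res_flanks(record: SeqRecord, truth: TruthSet) -> None:
    """Break inverted-repeat symmetry just outside each planted subsite so
    the scanner cannot extend an arm past the planted boundary."""
    seq = list(record.sequence)
    for f in truth.features:
        if not f.feature_type.startswith("res_subsite"):
            continue
        s, e = f.start, f.end
        if s - 1 >= 0 and e < len(seq):
            if seq[s - 1] == revcomp(seq[e]):
                seq[s - 1] = _non_complement(seq[s - 1], seq[e])
    record.sequence = "".join(seq)


def _non_complement(current: str, partner: str) -> str:
    for base in "ACGT":
        if base != current and base != revcomp(partner):
            return base
    return current


def simulate_genome(specs: list[SimSpec], background_length: int = 50_000,
                    gc: float = 0.5, seed: int = 0,
                    library: RefLibrary | None = None,
                    min_separation: int = 3000) -> tuple[SeqRecord, TruthSet]:
    """Embed modules at non-overlapping positions in a random background."""
    rng = np.random.default_rng(seed)
    modules = [simulate_transposon(spec, library) for spec in specs]
    total_needed = sum(len(rec) for rec, _ in modules) + (len(modules) + 1) * min_separation
    if modules and background_length < total_needed:
        raise ValueError(
            f"background of {background_length} bp cannot hold {len(modules)} modules "
            f"with {min_separation} bp separation (need >= {total_needed})"
        )
    background = _random_dna(rng, background_length, gc)
    seq_id = f"sim_genome_seed{seed}"
    if not modules:
        return SeqRecord(id=seq_id, sequence=background,
                         description="synthetic background genome"), TruthSet([])

    # ordered insertion offsets (output coordinates) with guaranteed
    # >= min_separation spacing: sorted random cuts over the free space
    lengths = [len(rec) for rec, _ in modules]
    free = background_length - sum(lengths) - (len(modules) + 1) * min_separation
    cuts = np.sort(rng.integers(0, free + 1, size=len(modules)))
    positions = [
        (i + 1) * min_separation + sum(lengths[:i]) + int(cuts[i])
        for i in range(len(modules))
    ]

    parts = []
    features: list[FeatureRow] = []
    realized: dict[str, float] = {}
    bg_cursor = 0
    out_cursor = 0
    for (rec, truth), start in zip(modules, positions):
        gap = start - out_cursor
        parts.append(background[bg_cursor : bg_cursor + gap])
        bg_cursor += gap
        out_cursor += gap
        shifted = truth.shifted(out_cursor, seq_id)
        features.extend(shifted.features)
        for token, val in shifted.realized_identity.items():
            realized[f"{rec.id}:{token}"] = val
        parts.append(rec.sequence)
        out_cursor += len(rec)
    parts.append(background[bg_cursor:])
    sequence = "".join(parts)
    return (
        SeqRecord(id=seq_id, sequence=sequence, description="synthetic genome"),
        TruthSet(features=features, realized_identity=realized),
    )


def simulate_chimera(rec_a: SeqRecord, truth_a: TruthSet,
                     rec_b: SeqRecord, truth_b: TruthSet,
                     junction: str | int = "res_site_I_crossover"
                     ) -> tuple[SeqRecord, TruthSet]:
    """Join the left part of A and the right part of B.

    With ``junction="res_site_I_crossover"`` the cut is at each parent's
    planted crossover AT; an integer cuts both parents at that coordinate.
    """
    if junction == "res_site_I_crossover":
        cx_a = truth_a.of_type("crossover_AT")
        cx_b = truth_b.of_type("crossover_AT")
        if not cx_a or not cx_b:
            raise ValueError("both parents need a planted res-site-I crossover")
        cut_a, cut_b = cx_a[0].start, cx_b[0].start
    else:
        cut_a = cut_b = int(junction)
    sequence = rec_a.sequence[:cut_a] + rec_b.sequence[cut_b:]
    seq_id = f"chimera_{rec_a.id}_{rec_b.id}"
    shift = cut_a - cut_b
    features = [
        FeatureRow(seq_id, f.start, f.end, f.strand, f.feature_type, dict(f.attributes))
        for f in truth_a.features if f.end <= cut_a + 2
    ]
    for f in truth_b.features:
        if f.start >= cut_b - 2 and f.end + shift <= len(sequence):
            features.append(FeatureRow(seq_id, f.start + shift, f.end + shift,
                                       f.strand, f.feature_type, dict(f.attributes)))
    record = SeqRecord(id=seq_id, sequence=sequence, description="synthetic chimera")
    return record, TruthSet(features=features, junction=cut_a)


def simulate_chimera_pair(seed: int, parent_identity: float = 60.0,
                          spec: SimSpec | None = None,
                          library: RefLibrary | None = None
                          ) -> tuple[SeqRecord, TruthSet, SeqRecord, TruthSet]:
    """Two parents sharing an identical res subsite I, otherwise diverged.

    Parent B is parent A mutated to ``parent_identity`` percent DNA
    identity everywhere except subsite I and its crossover — homologous
    recombination at site I presumes identity there — so a chimera of the
    two has an intact, scannable res site and a sharp identity junction.
    """
    spec = replace(spec, seed=seed) if spec is not None else SimSpec(seed=seed)
    rec_a, truth_a = simulate_transposon(spec, library)
    site_i = truth_a.of_type("res_subsite_I")[0]
    protected = set(range(site_i.start, site_i.end))
    seq_b = mutate_to_identity(rec_a.sequence, parent_identity, alphabet="dna",
                               seed=seed + 7_000_003, protect=protected)
    rec_b = SeqRecord(id=f"{rec_a.id}_div", sequence=seq_b,
                      description="diverged parent sharing res subsite I")
    truth_b = truth_a.shifted(0, rec_b.id)
    return rec_a, truth_a, rec_b, truth_b


def simulate_toxin_origins(k: int, n_per_origin: int = 3, divergence: float = 0.1,
                           n_seeds: int | None = None, seed: int = 0,
                           family: str = "SimTox", length: int = 120) -> ToxinSet:
    """A toxin family with ``k`` independent transposon acquisitions.

    ``k`` ancestor proteins are drawn independently (pairwise p-distance
    ~0.95, far above 2 x divergence); each spawns ``n_per_origin``
    transposon-associated descendants within ``divergence`` substitutions
    per site. Seed-origin (non-transposon) relatives attach to each
    ancestor at ~1.6 x divergence, interleaving the origins on the tree.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_seeds is None:
        n_seeds = max(k, 2)
    rng = np.random.default_rng(seed)
    entries: list[ToxinEntry] = []
    ancestors = []
    for i in range(k):
        ancestors.append("M" + "".join(rng.choice(_AA, size=length - 1)))
    for i, ancestor in enumerate(ancestors):
        # a founder branch below the ancestor makes each acquisition's
        # descendants monophyletic relative to the seed relatives
        founder = mutate_to_identity(ancestor, 100.0 * (1 - 0.5 * divergence),
                                     alphabet="protein", rng=rng)
        for j in range(n_per_origin):
            d = float(rng.uniform(0.1 * divergence, 0.5 * divergence))
            descendant = mutate_to_identity(founder, 100.0 * (1 - d),
                                            alphabet="protein", rng=rng)
            entries.append(ToxinEntry(f"tn_{i:02d}_{j:02d}", descendant,
                                      "tn_associated", family))
    seed_gap = min(1.6 * divergence, 0.8)
    for j in range(n_seeds):
        anchor = ancestors[j % k]
        seq = mutate_to_identity(anchor, 100.0 * (1 - seed_gap),
                                 alphabet="protein", rng=rng)
        entries.append(ToxinEntry(f"seed_{j:02d}", seq, "seed", family))
    return ToxinSet(entries=entries, family=family)
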