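# Methods

This note documents the models, numerical conventions and design choices
behind `tnta`, and what the simulation-based tests do and do not show.

## Homology screen

Candidate transposition modules are detected by translated homology
against a labelled exemplar library, following the published screening
rule for this family: a genomic region qualifies when ORF translations
align to transposase, resolvase, toxin or antitoxin exemplars with
identity above 40% and alignment coverage of 60%, and hits within 2,000 bp
of each other are chained into one locus.

Conventions that fix the numbers:

* **ORF calling** is an internal six-frame scan (genetic code 11, start
  codons ATG/GTG/TTG, minimum 80 aa, nested ORFs sharing a stop report the
  first start, ORFs containing N skipped), replacing the external gene
  finder used originally. Planted-truth tests only need deterministic
  coordinates; an ORF may over-extend upstream of the real gene to an
  earlier in-frame start in intergenic DNA, which is why downstream steps
  that need true gene boundaries (res-region clipping, TA adjacency) use
  the exemplar-aligned span of the hit instead of the raw ORF span.
* **Alignment** is optimal local Smith-Waterman under BLOSUM62 with gap
  open 11 / extend 1 (a gap of length L costs 11 + L), the classic
  protein-search defaults; the original search tool is named in the source
  material but its parameters are not. Identity is identities divided by
  *all* alignment columns, gap columns included; coverage is the aligned
  span of the *reference* divided by reference length (the screen's
  purpose is finding full-length role proteins). "Above 40%" is a strict
  `>`; coverage is `≥`. These choices are configurable and never silently
  changed.
* **Clustering** is single-linkage on nucleotide intervals with the gap
  measured end-to-start, inclusive at 2,000 bp; a chained locus may
  therefore span more than 2 kb in total.
* **Best-hit selection** keeps one hit per ORF: highest score, ties broken
  by identity, then lexicographically smallest reference id, so results
  are invariant to library order.
* **Truncated toxins.** A toxin gene interrupted by an internal stop
  (e.g. a catalogued transposon whose antitoxin is intact while the toxin
  is broken) cannot pass the 60% coverage cut, and its fragment is usually
  shorter than the 80-aa ORF floor. Two targeted relaxations recognise
  this case without opening the screen to noise: toxin matches with
  coverage in [25, 60)% are kept flagged `truncated`, and loci that have
  an antitoxin but no toxin are re-scanned around the antitoxin with a
  25-aa ORF floor. A truncated match is only believed when it lies within
  1 kb of an antitoxin hit — TA pairs are adjacent two-gene operons in
  every catalogued arrangement — and only the strongest fragment is
  reported. Such loci count as TA-carrying, with a `truncated_toxin` note.

## Configuration strings and TA order

Gene arrangements are rendered in arrow notation: tokens left to right in
genomic order, `NAME>` on the plus strand, `<NAME` on the minus strand,
`!res!` marking a predicted res site that falls between genes, `X` an
unclassified ORF lying between classified members. `parse(render(c)) = c`
on all generated configurations.

TA gene order considers only the T and A tokens. Co-oriented pairs are
read in transcription order — leftmost first on +/+, rightmost first on
−/− — with antitoxin-first the common ("normal") arrangement and
toxin-first "reversed". Opposite strands, missing genes or duplicated
tokens give `undetermined`/`absent`. The classifier is strictly
syntactic; catalog aggregation logs a warning for rows classified normal
whose toxin gene neighbours the resolvase, because by-eye readings of
such maps have been known to call them reversed, and the catalog contains
one row where published prose and table notation disagree.

## Res-site prediction

The serine-resolvase res site is modelled as three inverted-repeat
subsites (I, II, III) in a ~100–150 bp segment, subsite III proximal to
the resolvase gene and the recombination crossover at an AT dinucleotide
central in subsite I. The search region is the DNA immediately upstream
of the resolvase ORF in its own reading direction — for divergent
tnpR/tnpA this is exactly the intergenic region between them, for
colinear genes a window of at most 400 bp clipped at the neighbouring
gene; for TnpS+TnpT systems it is the segment between the divergent
resolvase and helper genes.

Inverted repeats are enumerated exhaustively within configurable bounds
(arm 8–14 bp, loop ≤ 14 bp, ≤ 3 arm mismatches; no published
position-weight model exists for these sites, so the score is simply arm
length minus mismatches). Site assembly picks the three mutually
non-overlapping motifs with inter-subsite gaps of 0–60 bp that maximise
total score; ties prefer compact motifs, then leftmost, making the result
invariant to motif enumeration order. A two-motif fallback is reported
as partial only on request. The crossover is the AT dinucleotide closest
to the centre of subsite I's span, ties going left.

## Pairwise comparison and breakpoints

Dot-plot matches list every exact shared word (default 10 bp, the default
word size of the dot-plot tool used in the original analysis), both
orientations. Identity profiles are computed on a unit-cost global
alignment (edlib) — the simulators are substitution-only, so edit-distance
optima coincide with any reasonable scoring — as the fraction of identical
columns in 100-bp windows every 10 bp along sequence A.

The recombination junction is operationalised as a least-squares
two-segment change-point on the identity profile, reported only when one
segment mean is ≥ 0.95 and the other ≤ 0.85; the original analysis
localised junctions by visual inspection of alignments, so an explicit,
testable statistic is substituted. The confidence interval covers split
positions within 5% of the optimal fit cost. The profile cannot resolve
a junction below about half a window, so "breakpoint inside subsite I" is
evaluated at ±(window/2 + step) resolution.

## Acquisition events

Within a toxin family, identical sequences are collapsed (representative:
smallest id), p-distances (mismatches over ungapped aligned columns of a
global alignment) feed neighbour-joining (scikit-bio), and the tree is
rooted above the lexicographically smallest seed-origin leaf (midpoint
when no seeds exist). Negative NJ branch lengths are clamped to zero. An
acquisition event is a maximal clade whose leaves are all
transposon-associated — the minimum number of seed→transposon transitions
under that rooting. This replaces maximum-likelihood trees with
bootstraps: the count needs only a topology, NJ is exact on additive
distances (tested), and the backend is pluggable. The event count is an
interpretation of the tree, not a likelihood statement.

## Synthetic data

The simulators define the test conditions; every output is
bit-reproducible from (spec, seed).

* **Genes** are exemplar proteins mutated by substitution only to a target
  identity (positions uniform, start Met protected; exactly
  round((1−t)·L) positions changed, so realized identity is within 1/L of
  target, well inside the ±5-point contract asserted over 200 random
  specs), then reverse-translated with uniform codon choice. GC of planted
  genes therefore floats free of the background GC; no stage uses GC.
* **Modules** lay genes out per configuration string with random
  intergenic gaps of 60–150 bp. The res block (three perfect-palindrome
  subsites, arm 13 bp, loop 4 bp, 8 bp apart, crossover AT embedded at
  the centre of subsite I) is planted immediately upstream of the
  resolvase with short 12–25 bp flanks — res sites abut the resolvase
  promoter region and the TA operon. One base just outside each subsite
  is set to break palindrome symmetry so arm extension past the planted
  boundary always costs a mismatch; with 13-bp arms an extension beyond
  the scanner's 14-bp maximum is impossible, which is what makes planted
  recovery exact rather than merely approximate.
* **Genomes** embed modules at seed-chosen positions in uniform random
  background with ≥ 3 kb separation.
* **Chimeras** join the left part of parent A at its crossover AT to the
  right part of parent B at its crossover. The convenience pair generator
  derives B from A at 60% DNA identity while preserving subsite I exactly,
  because recombination at site I presumes local homology; this also
  keeps the chimera's res site scannable. The junction therefore sits a
  few bases left of the end of the identical segment, an offset far
  inside the profile's resolution.
* **Toxin sets** draw k independent random ancestors (pairwise p-distance
  ≈ 0.95), give each a founder branch of 0.5·divergence — making each
  origin's descendants genuinely monophyletic — and spawn descendants
  within 0.5·divergence of the founder; seed-origin relatives attach to
  the ancestors at ≈1.6·divergence, interleaving the origins.

What passing these tests shows: the pipeline recovers exactly what was
planted under substitution-only divergence with intact gene order. What
it does not show: robustness to indels, frameshifts, nested insertions,
composition bias, or the curation judgement real annotation requires.

## Reference library

The exemplar library that ships with the package is *synthetic*: random
proteins at realistic lengths for each role (transposases per subgroup at
950 aa, resolvases 185–305 aa, toxins 90–150 aa, antitoxins 85–118 aa),
two exemplars per TA family with the second a 65%-identity variant of the
first. The original screens seeded from curated databases whose exact
sequences are not distributed here; the library is therefore a functional
stand-in that exercises every code path (role and family assignment,
subgroup propagation, best-hit tie-breaks) but carries no biological
information about real families. Swap in a curated directory (protein
FASTA + `metadata.tsv` with id/role/family/superfamily/subgroup) for real
screening; the metadata schema reserves fields so an HMM backend could be
slotted in per family.

## Problem sizes

The recovery benchmarks use 20 planted genomes of 20 kb (configurations
cycling through the catalog's eight arrangements, identities 55–100%),
10 pure-background genomes of 50 kb, 100 chimera replicates and 50
replicates per origin count — sizes at which every rate is stable across
seeds while the whole suite runs in about two minutes.

## Known limitations

* Family assignment is best-hit against exemplars, not profile HMM search;
  remote homologs of a family absent from the library are invisible.
* No terminal inverted-repeat (transposon end) detection, passenger-gene
  annotation, promoter prediction, or E-value statistics.
* The res-site score is mismatch-counting, not a trained motif model; on
  real sequence it should be treated as a candidate generator for
  curation, as in the original workflow.
* `identity_profile` assumes collinear sequences (no rearrangement
  handling) and unit-cost alignment.
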