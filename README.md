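# tnta — toxin-antitoxin gene pairs in Tn3-family transposition modules

Tn3-family transposons replicate by paste-and-copy transposition: a large
DDE transposase (TnpA) fuses donor and target replicons into a cointegrate,
which a site-specific resolvase (serine-type TnpR, tyrosine-type TnpI, or
the heteromeric TnpS+TnpT) then resolves at a short internal *res*/*irs*/*rst*
site. Some family members carry a type II toxin-antitoxin (TA) gene pair —
a stable toxin plus a labile antitoxin — embedded inside this transposition
module, directly beside the *res* site rather than out among ordinary
passenger genes. `tnta` is a toolkit for finding and analysing these
modules in bacterial sequence data:

* **screen** — six-frame ORF calling plus Smith-Waterman protein search
  against a labelled exemplar library (transposases per subgroup,
  resolvases, TA families), keeping matches with identity > 40% and
  reference coverage ≥ 60%, and single-linkage clustering of hits within
  2,000 bp into candidate loci;
* **classify** — arrow-notation configuration strings
  (`<T <A tnpR> tnpA>`: genes left to right, `<` / `>` giving strand), TA
  gene order (antitoxin-first "normal" vs toxin-first "reversed" by
  transcription order), completeness, resolvase type and TnpA subgroup;
* **res-scan** — inverted-repeat search upstream of the resolvase and
  assembly of the best non-overlapping subsite triple (I, II, III; III
  resolvase-proximal), with the crossover AT dinucleotide at the centre of
  subsite I;
* **compare** — exact word dot-plot matches, windowed identity profiles on
  global alignments, and a least-squares two-segment change-point that
  localises recombination junctions between transposons (TA-module exchange
  happens by recombination at *res* subsite I);
* **acquire** — collapse identical toxins, build a neighbour-joining tree
  on p-distances together with non-transposon seed relatives, and count
  independent TA-acquisition events as maximal transposon-only clades;
* **summarize** — aggregate a catalog of TA-carrying transposons (a
  packaged 12-row census fixture is included) into headline counts;
* **simulate** — seed-deterministic genomes with planted modules, res
  sites, chimeras and toxin sets, with exact ground truth for every stage.

The bundled exemplar library is a deterministic synthetic stand-in (see
`docs/methods.md`); all recovery benchmarks run on simulated data with
known truth and need no downloads.

## Worked example

```sh
python examples/scan_simulated_genome.py
```

```
simulated genome: 24,456 bp, 1 planted module (<T <A tnpR> tnpA>)
locus 3,793-8,092: <T <A !res! tnpR> tnpA>
  completeness=full_with_TA subgroup=Tn3000 resolvase=R ta_order=normal
  res site (4465, 4570), crossover AT at 4478, TA adjacent to subsite I: True
```

The scan recovered the planted module exactly: toxin and antitoxin on the
minus strand, then the predicted res site (`!res!`), then resolvase and
transposase on plus. `ta_order=normal` means the antitoxin gene is
transcribed before the toxin; `crossover AT at 4478` is the dinucleotide in
res subsite I where cointegrate resolution — and intertransposon
recombination — takes place; `TA adjacent ... True` records that the TA
pair sits immediately on the far side of subsite I from the resolvase, the
hallmark position of these systems.

Other entry points: `examples/detect_recombination_breakpoint.py` (junction
detection on a simulated res-site-I chimera),
`examples/count_acquisition_events.py`,
`examples/summarize_catalog.py`, and the equivalent `tnta` CLI commands
(`tnta scan`, `tnta res-scan`, `tnta compare`, `tnta acquire`,
`tnta summarize`, `tnta simulate`). Analyses that require downloading real
accession sequences are gated behind `examples/real_accession_demo.py
--fetch` and are not part of the test suite.

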