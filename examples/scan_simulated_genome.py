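"""Scan a genome for TA-carrying Tn3 transposition modules.

Builds a 20 kb synthetic genome with one planted module (toxin, antitoxin,
tnpR resolvase and tnpA transposase at 70% protein identity to the library
exemplars), screens it, and prints each candidate locus with its
arrow-notation configuration. The configuration "<T <A !res! tnpR> tnpA>"
reads left to right in genomic order: toxin and antitoxin on the minus
strand, the predicted res site, then resolvase and transposase on plus —
the canonical arrangement with the TA pair next to the resolution site.
"""

from tnta import SimSpec, load_reference_library, scan_genome, simulate_genome

library = load_reference_library()
spec = SimSpec(configuration="<T <A tnpR> tnpA>", identity=70.0, seed=1)
genome, truth = simulate_genome([spec], background_length=20_000, seed=1,
                                library=library)
print(f"simulated genome: {len(genome.sequence):,} bp, "
      f"1 planted module ({spec.configuration})")

for result in scan_genome(genome, library):
    locus = result.locus
    print(f"locus {locus.span[0]:,}-{locus.span[1]:,}: {locus.configuration}")
    print(f"  completeness={locus.completeness} subgroup={locus.subgroup} "
          f"resolvase={locus.resolvase_type} ta_order={locus.ta_order}")
    if result.res_site:
        print(f"  res site {result.res_site.region}, "
              f"crossover AT at {result.res_site.crossover}, "
              f"TA adjacent to subsite I: {result.res_site.ta_adjacent}")
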