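"""Demos that require downloading real accession sequences.

Quantities that depend on external sequence databases are not reproduced
by the test suite or the acceptance script: the 190-member transposon
census, the 27 predicted res sites, published tree topologies, and the
TA-module DNA identity between named transposons (e.g. the ~95% figure
for the TnTsp1 vs Tn5501 comparison, accessions NC_014154 / JN648090.1).
This script sketches that comparison but refuses to run without an
explicit network opt-in, since fetching is environment-dependent and
unverifiable offline.

Usage:  python examples/real_accession_demo.py --fetch
"""

import argparse
import sys


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fetch", action="store_true",
                        help="allow network access to download accessions")
    args = parser.parse_args()
    if not args.fetch:
        print("This demo downloads accession sequences from NCBI and is not "
              "reproducible offline.\nRe-run with --fetch to opt in.",
              file=sys.stderr)
        return 2

    from urllib.request import urlopen

    from tnta import identity_profile, load_reference_library, scan_genome, \
        ta_module_identity
    from tnta.io import SeqRecord

    def fetch(accession: str) -> SeqRecord:
        url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
               f"?db=nuccore&id={accession}&rettype=fasta&retmode=text")
        lines = urlopen(url).read().decode().splitlines()
        return SeqRecord(id=accession, sequence="".join(lines[1:]))

    library = load_reference_library()
    tn5501 = fetch("JN648090.1")
    tntsp1 = fetch("NC_014154")
    loci = {}
    for rec in (tn5501, tntsp1):
        full = [r.locus for r in scan_genome(rec, library)
                if r.locus.members_with_role("toxin")]
        if not full:
            print(f"{rec.id}: no TA locus found with the synthetic exemplar "
                  "library (expected: it is a stand-in, not a curated set)")
            return 0
        loci[rec.id] = full[0]
    identity = ta_module_identity(loci["JN648090.1"], tn5501.sequence,
                                  loci["NC_014154"], tntsp1.sequence)
    print(f"TA-module DNA identity TnTsp1 vs Tn5501: {identity:.1f}%")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
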