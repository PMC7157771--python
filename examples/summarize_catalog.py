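"""Aggregate the packaged census of TA-carrying Tn3 transposons.

Loads the packaged catalog (one row per toxin/antitoxin/resolvase/subgroup
combination with its member transposons) and prints the headline counts:
total instances, family diversity, distinct toxin-antitoxin pairs, and the
reversed-order (toxin-gene-first) arrangements by subgroup.
"""

from tnta import aggregate_counts, load_catalog

rows = load_catalog()
print(f"catalog: {len(rows)} rows, "
      f"{sum(r.nb for r in rows)} transposon instances")

summary = aggregate_counts(rows)
print(f"toxin families: {summary.n_toxin_families}")
print(f"antitoxin families (variant labels merged): {summary.n_antitoxin_families}")
print(f"distinct TA pairs: {summary.n_distinct_pairs}")
for (toxin, antitoxin), count in summary.pair_counts.items():
    print(f"  {toxin}-{antitoxin}: {count}")
print(f"TA gene order: {summary.ta_order_counts}")
print(f"reversed order by subgroup: {summary.reversed_by_subgroup}")
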