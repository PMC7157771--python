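"""Locate an intertransposon recombination junction at res subsite I.

Two parent transposons share their res subsite I but are otherwise 60%
identical at the DNA level — the situation in which resolvase-mediated
recombination can swap transposon halves and exchange TA modules. The
chimera of the two is compared with parent A: the windowed identity
profile is ~1.0 left of the junction and ~0.6 right of it, and the
two-segment change-point fit localises the junction to within about half
a window of the planted crossover AT.
"""

from tnta import detect_breakpoint, identity_profile
from tnta.simulate import simulate_chimera, simulate_chimera_pair

rec_a, truth_a, rec_b, truth_b = simulate_chimera_pair(seed=9)
chimera, truth_c = simulate_chimera(rec_a, truth_a, rec_b, truth_b)
print(f"parents: {len(rec_a.sequence):,} bp, 60% mutual identity, "
      f"shared res subsite I; junction planted at {truth_c.junction:,}")

profile = identity_profile(rec_a.sequence, chimera.sequence)
bp = detect_breakpoint(profile)
print(f"detected breakpoint at {bp.position:,.0f} "
      f"(truth {truth_c.junction:,}, error {bp.position - truth_c.junction:+.0f} bp)")
print(f"segment identities: left {bp.left_identity:.3f}, right {bp.right_identity:.3f}")
print(f"confidence interval: {bp.confidence_interval[0]:,.0f}-"
      f"{bp.confidence_interval[1]:,.0f}")
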