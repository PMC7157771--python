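"""Dot-plot word matching, identity profiles and breakpoint detection."""

import numpy as np
import pytest

import oracles
from tnta.compare import (IdentityProfile, detect_breakpoint, dotplot_matches,
                          identity_profile, ta_module_identity)
from tnta.io import revcomp
from tnta.pipeline import scan_genome
from tnta.simulate import (SimSpec, mutate_to_identity, simulate_chimera,
                           simulate_chimera_pair, simulate_genome)


def _random_dna(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


class TestDotplot:
    def test_self_comparison_gives_full_diagonal(self):
        seq = _random_dna(1, 50)
        ml = dotplot_matches(seq, seq, wordsize=10)
        diagonal = [(a, b) for a, b, s in ml.matches if s == "+" and a == b]
        assert len(diagonal) == 41  # n - w + 1

    def test_reverse_complement_gives_antidiagonal(self):
        seq = _random_dna(2, 60)
        ml = dotplot_matches(seq, revcomp(seq), wordsize=10)
        minus = [(a, b) for a, b, s in ml.matches if s == "-"]
        n, w = 60, 10
        assert {(a, n - w - a) for a in range(n - w + 1)} <= set(minus)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_matches_equal_bruteforce_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        # low-cardinality alphabet draw raises the chance of shared words
        a = "".join(rng.choice(list("ACG"), size=150))
        b = "".join(rng.choice(list("ACG"), size=150))
        got = set(dotplot_matches(a, b, wordsize=6).matches)
        assert got == oracles.shared_words(a, b, 6)

    def test_transpose_symmetry(self):
        a, b = _random_dna(3, 200), _random_dna(4, 200)
        ab = set(dotplot_matches(a, b, wordsize=8).matches)
        ba = set(dotplot_matches(b, a, wordsize=8).matches)
        assert {(j, i, s) for i, j, s in ab} == ba


class TestIdentityProfile:
    def test_identical_sequences_profile_is_one(self):
        seq = _random_dna(5, 1000)
        profile = identity_profile(seq, seq)
        assert np.all(profile.identity == 1.0)
        assert np.all(np.diff(profile.centers) > 0)

    def test_uniform_mutation_matches_binomial_expectation(self):
        seq = _random_dna(6, 2000)
        mutated = mutate_to_identity(seq, 90.0, seed=5)
        profile = identity_profile(seq, mutated)
        assert 0.85 <= float(profile.identity.mean()) <= 0.95

    def test_shared_prefix_is_perfect_in_concatenation(self):
        seq = _random_dna(7, 800)
        extended = seq + _random_dna(8, 300)
        profile = identity_profile(seq, extended)
        assert np.all(profile.identity[: len(profile.centers) // 2] == 1.0)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            identity_profile("ACGT", "ACGT")


class TestDetectBreakpoint:
    def test_flat_profiles_yield_null(self):
        centers = np.arange(50.0, 1050.0, 10.0)
        flat_high = IdentityProfile(100, 10, centers, np.ones(len(centers)))
        flat_low = IdentityProfile(100, 10, centers, np.full(len(centers), 0.5))
        assert detect_breakpoint(flat_high) is None
        assert detect_breakpoint(flat_low) is None

    def test_sharp_transition_located(self):
        centers = np.arange(50.0, 2050.0, 10.0)
        identity = np.where(centers < 1200, 1.0, 0.6)
        profile = IdentityProfile(100, 10, centers, identity)
        bp = detect_breakpoint(profile)
        assert bp is not None
        assert abs(bp.position - 1200) <= 10
        assert bp.confidence_interval[0] <= bp.position <= bp.confidence_interval[1]

    def test_short_profile_rejected(self):
        profile = IdentityProfile(100, 10, np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            detect_breakpoint(profile)

    @pytest.mark.parametrize("seed", range(15))
    def test_simulated_res_chimera_junction_recovered(self, library, seed):
        rec_a, truth_a, rec_b, truth_b = simulate_chimera_pair(seed, library=library)
        chimera, truth_c = simulate_chimera(rec_a, truth_a, rec_b, truth_b)
        profile = identity_profile(rec_a.sequence, chimera.sequence)
        bp = detect_breakpoint(profile)
        assert bp is not None
        assert abs(bp.position - truth_c.junction) <= profile.window / 2 + profile.step

    def test_identical_parents_make_undetectable_chimera(self, library):
        spec = SimSpec(seed=3)
        from tnta.simulate import simulate_transposon
        rec, truth = simulate_transposon(spec, library)
        chimera, _ = simulate_chimera(rec, truth, rec, truth)
        assert chimera.sequence == rec.sequence
        assert detect_breakpoint(identity_profile(rec.sequence, chimera.sequence)) is None

    def test_custom_junction_recorded(self, library):
        from tnta.simulate import simulate_transposon
        rec, truth = simulate_transposon(SimSpec(seed=4), library)
        rec2, truth2 = simulate_transposon(SimSpec(seed=5), library)
        _, truth_c = simulate_chimera(rec, truth, rec2, truth2, junction=1200)
        assert truth_c.junction == 1200


class TestTaModuleIdentity:
    def _full_locus(self, library, seed, identity=85.0):
        spec = SimSpec(identity=identity, seed=seed)
        genome, _ = simulate_genome([spec], background_length=12_000, seed=seed,
                                    library=library)
        results = scan_genome(genome, library, scan_res=False)
        locus = [r.locus for r in results if r.locus.completeness == "full_with_TA"][0]
        return locus, genome.sequence

    def test_identical_modules_are_100pct(self, library):
        locus, seq = self._full_locus(library, 41)
        assert ta_module_identity(locus, seq, locus, seq) == pytest.approx(100.0)

    def test_diverged_copy_tracks_mutation_load(self, library):
        locus, seq = self._full_locus(library, 42)
        mutated = mutate_to_identity(seq, 95.0, seed=42)
        got = ta_module_identity(locus, seq, locus, mutated)
        assert 93.0 <= got <= 97.0

    def test_unrelated_modules_are_dissimilar(self, library):
        locus_a, seq_a = self._full_locus(library, 43, identity=55.0)
        locus_b, seq_b = self._full_locus(library, 44, identity=55.0)
        assert ta_module_identity(locus_a, seq_a, locus_b, seq_b) < 60.0

    def test_missing_ta_pair_rejected(self, library):
        locus, seq = self._full_locus(library, 45)
        locus.members = [h for h in locus.members if h.role != "toxin"]
        with pytest.raises(ValueError):
            ta_module_identity(locus, seq, locus, seq)
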