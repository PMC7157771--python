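"""Inverted-repeat scanning, res-site assembly, crossover location."""

import numpy as np
import pytest

import oracles
from tnta.io import revcomp
from tnta.pipeline import scan_genome
from tnta.resscan import (IRMotif, assemble_res_site, extract_search_region,
                          find_inverted_repeats, locate_crossover)
from tnta.simulate import SimSpec, simulate_genome


def test_perfect_palindrome_found_with_zero_mismatches():
    arm = "GCTAGGCTAC"
    seq = "TTTTT" + arm + "ACGA" + revcomp(arm) + "TTTTT"
    motifs = find_inverted_repeats(seq, max_mismatch=0)
    top = motifs[0]
    assert top.mismatches == 0
    assert top.arm_len == 10
    assert top.span == (5, 29)
    assert top.score == 10


def test_poly_a_has_no_motifs():
    assert find_inverted_repeats("A" * 60) == []


@pytest.mark.parametrize("seed", range(8))
def test_motif_set_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=120))
    got = {(m.left_arm[0], m.left_arm[1], m.right_arm[0], m.right_arm[1],
            m.mismatches) for m in find_inverted_repeats(seq)}
    assert got == oracles.inverted_repeats(seq, 8, 14, 0, 14, 3)


def test_sequence_shorter_than_two_arms_rejected():
    with pytest.raises(ValueError):
        find_inverted_repeats("ACGTACGTACGTACG")  # 15 < 2*8


class TestExtractSearchRegion:
    def _locus(self, library, config, seed=4):
        spec = SimSpec(configuration=config, identity=85.0, seed=seed)
        genome, truth = simulate_genome([spec], background_length=15_000,
                                        seed=seed, library=library)
        results = scan_genome(genome, library, scan_res=False)
        full = [r for r in results if r.locus.completeness == "full_with_TA"]
        return full[0].locus, genome, truth

    def test_region_contains_planted_res_site(self, library):
        locus, genome, truth = self._locus(library, "<T <A tnpR> tnpA>")
        region, offset = extract_search_region(locus, genome.sequence)
        res = truth.of_type("res_site")[0]
        assert offset <= res.start and res.end <= offset + len(region)

    def test_divergent_resolvase_region_between_genes(self, library):
        locus, genome, truth = self._locus(library, "<tnpR A> T> tnpA>")
        region, offset = extract_search_region(locus, genome.sequence)
        res = truth.of_type("res_site")[0]
        assert offset <= res.start and res.end <= offset + len(region)
        # region starts right at the divergent resolvase gene's end
        resolvase = locus.members_with_role("resolvase_S")[0]
        assert offset == resolvase.orf.end

    def test_colinear_region_clipped_to_window(self, library):
        locus, genome, _ = self._locus(library, "<T <A tnpR> tnpA>")
        region, offset = extract_search_region(locus, genome.sequence, window=400)
        assert len(region) <= 400

    def test_no_resolvase_fails(self, library):
        locus, genome, _ = self._locus(library, "<T <A tnpR> tnpA>")
        locus.members = [h for h in locus.members if h.role != "resolvase_S"]
        with pytest.raises(ValueError):
            extract_search_region(locus, genome.sequence)


class TestAssembleResSite:
    def test_planted_triple_recovered_with_correct_labels(self, library):
        spec = SimSpec(configuration="<T <A tnpR> tnpA>", identity=85.0, seed=21)
        genome, truth = simulate_genome([spec], background_length=15_000,
                                        seed=21, library=library)
        result = scan_genome(genome, library)[0]
        site = result.res_site
        assert site is not None and not site.partial
        for label in ("I", "II", "III"):
            planted = truth.of_type(f"res_subsite_{label}")[0]
            got = site.subsites[label].span
            inter = max(0, min(got[1], planted.end) - max(got[0], planted.start))
            union = max(got[1], planted.end) - min(got[0], planted.start)
            assert inter / union >= 0.8, (label, got, (planted.start, planted.end))

    def test_single_motif_yields_none_without_allow_partial(self):
        motif = IRMotif((0, 10), (14, 24), 0)
        assert assemble_res_site([motif], 500, (0, 100)) is None
        partial = assemble_res_site([motif, IRMotif((30, 40), (44, 54), 0)],
                                    500, (0, 100), allow_partial=True)
        assert partial is not None and partial.partial
        assert set(partial.subsites) == {"I", "III"}

    def test_motif_permutation_invariance(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        motifs = find_inverted_repeats(seq)
        if len(motifs) < 3:
            pytest.skip("no triple in this draw")
        baseline = assemble_res_site(motifs, 400, (0, 300))
        for _ in range(10):
            shuffled = list(motifs)
            rng.shuffle(shuffled)
            again = assemble_res_site(shuffled, 400, (0, 300))
            assert (baseline is None) == (again is None)
            if baseline is not None:
                assert again.subsites == baseline.subsites


class TestLocateCrossover:
    def test_single_central_at(self):
        site = IRMotif((0, 4), (6, 10), 0)
        assert locate_crossover(site, "GGGGATCCCC") == 4

    def test_equidistant_tie_goes_left(self):
        #           0123456789
        seq = "GATGGGGATG"
        site = IRMotif((0, 4), (6, 10), 0)
        # centre start is 4; ATs at 1 and 7, both 3 away: leftmost wins
        assert locate_crossover(site, seq) == 1

    def test_no_at_returns_none(self):
        site = IRMotif((0, 4), (6, 10), 0)
        assert locate_crossover(site, "GGGGGGGGGG") is None

    @pytest.mark.parametrize("seed", range(25))
    def test_planted_crossover_recovered_exactly(self, library, seed):
        spec = SimSpec(configuration="<T <A tnpR> tnpA>", identity=85.0,
                       seed=1000 + seed)
        genome, truth = simulate_genome([spec], background_length=12_000,
                                        seed=1000 + seed, library=library)
        result = scan_genome(genome, library)[0]
        assert result.res_site is not None
        planted = truth.of_type("crossover_AT")[0].start
        assert result.res_site.crossover == planted


def test_ta_adjacency_true_for_canonical_and_false_when_ta_beyond_tnpa(library):
    spec = SimSpec(configuration="<T <A tnpR> tnpA>", identity=85.0, seed=31)
    genome, _ = simulate_genome([spec], background_length=12_000, seed=31,
                                library=library)
    result = scan_genome(genome, library)[0]
    assert result.res_site.ta_adjacent is True

    # TA genes on the far side of tnpA: nearest gene flanking subsite I on
    # the non-resolvase side is the transposase, not the TA pair
    spec2 = SimSpec(configuration="<tnpR tnpA> T> A>", identity=85.0, seed=32)
    genome2, _ = simulate_genome([spec2], background_length=12_000, seed=32,
                                 library=library)
    results2 = scan_genome(genome2, library)
    full = [r for r in results2 if r.res_site is not None]
    assert full and full[0].res_site.ta_adjacent is False
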