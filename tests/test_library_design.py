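"""Degenerate-codon expansion, diversity counts and library-size bounds."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from fn3kit.library_design import (
    DegenerateCodon,
    LoopDesign,
    LibraryDesign,
    aa_distribution,
    collision_diversity_bound,
    default_library_design,
    design_loop_oligos,
    expand_degenerate_codon,
    stop_free_fraction,
    theoretical_diversity,
)
from fn3kit.scaffold import default_scaffold

IUPAC_LETTERS = "ACGTRYSWKMBDHVN"


class TestExpansion:
    @pytest.mark.parametrize("codon,n", [("NNK", 32), ("ATG", 1), ("NNN", 64)])
    def test_expansion_size(self, codon, n):
        exp = expand_degenerate_codon(codon)
        assert len(exp) == n
        assert all(p == Fraction(1, n) for _, p in exp)
        assert len({c for c, _ in exp}) == n

    def test_atg_is_trivial(self):
        assert expand_degenerate_codon("ATG") == [("ATG", Fraction(1))]

    def test_rejects_non_iupac(self):
        with pytest.raises(ValueError):
            DegenerateCodon("NXK")
        with pytest.raises(ValueError):
            DegenerateCodon("NNKA")

    @given(st.text(alphabet=IUPAC_LETTERS, min_size=3, max_size=3))
    @settings(deadline=None, max_examples=60)
    def test_probabilities_sum_to_one(self, codon):
        total = sum(p for _, p in expand_degenerate_codon(codon))
        assert total == 1


class TestAaDistribution:
    def test_nnk_amber_only_stop(self):
        # oracle: among the 32 NNK codons the only stop is amber TAG
        dist = aa_distribution("NNK")
        assert dist["*"] == Fraction(1, 32)
        assert dist["W"] == Fraction(1, 32)  # TGG is the single Trp codon
        assert len([aa for aa in dist if aa != "*"]) == 20

    def test_fixed_codon(self):
        assert aa_distribution("TGG") == {"W": Fraction(1)}

    def test_amber_suppression_moves_mass_to_gln(self):
        dist = aa_distribution("NNK", amber_suppression=True)
        assert "*" not in dist
        assert dist["Q"] == Fraction(2, 32)  # CAG plus read-through TAG

    @given(st.text(alphabet=IUPAC_LETTERS, min_size=3, max_size=3))
    @settings(deadline=None, max_examples=60)
    def test_marginals_sum_to_one(self, codon):
        assert sum(aa_distribution(codon).values()) == 1


class TestOligoDesign:
    def test_bc_design_has_five_oligos(self, scaffold):
        design = LoopDesign("BC", anchor_codon_position=25, length_range=(5, 9))
        oligos = design_loop_oligos(design, scaffold)
        assert len(oligos) == 5
        assert [o.n_random_codons for o in oligos] == [5, 6, 7, 8, 9]

    def test_fg_design_has_seven_oligos(self, scaffold):
        design = LoopDesign("FG", anchor_codon_position=75, length_range=(7, 13))
        oligos = design_loop_oligos(design, scaffold)
        assert len(oligos) == 7

    def test_single_length_single_oligo(self, scaffold):
        design = LoopDesign("BC", anchor_codon_position=25, length_range=(3, 3))
        assert len(design_loop_oligos(design, scaffold)) == 1

    def test_oligo_structure(self, scaffold):
        design = LoopDesign("BC", anchor_codon_position=25, length_range=(5, 5))
        (oligo,) = design_loop_oligos(design, scaffold, flank_len=6)
        assert oligo.sequence == scaffold.five_flank("BC") + "NNK" * 5 + scaffold.three_flank("BC")

    @given(lo=st.integers(1, 6), span=st.integers(0, 6))
    @settings(deadline=None, max_examples=30)
    def test_oligo_count_is_range_width(self, scaffold, lo, span):
        design = LoopDesign("BC", anchor_codon_position=25, length_range=(lo, lo + span))
        assert len(design_loop_oligos(design, scaffold)) == span + 1

    def test_flank_outside_scaffold_raises(self, scaffold):
        design = LoopDesign("BC", anchor_codon_position=25, length_range=(5, 5))
        with pytest.raises(ValueError):
            design_loop_oligos(design, scaffold, flank_len=40)


class TestDiversity:
    def test_single_nnk_protein_stop_free(self, scaffold):
        lib = LibraryDesign(None, (LoopDesign("BC", 25, (1, 1)),))
        count, _ = theoretical_diversity(lib, "protein", stop_free=True)
        assert count == 20

    def test_two_nnk_dna(self):
        lib = LibraryDesign(None, (LoopDesign("BC", 25, (2, 2)),))
        count, _ = theoretical_diversity(lib, "dna")
        assert count == 32 ** 2 == 1024

    def test_full_design_matches_bigint_oracle(self, scaffold):
        lib = default_library_design(scaffold)
        count, log10 = theoretical_diversity(lib, "dna")
        oracle = sum(32 ** l for l in range(5, 10)) * sum(32 ** m for m in range(7, 14))
        assert count == oracle
        assert log10 == pytest.approx(math.log10(oracle))

    def test_protein_never_exceeds_dna(self, scaffold):
        lib = default_library_design(scaffold)
        dna, _ = theoretical_diversity(lib, "dna")
        prot, _ = theoretical_diversity(lib, "protein", stop_free=True)
        assert prot <= dna

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            LibraryDesign(None, ())


class TestStopFreeFraction:
    def test_single_nnk(self):
        lib = LibraryDesign(None, (LoopDesign("BC", 25, (1, 1)),))
        assert stop_free_fraction(lib) == pytest.approx(31 / 32)

    def test_twelve_nnk_product(self, scaffold):
        lib = default_library_design(scaffold)
        frac = stop_free_fraction(lib, fixed_lengths={"BC": 5, "FG": 7})
        assert frac == pytest.approx((31 / 32) ** 12)

    def test_length_average(self):
        lib = LibraryDesign(None, (LoopDesign("BC", 25, (1, 2)),))
        expected = ((31 / 32) + (31 / 32) ** 2) / 2
        assert stop_free_fraction(lib) == pytest.approx(expected)


class TestCollisionBound:
    def test_two_distinct_draws(self):
        assert collision_diversity_bound(2, 0, 0.5) == 2

    def test_96_colonies_matches_product_oracle(self):
        d = collision_diversity_bound(96, 0, 0.95)
        # oracle: exact product P(no collision) crosses 0.05 exactly at d
        def p(div):
            return math.exp(sum(math.log1p(-i / div) for i in range(96)))
        assert p(d) >= 0.05 > p(d - 1)

    def test_all_identical_gives_one(self):
        assert collision_diversity_bound(96, 95, 0.95) == 1

    def test_monotone_in_sample_size(self):
        bounds = [collision_diversity_bound(n, 0, 0.95) for n in (10, 30, 96, 200)]
        assert bounds == sorted(bounds)

    def test_confidence_validation(self):
        with pytest.raises(ValueError):
            collision_diversity_bound(10, 0, 1.5)
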