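import pytest
from hypothesis import given
from hypothesis import strategies as st

from palmshell import (
    AlleleClass,
    Diplotype,
    Haplotype,
    IncompleteGenotypeError,
    LocusCall,
    MultiLocusGenotype,
    classify_allele,
    enumerate_phasings,
    functional_copies_phased,
    functional_copy_bounds,
    mutant_burden,
    mutant_haplotype,
    wildtype_haplotype,
)

from conftest import all_zygosity_states, make_genotype


class TestClassifyAllele:
    @pytest.mark.parametrize("vid, allele, expected", [
        ("sh_AVROS", "T", AlleleClass.KNOWN_MUTANT),
        ("sh_AVROS", "A", AlleleClass.WILDTYPE),
        ("sh_MPOB", "T", AlleleClass.WILDTYPE),
        ("sh_MPOB", "C", AlleleClass.KNOWN_MUTANT),
        ("sh_MPOB3", "G", AlleleClass.NOVEL_MUTANT),
        ("sh_AVROS", "G", AlleleClass.NOVEL_MUTANT),
    ])
    def test_examples(self, panel, vid, allele, expected):
        assert classify_allele(panel, vid, allele) is expected

    def test_errors(self, panel):
        with pytest.raises(KeyError):
            classify_allele(panel, "sh_UNKNOWN", "A")
        with pytest.raises(ValueError):
            classify_allele(panel, "sh_AVROS", "N")


class TestLocusCall:
    def test_parse_separators(self):
        assert LocusCall.parse("x", "A/T") == LocusCall("x", "A", "T", phased=False)
        assert LocusCall.parse("x", "A|T") == LocusCall("x", "A", "T", phased=True)
        assert LocusCall.parse("x", "./.").is_missing

    def test_half_missing_rejected(self):
        with pytest.raises(ValueError):
            LocusCall("x", "A", ".")


class TestMutantBurden:
    def test_all_wildtype(self, panel, retest_cohort):
        v907 = next(r for r in retest_cohort if r.sample_id == "V907")
        assert mutant_burden(v907.genotype, panel) == (0, 0)

    def test_triple_heterozygote(self, panel, retest_cohort):
        v121 = next(r for r in retest_cohort if r.sample_id == "V121")
        assert mutant_burden(v121.genotype, panel) == (3, 0)

    def test_homozygous_mutant(self, panel, retest_cohort):
        v152 = next(r for r in retest_cohort if r.sample_id == "V152")
        assert mutant_burden(v152.genotype, panel) == (0, 1)

    def test_missing_call_signals_incomplete(self, panel):
        g = MultiLocusGenotype("s", {})
        with pytest.raises(IncompleteGenotypeError):
            mutant_burden(g, panel)


class TestFunctionalCopiesPhased:
    def test_zygosity_cases(self, panel):
        wt = wildtype_haplotype(panel)
        avros = mutant_haplotype(panel, "sh_AVROS")
        mpob = mutant_haplotype(panel, "sh_MPOB")
        cis = mutant_haplotype(panel, "sh_MPOB", "sh_AVROS")
        assert functional_copies_phased(Diplotype(wt, wt), panel) == 2
        assert functional_copies_phased(Diplotype(wt, avros), panel) == 1
        assert functional_copies_phased(Diplotype(mpob, avros), panel) == 0
        # cis-compound carrier keeps one functional copy
        assert functional_copies_phased(Diplotype(cis, wt), panel) == 1

    @given(st.data())
    def test_invariant_under_haplotype_swap(self, panel, data):
        alleles = st.sampled_from("ACGT")
        h1 = Haplotype(tuple(data.draw(alleles) for _ in range(5)))
        h2 = Haplotype(tuple(data.draw(alleles) for _ in range(5)))
        assert (functional_copies_phased(Diplotype(h1, h2), panel)
                == functional_copies_phased(Diplotype(h2, h1), panel))


class TestCopyBounds:
    @pytest.mark.parametrize("counts, expected", [
        ({}, (2, 2)),
        ({"sh_AVROS": 1}, (1, 1)),                      # e.g. V646, observed tenera
        ({"sh_MPOB4": 1, "sh_MPOB": 1, "sh_AVROS": 1}, (0, 1)),  # V121 three hets
        ({"sh_AVROS": 2}, (0, 0)),                      # V152, observed pisifera
        ({"sh_MPOB": 1, "sh_AVROS": 2}, (0, 0)),
    ])
    def test_closed_form_examples(self, panel, counts, expected):
        bounds = functional_copy_bounds(make_genotype(panel, counts), panel)
        assert (bounds.min_copies, bounds.max_copies) == expected

    def test_missing_calls_raise(self, panel):
        g = MultiLocusGenotype("s", {"sh_AVROS": LocusCall("sh_AVROS", "A", "T")})
        with pytest.raises(IncompleteGenotypeError):
            functional_copy_bounds(g, panel)

    def test_fully_phased_genotype_collapses_bounds(self, panel):
        # trans-phased double het: both orientations are pinned, 0 copies
        calls = {}
        for v in panel:
            a = b = v.wildtype_allele
            if v.id == "sh_AVROS":
                a = "T"
            if v.id == "sh_MPOB":
                b = "C"
            calls[v.id] = LocusCall(v.id, a, b, phased=True)
        bounds = functional_copy_bounds(MultiLocusGenotype("s", calls), panel)
        assert (bounds.min_copies, bounds.max_copies) == (0, 0)
        # cis-phased: both mutations on haplotype 1, one copy survives
        calls2 = {
            v.id: LocusCall(
                v.id,
                {"sh_AVROS": "T", "sh_MPOB": "C"}.get(v.id, v.wildtype_allele),
                v.wildtype_allele,
                phased=True,
            )
            for v in panel
        }
        bounds2 = functional_copy_bounds(MultiLocusGenotype("s", calls2), panel)
        assert (bounds2.min_copies, bounds2.max_copies) == (1, 1)


class TestEnumeratePhasings:
    @pytest.mark.parametrize("counts, n_expected", [
        ({}, 1),
        ({"sh_AVROS": 1}, 1),
        ({"sh_AVROS": 1, "sh_MPOB": 1}, 2),  # cis and trans
        ({"sh_AVROS": 1, "sh_MPOB": 1, "sh_MPOB4": 1}, 4),
        ({"sh_AVROS": 2, "sh_MPOB": 1}, 1),
    ])
    def test_counts(self, panel, counts, n_expected):
        # 2^(h-1) unordered diplotypes for h het loci, 1 when h = 0
        assert len(enumerate_phasings(make_genotype(panel, counts), panel)) == n_expected


class TestOracleEquivalence:
    def test_bounds_match_enumeration_on_every_state(self, panel):
        """Closed-form bounds equal brute-force min/max over all phasings,
        for each of the 3^5 unphased zygosity states."""
        for state in all_zygosity_states(panel):
            g = make_genotype(panel, state)
            bounds = functional_copy_bounds(g, panel)
            copies = [functional_copies_phased(d, panel)
                      for d in enumerate_phasings(g, panel)]
            assert bounds.min_copies == min(copies)
            assert bounds.max_copies == max(copies)

    def test_bounds_exact_iff_hom_or_single_het(self, panel):
        for state in all_zygosity_states(panel):
            g = make_genotype(panel, state)
            n_het, n_hom = mutant_burden(g, panel)
            bounds = functional_copy_bounds(g, panel)
            assert bounds.is_exact == (n_hom >= 1 or n_het <= 1)

    def test_restricting_panel_never_decreases_bounds(self, panel):
        sub = panel.restrict(["sh_MPOB", "sh_AVROS"])
        for state in all_zygosity_states(panel):
            g = make_genotype(panel, state)
            full = functional_copy_bounds(g, panel)
            part = functional_copy_bounds(g, sub)
            assert part.min_copies >= full.min_copies
            assert part.max_copies >= full.max_copies
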