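import numpy as np
import pytest

from palmshell import (
    CohortConfig,
    FruitForm,
    HiddenMutation,
    RectificationStatus,
    evaluate,
    rectify,
)
from palmshell.synthetic import (
    AccessionDrawFamily,
    CrossFamily,
    StratifiedFamilyGroup,
    first_validation_config,
    hybrid_cross_config,
    load_config,
    retest_fixture,
    simulate_cohort,
    write_cohort,
)


class TestRetestFixture:
    def test_spot_checks(self):
        by_id = {r.sample_id: r for r in retest_fixture()}
        assert by_id["V121"].genotype.call_for("sh_MPOB4").alleles == ("T", "A")
        assert by_id["V152"].genotype.call_for("sh_AVROS").alleles == ("T", "T")
        v927 = by_id["V927"]
        assert v927.observed_form is FruitForm.TENERA
        assert all(
            v927.genotype.call_for(v).alleles.count(w) == 2
            for v, w in [("sh_MPOB2", "A"), ("sh_MPOB4", "A"), ("sh_MPOB", "T"),
                         ("sh_AVROS", "A"), ("sh_MPOB3", "C")]
        )

    def test_thirteen_unique_palms(self):
        records = retest_fixture()
        assert len(records) == 13
        assert len({r.sample_id for r in records}) == 13


class TestFirstValidationCohort:
    def test_counts_match_study_design(self):
        records, truth = simulate_cohort(first_validation_config(), seed=3)
        assert len(records) == 587
        marginals = truth["true_form"].value_counts().to_dict()
        assert marginals == {"dura": 120, "tenera": 305, "pisifera": 162}
        assert truth["family"].nunique() == 42

    def test_accession_variant_structure(self, panel):
        records, _ = simulate_cohort(first_validation_config(), seed=3)
        ekona = [r.genotype for r in records if r.accession == "Ekona"]
        # Ekona carries sh_MPOB only: no sh_AVROS mutant allele anywhere
        assert all(g.call_for("sh_AVROS").alleles == ("A", "A") for g in ekona)
        hybrid = [r.genotype for r in records if r.accession == "AVROS-SP x Ekona"]
        assert any(g.call_for("sh_AVROS").is_het for g in hybrid)
        assert any(g.call_for("sh_MPOB").is_het for g in hybrid)

    def test_perfect_generator_gives_perfect_copies_accuracy(self, panel):
        for seed in (0, 1, 2):
            records, _ = simulate_cohort(first_validation_config(), seed=seed)
            report = evaluate(records, panel, method="copies")
            assert report.total.accuracy_percent == 100.00


class TestDeterminismAndNoise:
    def test_same_seed_byte_identical_outputs(self, panel, tmp_path):
        cfg = hybrid_cross_config(50, phenotyping_error_rate=0.1)
        files = []
        for run in ("a", "b"):
            records, truth = simulate_cohort(cfg, seed=9)
            files.append(write_cohort(records, truth, panel, tmp_path / run))
        for key in ("vcf", "phenotypes", "truth"):
            assert files[0][key].read_bytes() == files[1][key].read_bytes()

    def test_observed_differs_from_truth_only_on_flagged_errors(self):
        _, truth = simulate_cohort(hybrid_cross_config(500, phenotyping_error_rate=0.2),
                                   seed=4)
        mism = truth["true_form"] != truth["observed_form"]
        assert (mism == truth["phenotyping_error"]).all()

    def test_error_rate_recovered(self):
        n, eps = 2000, 0.05
        _, truth = simulate_cohort(hybrid_cross_config(n, phenotyping_error_rate=eps),
                                   seed=6)
        rate = float(truth["phenotyping_error"].mean())
        assert abs(rate - eps) < 3 * np.sqrt(eps * (1 - eps) / n)

    def test_founder_pool_frequency_recovered(self, panel):
        n = 1000
        cfg = CohortConfig(panel=panel,
                           families=[AccessionDrawFamily("AVROS", n, "F1")], seed=0)
        records, _ = simulate_cohort(cfg, seed=12)
        alleles = [a for r in records for a in r.genotype.call_for("sh_AVROS").alleles]
        freq = alleles.count("T") / (2 * n)
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / (2 * n))


class TestHiddenMutation:
    def test_hidden_carriers_surface_as_rectification_misses(self, panel):
        cfg = CohortConfig(
            panel=panel,
            families=[AccessionDrawFamily("AVROS", 200, "F1")],
            hidden_mutation=HiddenMutation(frequency=0.05),
            seed=0,
        )
        records, truth = simulate_cohort(cfg, seed=21)
        assert truth["hidden_carrier"].sum() >= 1
        initial = panel.restrict(["sh_MPOB", "sh_AVROS"])
        outcome = rectify(records, initial, panel)
        assert outcome.counts()[RectificationStatus.MISS] >= 1
        # misses coincide with hidden carriers (no other noise injected)
        carriers = set(truth.loc[truth.hidden_carrier, "sample_id"])
        misses = {s.sample_id for s in outcome.samples
                  if s.status is RectificationStatus.MISS}
        assert misses <= carriers

    def test_hidden_site_absent_from_panel_genotypes(self, panel):
        cfg = CohortConfig(panel=panel,
                           families=[AccessionDrawFamily("AVROS", 20, "F1")],
                           hidden_mutation=HiddenMutation(frequency=1.0), seed=0)
        records, truth = simulate_cohort(cfg)
        assert truth["hidden_carrier"].all()
        for r in records:
            assert set(r.genotype.calls) == set(panel.ids)


class TestConfigValidation:
    def test_bad_rates_and_sizes_rejected(self, panel):
        with pytest.raises(ValueError):
            CohortConfig(panel, [], seed=0).validate()
        with pytest.raises(ValueError):
            CohortConfig(panel, [AccessionDrawFamily("AVROS", 0, "F")],
                         seed=0).validate()
        with pytest.raises(ValueError):
            CohortConfig(panel, [AccessionDrawFamily("AVROS", 5, "F")],
                         phenotyping_error_rate=1.5, seed=0).validate()
        with pytest.raises(ValueError):
            # tenera need a segregating variant
            StratifiedFamilyGroup("X", (), 1, 1, 0).validate(panel)

    def test_unknown_accession_model(self, panel):
        cfg = CohortConfig(panel, [AccessionDrawFamily("Atlantis", 5, "F")], seed=0)
        with pytest.raises(ValueError, match="Atlantis"):
            simulate_cohort(cfg)


class TestYamlConfig:
    def test_load_and_simulate(self, tmp_path, panel):
        cfg_path = tmp_path / "cohort.yaml"
        cfg_path.write_text(
            "panel: builtin\n"
            "seed: 11\n"
            "phenotyping_error_rate: 0.0\n"
            "hidden_mutation: {label: sh_hidden, frequency: 0.0}\n"
            "families:\n"
            "  - kind: stratified\n"
            "    accession: Congo\n"
            "    variants: [sh_AVROS]\n"
            "    forms: {dura: 3, tenera: 4, pisifera: 2}\n"
            "  - kind: cross\n"
            "    family_id: H1\n"
            "    accession: hybrid\n"
            "    parent1: WT|sh_AVROS\n"
            "    parent2: sh_MPOB|WT\n"
            "    size: 10\n"
            "  - kind: draw\n"
            "    accession: custom\n"
            "    size: 5\n"
            "    pool:\n"
            "      - {mutations: [], frequency: 0.75}\n"
            "      - {mutations: [sh_MPOB, sh_AVROS], frequency: 0.25}\n"
        )
        cfg = load_config(cfg_path)
        assert cfg.seed == 11
        records, truth = simulate_cohort(cfg)
        assert len(records) == 24  # 9 stratified + 10 cross + 5 draw
        again, _ = simulate_cohort(load_config(cfg_path))
        assert [(r.sample_id, r.observed_form) for r in again] == [
            (r.sample_id, r.observed_form) for r in records
        ]

    def test_unknown_family_kind(self, tmp_path):
        cfg_path = tmp_path / "bad.yaml"
        cfg_path.write_text("families:\n  - {kind: magic, size: 3}\n")
        with pytest.raises(ValueError, match="magic"):
            load_config(cfg_path)
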