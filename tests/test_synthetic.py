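"""Synthetic cohort generator: validity, reproducibility, analytic oracle."""

import math

import pytest

from comopat import (
    CohortConfig,
    PlantedDependency,
    build_transactions,
    expected_rule_metrics,
    filter_cohort,
    generate_cohort,
    rule_metrics,
    write_cohort,
)
from comopat.synthetic import CohortConfigError, UnknownLabelError, catalog_for


def _prevalence(config: CohortConfig, label: str) -> float:
    records = generate_cohort(config)
    cat = catalog_for(config)
    code = cat.code_of(label)
    return sum(code in r.icd10_codes for r in records[:config.n_patients]) / config.n_patients


def _tdb(config: CohortConfig):
    records = generate_cohort(config)
    cat = catalog_for(config)
    kept, _ = filter_cohort(records, cat)
    return build_transactions(kept, cat)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs, match", [
        (dict(n_patients=0), "n_patients"),
        (dict(male_fraction=1.2), "male_fraction"),
        (dict(missing_field_rate=-0.1), "missing_field_rate"),
        (dict(age_distribution=(((65, 74), 0.5), ((75, 84), 0.4))), "age_distribution"),
        (dict(disease_marginals={"A": 1.5}), "disease_marginals"),
    ])
    def test_invalid_config_names_offending_field(self, kwargs, match):
        with pytest.raises(CohortConfigError, match=match):
            CohortConfig(**kwargs)

    def test_target_in_own_sources_rejected(self):
        with pytest.raises(CohortConfigError):
            PlantedDependency(frozenset({"A"}), "A", 0.5)

    def test_backward_chain_rejected(self):
        # B's target feeds an earlier rule's source: overrides would not be a
        # forward chain, so the joint law would not be enumerable in order
        with pytest.raises(CohortConfigError):
            CohortConfig(
                disease_marginals={"A": 0.2, "B": 0.2, "C": 0.2},
                planted_rules=[
                    PlantedDependency(frozenset({"A"}), "C", 0.5),
                    PlantedDependency(frozenset({"B"}), "A", 0.5),
                ])


class TestGeneration:
    def test_marginal_recovery_within_three_binomial_se(self):
        cfg = CohortConfig(n_patients=1000, disease_marginals={"HTN": 0.13}, rng_seed=7)
        se = math.sqrt(0.13 * 0.87 / 1000)
        assert abs(_prevalence(cfg, "HTN") - 0.13) <= 3 * se

    def test_zero_marginal_never_present(self):
        cfg = CohortConfig(n_patients=500, disease_marginals={"D": 0.0}, rng_seed=3)
        assert _prevalence(cfg, "D") == 0.0

    def test_planted_conditional_recovered(self):
        cfg = CohortConfig(
            n_patients=20000, disease_marginals={"A": 0.2, "B": 0.05},
            planted_rules=[PlantedDependency(frozenset({"A"}), "B", 0.9)], rng_seed=11)
        records = generate_cohort(cfg)
        cat = catalog_for(cfg)
        a_code, b_code = cat.code_of("A"), cat.code_of("B")
        with_a = [r for r in records if a_code in r.icd10_codes]
        p_b_given_a = sum(b_code in r.icd10_codes for r in with_a) / len(with_a)
        se = math.sqrt(0.9 * 0.1 / len(with_a))
        assert abs(p_b_given_a - 0.9) <= 3 * se

    def test_every_record_has_index_code_and_min_age(self):
        cfg = CohortConfig(n_patients=200, rng_seed=5)
        for rec in generate_cohort(cfg):
            assert "C34" in rec.icd10_codes
            assert rec.age >= 65

    def test_deterministic_output_files(self, tmp_path):
        cfg = CohortConfig(n_patients=300, rng_seed=9, missing_field_rate=0.02,
                           duplicate_key_rate=0.01)
        a_csv, a_man = write_cohort(cfg, tmp_path / "a")
        b_csv, b_man = write_cohort(cfg, tmp_path / "b")
        assert a_csv.read_bytes() == b_csv.read_bytes()
        assert a_man.read_bytes() == b_man.read_bytes()

    def test_corruption_accounting_exact(self):
        cfg = CohortConfig(n_patients=1000, rng_seed=13,
                           missing_field_rate=0.05, duplicate_key_rate=0.03)
        records = generate_cohort(cfg)
        assert len(records) == 1000 + 30
        kept, report = filter_cohort(records, catalog_for(cfg))
        assert report.missing_field == 50
        assert report.duplicate_key == 30
        assert report.n_excluded == 50 + 30
        assert report.n_input == report.n_kept + report.n_excluded

    def test_corruption_does_not_change_clean_disease_patterns(self):
        base = CohortConfig(n_patients=400, rng_seed=21)
        noisy = CohortConfig(n_patients=400, rng_seed=21, missing_field_rate=0.1)
        clean_codes = {r.case_number: r.icd10_codes for r in generate_cohort(base)}
        for rec in generate_cohort(noisy):
            if rec.case_number is not None:
                assert rec.icd10_codes == clean_codes[rec.case_number]


class TestAnalyticOracle:
    def test_independent_pair_has_unit_lift(self):
        cfg = CohortConfig(disease_marginals={"A": 0.2, "B": 0.5})
        sup, conf, lift = expected_rule_metrics(cfg, {"A"}, "B")
        assert sup == pytest.approx(0.1)
        assert conf == pytest.approx(0.5)
        assert lift == pytest.approx(1.0)

    def test_forced_cooccurrence_has_unit_confidence(self):
        cfg = CohortConfig(disease_marginals={"A": 0.2, "B": 0.05},
                           planted_rules=[PlantedDependency(frozenset({"A"}), "B", 1.0)])
        _, conf, _ = expected_rule_metrics(cfg, {"A"}, "B")
        assert conf == 1.0

    def test_four_cell_enumeration(self):
        # joint law of (A, B): P(A)=0.2, P(B|A)=0.9, P(B|not A)=0.05
        # => P(AB)=0.18, P(B)=0.18+0.8*0.05=0.22, lift=0.9/0.22
        cfg = CohortConfig(disease_marginals={"A": 0.2, "B": 0.05},
                           planted_rules=[PlantedDependency(frozenset({"A"}), "B", 0.9)])
        sup, conf, lift = expected_rule_metrics(cfg, {"A"}, "B")
        assert sup == pytest.approx(0.18, abs=1e-12)
        assert conf == pytest.approx(0.9, abs=1e-12)
        assert lift == pytest.approx(0.9 / 0.22, abs=1e-12)

    def test_unknown_label_raises(self):
        cfg = CohortConfig(disease_marginals={"A": 0.2})
        with pytest.raises((UnknownLabelError, KeyError)):
            expected_rule_metrics(cfg, {"A"}, "nope")

    def test_chained_dependencies_match_simulation(self):
        """Distribution propagation agrees with a large simulated cohort."""
        cfg = CohortConfig(
            n_patients=20000,
            disease_marginals={"A": 0.3, "B": 0.05, "C": 0.1},
            planted_rules=[
                PlantedDependency(frozenset({"A"}), "B", 0.6),
                PlantedDependency(frozenset({"A", "B"}), "C", 0.8),
            ],
            rng_seed=17)
        sup, conf, lift = expected_rule_metrics(cfg, {"A", "B"}, "C")
        tdb = _tdb(cfg)
        e_sup, e_conf, e_lift = rule_metrics(tdb, {"A", "B"}, "C")
        n_ab = round(e_sup / e_conf * tdb.n_patients)
        se_conf = math.sqrt(conf * (1 - conf) / n_ab)
        assert abs(e_conf - conf) <= 3 * se_conf
        assert abs(e_sup - sup) <= 3 * math.sqrt(sup * (1 - sup) / tdb.n_patients)
        assert e_lift == pytest.approx(lift, rel=0.15)
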