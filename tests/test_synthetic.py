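import numpy as np
import pytest

from fcmalloc import UNSURE, ValidationError
from fcmalloc.synthetic import (
    FactorSpec,
    SyntheticConfig,
    bundled_panel_config,
    constant,
    exercise_trial_design,
    generate_cohort,
    inject_missing_factors,
    inject_missing_relationships,
    linear,
    normal,
    sedentary_cohort_config,
    uniform,
)


@pytest.fixture(scope="module")
def panel():
    return bundled_panel_config()


class TestGenerateCohort:
    def test_seeded_reproducibility(self, panel):
        a = generate_cohort(panel, 25, seed=7)
        b = generate_cohort(panel, 25, seed=7)
        assert a == b
        c = generate_cohort(panel, 25, seed=8)
        assert a != c

    def test_constant_factor_is_constant(self):
        cfg = SyntheticConfig(factors={"x": constant(0.4)}, answer_specs={})
        records, _ = generate_cohort(cfg, 30, seed=0)
        assert all(r.factor_values["x"] == 0.4 for r in records)

    def test_identity_linear_dependence(self):
        cfg = SyntheticConfig(
            factors={"x": uniform(), "y": linear("x", slope=1.0, intercept=0.0)},
            answer_specs={})
        records, _ = generate_cohort(cfg, 30, seed=1)
        assert all(r.factor_values["y"] == r.factor_values["x"] for r in records)

    def test_truncated_normal_sampler_mean(self):
        cfg = SyntheticConfig(factors={"x": normal(0.5, 0.1)}, answer_specs={})
        records, _ = generate_cohort(cfg, 10_000, seed=2)
        vals = np.array([r.factor_values["x"] for r in records])
        assert abs(vals.mean() - 0.5) < 0.01
        assert vals.min() >= 0 and vals.max() <= 1

    def test_sedentary_exercise_skew(self, panel):
        records, _ = generate_cohort(panel, 4000, seed=3)
        ex = np.array([r.factor_values["exercise"] for r in records])
        # most individuals sedentary: right-skewed with low median
        assert np.median(ex) < np.mean(ex)
        assert np.median(ex) < 0.35

    def test_cyclic_dependence_rejected(self):
        cfg = SyntheticConfig(
            factors={"x": linear("y"), "y": linear("x")}, answer_specs={})
        with pytest.raises(ValidationError):
            generate_cohort(cfg, 5, seed=0)

    def test_answer_frequencies_match_configured_probabilities(self, panel):
        design = exercise_trial_design()
        pair = sorted(design.active_relationships)[0]
        _, answers = generate_cohort(panel, 10_000, seed=4)
        spec = panel.answer_specs[pair]
        got = {}
        for a in answers:
            if (a.source, a.target) == pair:
                got[(a.term, a.direction)] = got.get((a.term, a.direction), 0) + 1
        for cat, p in zip(spec.categories, spec.probabilities):
            if p > 0.01:
                assert got.get(cat, 0) / 10_000 == pytest.approx(p, abs=0.02)


class TestMissingness:
    def test_relationship_rounds_closed_form(self, panel):
        _, answers = generate_cohort(panel, 150, seed=5)
        out = inject_missing_relationships(answers, 0.05, rounds=4, seed=6)
        frac = np.mean([a.term == UNSURE for a in out])
        base = np.mean([a.term == UNSURE for a in answers])
        expected = 1 - (1 - base) * 0.95 ** 4
        assert frac == pytest.approx(expected, abs=0.01)

    def test_rate_zero_is_identity(self, panel):
        _, answers = generate_cohort(panel, 20, seed=5)
        assert inject_missing_relationships(answers, 0.0, rounds=3, seed=1) == answers

    def test_rate_one_blanks_everything(self, panel):
        _, answers = generate_cohort(panel, 10, seed=5)
        out = inject_missing_relationships(answers, 1.0, rounds=1, seed=1)
        assert all(a.term == UNSURE and a.direction is None for a in out)

    def test_factor_missingness_exact_count(self, panel):
        records, _ = generate_cohort(panel, 500, seed=6)
        k = len(records[0].factor_values)
        out = inject_missing_factors(records, 0.08, seed=7)
        n_missing = sum(v is None for r in out for v in r.factor_values.values())
        assert n_missing == round(0.08 * 500 * k)

    def test_factor_missingness_extremes(self, panel):
        records, _ = generate_cohort(panel, 10, seed=6)
        assert inject_missing_factors(records, 0.0, seed=1) == records
        gone = inject_missing_factors(records, 1.0, seed=1)
        assert all(v is None for r in gone for v in r.factor_values.values())


class TestPanel:
    def test_panel_probabilities_are_distributions(self, panel):
        for spec in panel.answer_specs.values():
            assert sum(spec.probabilities) == pytest.approx(1.0)
            assert all(p >= 0 for p in spec.probabilities)

    def test_panel_covers_every_active_relationship(self, panel):
        design = exercise_trial_design()
        assert set(panel.answer_specs) == design.active_relationships

    def test_different_panel_seeds_differ(self):
        a = sedentary_cohort_config(seed=0)
        b = sedentary_cohort_config(seed=1)
        assert a.answer_specs != b.answer_specs

    def test_unknown_distribution_kind_rejected(self):
        with pytest.raises(ValidationError):
            FactorSpec("lognormal", {})
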