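"""Synthetic-report generator: ground truth, determinism, fixture marginals."""

import math

import numpy as np
import pytest

from pvdispro import reference_counts as ref
from pvdispro.cohorts import build_cohorts, soc_presence_counts
from pvdispro.disproportionality import ContingencyTable, ror
from pvdispro.line_listing import deduplicate
from pvdispro.outcomes import OUTCOME_ORDER, outcome_distribution
from pvdispro.simulate import SimulationConfig, generate, reference_fixture, true_ror


def _small_config(**overrides):
    defaults = dict(
        n_target_only=300,
        n_comparator_only=600,
        n_both=20,
        n_neither=10,
        event_probs={
            "myalgia": {"target_only": 0.2366, "comparator_only": 0.1394, "both": 0.5},
            "rhabdomyolysis": {"target_only": 0.003, "comparator_only": 0.05, "both": 0.03},
        },
        outcome_probs={},
        duplicate_rate=0.1,
        seed=42,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.mark.parametrize(
    "p_t, p_c, expected",
    [
        (0.3, 0.3, 1.0),
        (0.5, 0.25, 3.0),
        (0.2366, 0.1394, 1.913),
    ],
)
def test_true_ror_closed_form(p_t, p_c, expected):
    config = _small_config(
        event_probs={"myalgia": {"target_only": p_t, "comparator_only": p_c}}
    )
    assert true_ror(config, "myalgia") == pytest.approx(expected, abs=5e-4)


def test_true_ror_undefined_at_degenerate_rates():
    config = _small_config(
        event_probs={"myalgia": {"target_only": 0.0, "comparator_only": 0.5}}
    )
    with pytest.raises(ValueError):
        true_ror(config, "myalgia")


def test_zero_sizes_give_empty_dataset():
    config = _small_config(
        n_target_only=0, n_comparator_only=0, n_both=0, n_neither=0, duplicate_rate=0.0
    )
    assert generate(config) == []


def test_same_seed_is_deterministic():
    config = _small_config()
    first = generate(config)
    second = generate(config)
    assert len(first) == len(second)
    for x, y in zip(first, second):
        assert x.case_id == y.case_id
        assert x.sex == y.sex
        assert [(r.pt, r.outcome) for r in x.reactions] == [
            (r.pt, r.outcome) for r in y.reactions
        ]


def test_group_sizes_are_exact():
    config = _small_config(duplicate_rate=0.0)
    cohorts = build_cohorts(generate(config))
    assert len(cohorts.target_only) == 300
    assert len(cohorts.comparator_only) == 600
    assert len(cohorts.both) == 20
    assert len(cohorts.neither) == 10


def test_every_report_has_a_reaction():
    config = _small_config()
    assert all(r.reactions for r in generate(config))


def test_dedup_removes_exactly_injected_count():
    config = _small_config(n_target_only=500, n_comparator_only=500, n_both=0,
                           n_neither=0, duplicate_rate=0.1)
    reports = generate(config)
    assert len(reports) == 1_000 + config.n_injected_duplicates
    kept, removed = deduplicate(reports)
    assert removed == config.n_injected_duplicates == 100
    assert len(kept) == 1_000


def test_estimated_ror_near_truth_at_moderate_n():
    config = _small_config(
        n_target_only=5_000, n_comparator_only=5_000, n_both=0, n_neither=0,
        duplicate_rate=0.0, seed=3,
    )
    cohorts = build_cohorts(generate(config))
    a = sum(1 for r in cohorts.target_only if r.has_pt("myalgia"))
    c = sum(1 for r in cohorts.comparator_only if r.has_pt("myalgia"))
    result = ror(ContingencyTable(a, 5_000 - a, c, 5_000 - c))
    truth = true_ror(config, "myalgia")
    # Within 4 standard errors on the log scale.
    se = math.sqrt(1 / a + 1 / (5_000 - a) + 1 / c + 1 / (5_000 - c))
    assert abs(math.log(result.ror) - math.log(truth)) < 4 * se


def test_estimator_consistency_error_shrinks_with_n():
    """Relative error of the ROR estimate shrinks roughly as n^(-1/2)."""
    errors = {}
    for n, seed in ((500, 21), (50_000, 22)):
        config = _small_config(
            n_target_only=n, n_comparator_only=n, n_both=0, n_neither=0,
            duplicate_rate=0.0, seed=seed,
        )
        cohorts = build_cohorts(generate(config))
        a = sum(1 for r in cohorts.target_only if r.has_pt("myalgia"))
        c = sum(1 for r in cohorts.comparator_only if r.has_pt("myalgia"))
        est = ror(ContingencyTable(a, n - a, c, n - c)).ror
        errors[n] = abs(est / true_ror(_small_config(), "myalgia") - 1)
    assert errors[50_000] < errors[500]


def test_combination_products_emitted_at_configured_fraction():
    config = _small_config(
        n_target_only=2_000, n_comparator_only=0, n_both=0, n_neither=0,
        combination_fraction=0.25, duplicate_rate=0.0,
    )
    reports = generate(config)
    n_combo = sum(1 for r in reports if any(len(p) > 1 for p in r.suspect_drugs))
    assert 0.20 < n_combo / 2_000 < 0.30  # binomial, well within 3 SD


class TestReferenceFixture:
    """The deterministic dataset reproduces every published marginal."""

    def test_group_sizes(self, reference_cohorts):
        assert len(reference_cohorts.target_only) == 2_667
        assert len(reference_cohorts.comparator_only) == 76_137
        assert len(reference_cohorts.both) == 126

    def test_soc_presence_marginals(self, reference_cohorts, meddra):
        for group in ("target_only", "comparator_only", "both"):
            counts = soc_presence_counts(getattr(reference_cohorts, group), meddra)
            for soc, per_group in ref.SOC_PRESENCE.items():
                assert counts.get(soc, 0) == per_group[group], (group, soc)

    def test_mr_pt_outcome_marginals(self, reference_cohorts):
        groups = {
            "target_only": reference_cohorts.target_only,
            "comparator_only": reference_cohorts.comparator_only,
            "both": reference_cohorts.both,
        }
        for pt, per_group in ref.MR_PT_OUTCOMES.items():
            for group, expected in per_group.items():
                dist = outcome_distribution(groups[group], pt)
                got = tuple(dist.counts[cat] for cat in OUTCOME_ORDER)
                assert got == expected, (pt, group)

    def test_demographic_marginals(self, reference_cohorts):
        from pvdispro.icsr import Sex

        sexes = [r.sex for r in reference_cohorts.target_only]
        assert sexes.count(Sex.FEMALE) == 1_439
        assert sexes.count(Sex.MALE) == 1_201
        assert sexes.count(Sex.UNSPECIFIED) == 27

    def test_fatality_count_comparator_rhabdomyolysis(self, reference_cohorts):
        dist = outcome_distribution(
            reference_cohorts.comparator_only, "rhabdomyolysis"
        )
        assert dist.counts[OUTCOME_ORDER[0]] == 169  # fatal cases


def test_default_config_mirrors_published_rates():
    config = SimulationConfig()
    assert config.n_base == 78_930
    assert true_ror(config, "myalgia") == pytest.approx(1.913, abs=2e-3)
    assert config.event_probs["myalgia"]["target_only"] == pytest.approx(631 / 2_667)
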