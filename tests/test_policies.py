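"""Policy projections: default/alternative policies, benchmark and ICER."""

import numpy as np
import pandas as pd
import pytest

from inhalersim.costs import PATTERNS, CohortSpec, UnitCosts, UnitFootprints
from inhalersim.policies import (
    POLICIES,
    PolicyConfig,
    PolicyConfigError,
    benchmark_reusable,
    icer_pair,
    project_alternative_policy,
    project_default_policy,
    project_policy,
)
from inhalersim.published import published_gains

DERIVED_COHORT = int(64.5e6 / 685.8)  # whole patients implied by the 64.5 M EUR cell
YEARS = list(range(2024, 2029))


def cohort(f=0.32, gains=None, severity="moderate"):
    if gains is None:
        gains = published_gains("five_year", severity, post_training=True)
    elif not isinstance(gains, pd.Series):
        gains = pd.Series(gains, index=YEARS, dtype=float)
    return CohortSpec(
        n_patients=DERIVED_COHORT, severity=severity, learned_fraction=f, gain_schedule=gains
    )


class TestPolicyConfig:
    def test_registry_is_consistent(self):
        assert POLICIES["SR2M"].design_version == "B"
        assert POLICIES["SR2M"].mode == "alternative"
        assert POLICIES["R"].design_version is None

    def test_mismatched_configuration_rejected(self):
        with pytest.raises(PolicyConfigError):
            PolicyConfig("SR1", "B", "default")
        with pytest.raises(PolicyConfigError):
            PolicyConfig("SRX", "A", "default")

    def test_mode_dispatch_enforced(self):
        with pytest.raises(PolicyConfigError):
            project_default_policy(POLICIES["SR2M"], PATTERNS[1], cohort())
        with pytest.raises(PolicyConfigError):
            project_alternative_policy(POLICIES["SR1"], PATTERNS[1], cohort())


class TestBenchmark:
    def test_per_patient_cost_from_printed_unit_costs(self):
        res = benchmark_reusable(PATTERNS[1], cohort())
        per_patient = res.mean_cost_eur / DERIVED_COHORT
        assert per_patient == pytest.approx(12 * (42.96 + 1.87))  # 537.96 EUR

    def test_cheaper_than_any_smart_policy_with_standard_cartridges(self):
        bench = benchmark_reusable(PATTERNS[2], cohort())
        for pol_id in ("SR1", "SR2", "SR3"):
            smart = project_policy(POLICIES[pol_id], PATTERNS[2], cohort(f=0.0))
            assert bench.mean_cost_eur < smart.mean_cost_eur


class TestDefaultPolicy:
    def test_no_learners_reproduces_baseline_with_zero_savings(self):
        res = project_default_policy(POLICIES["SR2"], PATTERNS[1], cohort(f=0.0))
        baseline = 12 * (42.96 + 1.87 + 7.46) * DERIVED_COHORT
        assert np.allclose(res.cost_eur, baseline)
        assert np.allclose(res.savings_eur, 0.0)

    def test_zero_gains_give_zero_savings_despite_learners(self):
        res = project_default_policy(POLICIES["SR2"], PATTERNS[1], cohort(f=0.32, gains=[0] * 5))
        assert np.allclose(res.savings_eur, 0.0)

    def test_reproduces_published_mean_cost_cell(self):
        """SR2 / pattern 1 / moderate five-year: 58.65 million EUR at print rounding."""
        res = project_default_policy(POLICIES["SR2"], PATTERNS[1], cohort(f=0.32))
        assert res.mean_cost_eur / 1e6 == pytest.approx(58.65, abs=0.02)

    @pytest.mark.parametrize("pol_id", ["SR1", "SR2", "SR3"])
    @pytest.mark.parametrize("pattern_id", [1, 2, 3])
    def test_cost_plus_savings_conserves_baseline(self, pol_id, pattern_id):
        res = project_default_policy(POLICIES[pol_id], PATTERNS[pattern_id], cohort(f=0.32))
        totals = res.cost_eur + res.savings_eur
        assert np.allclose(totals, totals.iloc[0])
        totals_scc = res.cost_scc_eur + res.savings_scc_eur
        assert np.allclose(totals_scc, totals_scc.iloc[0])

    def test_savings_identical_across_versions_and_patterns(self):
        """Content reduction is the only saving, so design/pattern drop out."""
        base = project_default_policy(POLICIES["SR1"], PATTERNS[1], cohort()).savings_eur
        for pol_id in ("SR2", "SR3"):
            for pid in (1, 2, 3):
                other = project_default_policy(POLICIES[pol_id], PATTERNS[pid], cohort())
                assert np.allclose(other.savings_eur, base)


class TestAlternativePolicy:
    def test_no_learners_reproduces_all_smart_standard(self):
        res = project_alternative_policy(POLICIES["SR2M"], PATTERNS[1], cohort(f=0.0))
        baseline = 12 * (42.96 + 1.87 + 7.46) * DERIVED_COHORT
        assert np.allclose(res.cost_eur, baseline)
        assert np.allclose(res.savings_eur, 0.0)

    def test_all_learners_zero_gains_save_exactly_the_modules(self):
        res = project_alternative_policy(
            POLICIES["SR2M"], PATTERNS[2], cohort(f=1.0, gains=[0] * 5)
        )
        expected = DERIVED_COHORT * 6 * 7.46
        assert np.allclose(res.savings_eur, expected)

    def test_reproduces_published_savings_within_two_percent(self):
        """SR2M five-year moderate savings: 3.08 / 1.72 / 1.27 million EUR."""
        printed = {1: 3.08, 2: 1.72, 3: 1.27}
        for pid, expected in printed.items():
            res = project_alternative_policy(POLICIES["SR2M"], PATTERNS[pid], cohort(f=0.32))
            assert res.mean_savings_eur / 1e6 == pytest.approx(expected, rel=0.02)

    def test_savings_monotone_in_learned_fraction_and_gains(self):
        lo = project_alternative_policy(POLICIES["SR3M"], PATTERNS[1], cohort(f=0.1))
        hi = project_alternative_policy(POLICIES["SR3M"], PATTERNS[1], cohort(f=0.4))
        assert hi.mean_savings_eur > lo.mean_savings_eur
        small = project_alternative_policy(POLICIES["SR3M"], PATTERNS[1], cohort(gains=[1] * 5))
        large = project_alternative_policy(POLICIES["SR3M"], PATTERNS[1], cohort(gains=[3] * 5))
        assert large.mean_savings_eur > small.mean_savings_eur

    def test_savings_ordering_across_patterns(self):
        """More inhalers per year means more module spend avoided: P1 > P2 > P3."""
        savings = [
            project_alternative_policy(POLICIES["SR2M"], PATTERNS[pid], cohort()).mean_savings_eur
            for pid in (1, 2, 3)
        ]
        assert savings[0] > savings[1] > savings[2]

    def test_five_year_training_saves_at_least_four_year(self):
        for pid in (1, 2, 3):
            five = project_alternative_policy(
                POLICIES["SR2M"], PATTERNS[pid],
                cohort(f=0.32, gains=published_gains("five_year", "moderate", post_training=True)),
            )
            four = project_alternative_policy(
                POLICIES["SR2M"], PATTERNS[pid],
                cohort(f=0.23, gains=published_gains("four_year", "moderate", post_training=True)),
            )
            assert five.mean_savings_eur >= four.mean_savings_eur

    def test_first_year_savings_without_content_reduction(self):
        """Four-year training: 2024 gain is 0 yet module removal already saves."""
        res = project_alternative_policy(
            POLICIES["SR2M"], PATTERNS[1],
            cohort(f=0.23, gains=published_gains("four_year", "moderate", post_training=True)),
        )
        assert res.savings_eur.loc[2024] == pytest.approx(DERIVED_COHORT * 0.23 * 12 * 7.46)


class TestIcer:
    def test_policy_against_itself_is_zero(self):
        res = project_policy(POLICIES["SR2"], PATTERNS[1], cohort())
        assert icer_pair(res, res) == (0.0, 0.0)

    def test_version_b_cheaper_than_version_a(self):
        sr1 = project_policy(POLICIES["SR1"], PATTERNS[1], cohort())
        sr2 = project_policy(POLICIES["SR2"], PATTERNS[1], cohort())
        d_eur, d_scc = icer_pair(sr2, sr1)
        assert d_eur < 0 and d_scc < 0

    def test_version_c_greener_but_costlier_than_b(self):
        sr2 = project_policy(POLICIES["SR2"], PATTERNS[1], cohort())
        sr3 = project_policy(POLICIES["SR3"], PATTERNS[1], cohort())
        d_eur, d_scc = icer_pair(sr3, sr2)
        assert d_eur > 0 and d_scc < 0

    def test_mismatched_patterns_rejected(self):
        a = project_policy(POLICIES["SR2"], PATTERNS[1], cohort())
        b = benchmark_reusable(PATTERNS[2], cohort())
        with pytest.raises(ValueError):
            icer_pair(a, b)
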