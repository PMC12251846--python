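"""Monte Carlo training simulator: sampling contracts and cohort behaviour."""

import numpy as np
import pytest

from inhalersim.profiles import MODERATE_PROFILE, build_reference_profile, decompose_slopes
from inhalersim.training import (
    DeliveryRateModel,
    TrainingConfig,
    VariabilitySchedule,
    attempt_year,
    run_cohort,
    sample_delivery_gain,
    sample_year_slopes,
    update_schedule,
)

FIVE_YEARS = tuple(range(2019, 2024))
FOUR_YEARS = tuple(range(2020, 2024))


def schedule(pre=0.6, post=0.3, decay=0.9, floor_ratio=0.5):
    return VariabilitySchedule(pre, pre * floor_ratio, post, post * floor_ratio, decay)


def zero_schedule():
    return VariabilitySchedule(0.0, 0.0, 0.0, 0.0, 1.0)


DELIVERY = DeliveryRateModel(baseline_mean=59.2, max_final_gain=4.9, annual_increment_sd=0.25)


def config(**kw):
    base = dict(
        severity="moderate",
        years=FIVE_YEARS,
        schedule=schedule(),
        delivery=DELIVERY,
        n_runs=2000,
        seed=7,
    )
    base.update(kw)
    return TrainingConfig(**base)


@pytest.fixture(scope="module")
def reference():
    return build_reference_profile(MODERATE_PROFILE)


class TestSampleYearSlopes:
    def test_zero_cv_returns_reference_exactly(self, reference, rng):
        ref = decompose_slopes(reference)
        out = sample_year_slopes(ref, reference.pif_index, zero_schedule().initial_state(), rng)
        np.testing.assert_array_equal(out.slopes, ref.slopes)

    def test_sample_mean_and_segment_variability(self, reference, rng):
        ref = decompose_slopes(reference)
        state = schedule(pre=0.5, post=0.1).initial_state()
        k = reference.pif_index
        draws = np.array(
            [sample_year_slopes(ref, k, state, rng).slopes for _ in range(100_000)]
        )
        se = np.abs(ref.slopes) * np.where(np.arange(len(ref)) < k, 0.5, 0.1) / np.sqrt(len(draws))
        # Monte Carlo mean within 3 standard errors of the reference slopes
        assert np.all(np.abs(draws.mean(axis=0) - ref.slopes) <= 3 * se + 1e-12)
        # relative spread obeys the pre/post-PIF schedule
        rel_sd = draws.std(axis=0) / np.abs(ref.slopes)
        assert rel_sd[:k].min() > rel_sd[k:].max()


class TestAttemptYear:
    def test_zero_variability_always_confirms(self, reference, rng):
        state = zero_schedule().initial_state()
        from inhalersim.profiles import inhaled_volume

        confirmed, vol = attempt_year(reference, state, rng)
        assert confirmed
        assert vol == pytest.approx(inhaled_volume(reference))

    def test_first_success_consumes_one_draw(self, reference):
        class CountingRNG:
            def __init__(self):
                self.rng = np.random.default_rng(0)
                self.calls = 0

            def standard_normal(self, n):
                self.calls += 1
                return np.zeros(n)  # deterministic success on the first attempt

        counter = CountingRNG()
        confirmed, _ = attempt_year(reference, schedule().initial_state(), counter)
        assert confirmed and counter.calls == 1

    def test_retry_matches_closed_form(self, reference, rng):
        """Two-attempt confirmation probability is 1 - (1-q)^2."""
        state = schedule(pre=0.8, post=0.4).initial_state()
        n = 20_000
        singles = np.fromiter(
            (attempt_year(reference, state, rng, allow_retry=False)[0] for _ in range(n)),
            dtype=bool,
        )
        pairs = np.fromiter(
            (attempt_year(reference, state, rng)[0] for _ in range(n)), dtype=bool
        )
        q = singles.mean()
        expected = 1 - (1 - q) ** 2
        se = 3 * np.sqrt(expected * (1 - expected) / n + q * (1 - q) / n)
        assert pairs.mean() == pytest.approx(expected, abs=se)


class TestUpdateSchedule:
    def test_unconfirmed_leaves_state_unchanged(self):
        state = schedule().initial_state()
        assert update_schedule(state, confirmed=False) == state

    def test_repeated_confirmation_converges_to_floor(self):
        sched = schedule(pre=1.0, post=0.5, decay=0.5, floor_ratio=0.4)
        state = sched.initial_state()
        for _ in range(20):
            state = update_schedule(state, confirmed=True)
        assert state.pre_cv == pytest.approx(sched.pre_pif_cv_floor)
        assert state.post_cv == pytest.approx(sched.post_pif_cv_floor)

    def test_unit_decay_factor_is_inert(self):
        state = schedule(decay=1.0).initial_state()
        assert update_schedule(state, confirmed=True) == state

    def test_pre_pif_must_dominate_post_pif(self):
        with pytest.raises(ValueError):
            VariabilitySchedule(0.2, 0.1, 0.5, 0.2, 0.9)


class TestDeliveryGain:
    def test_unconfirmed_year_leaves_gain_unchanged(self, rng):
        assert sample_delivery_gain(1.5, 2, 5, DELIVERY, confirmed=False, rng=rng) == 1.5

    def test_zero_sd_follows_linear_ramp_to_cap(self, rng):
        model = DeliveryRateModel(59.2, 4.9, annual_increment_sd=0.0)
        gain = 0.0
        path = []
        for year in range(5):
            gain = sample_delivery_gain(gain, year, 5, model, confirmed=True, rng=rng)
            path.append(gain)
        np.testing.assert_allclose(path, 4.9 / 5 * np.arange(1, 6))
        assert path[-1] == pytest.approx(4.9)

    def test_cumulative_gain_never_exceeds_cap(self, rng):
        model = DeliveryRateModel(59.2, 4.9, annual_increment_sd=2.0)
        for _ in range(200):
            gain = 0.0
            for year in range(5):
                gain = sample_delivery_gain(gain, year, 5, model, confirmed=True, rng=rng)
                assert 0.0 <= gain <= 4.9 + 1e-12


class TestRunCohort:
    def test_zero_variability_learns_everyone(self):
        summary = run_cohort(config(schedule=zero_schedule(), n_runs=500))
        assert summary.learned_fraction == 1.0

    def test_zero_variability_zero_sd_is_deterministic_ramp(self):
        cfg = config(
            schedule=zero_schedule(),
            delivery=DeliveryRateModel(59.2, 4.9, annual_increment_sd=0.0),
            n_runs=50,
        )
        summary = run_cohort(cfg)
        np.testing.assert_allclose(
            summary.mean_annual_gain.to_numpy(), 4.9 / 5 * np.arange(1, 6)
        )

    def test_same_seed_reproduces_summary(self):
        a = run_cohort(config(seed=99))
        b = run_cohort(config(seed=99))
        assert a.learned_fraction == b.learned_fraction
        assert a.mean_annual_gain.equals(b.mean_annual_gain)

    def test_learned_fraction_within_binomial_band_across_seeds(self):
        fractions = [run_cohort(config(seed=s, n_runs=4000)).learned_fraction for s in range(5)]
        pooled = np.mean(fractions)
        half_width = 2.58 * np.sqrt(pooled * (1 - pooled) / 4000)
        assert all(abs(f - pooled) <= half_width + 1e-9 for f in fractions)

    def test_mean_gain_non_decreasing_over_years(self):
        summary = run_cohort(config(n_runs=4000, seed=3))
        gains = summary.mean_annual_gain.to_numpy()
        assert np.all(np.diff(gains) >= -1e-12)

    def test_four_year_lead_in_year_has_zero_gain(self):
        cfg = config(years=FOUR_YEARS, lead_in_years=1, n_runs=3000, seed=11)
        summary = run_cohort(cfg)
        assert summary.mean_annual_gain.index[0] == 2019
        assert summary.mean_annual_gain.iloc[0] == 0.0

    def test_lead_in_lowers_learned_fraction(self):
        """An extra unassisted year can only remove learners."""
        with_lead = run_cohort(config(years=FOUR_YEARS, lead_in_years=1, seed=5, n_runs=8000))
        without = run_cohort(config(years=FOUR_YEARS, lead_in_years=0, seed=5, n_runs=8000))
        assert with_lead.learned_fraction < without.learned_fraction

    def test_trajectories_consistent_with_summary(self):
        summary, trajectories = run_cohort(config(n_runs=200, seed=2), return_trajectories=True)
        learned = [t for t in trajectories if t.learned]
        assert len(learned) == summary.n_learned
        for t in trajectories:
            assert np.all(np.diff(t.gains) >= -1e-12)
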