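import numpy as np
import pytest

import crcscreen as cs
from crcscreen.cohort_engine import (
    COHORT_SIZE,
    ScreeningStrategy,
    apply_screening_round,
    deaths_averted,
    run_cohort,
    run_strategy_grid,
)
from crcscreen.natural_history import N_STATES, HealthState as S, aged_distribution

from conftest import no_death_unit_utility


def unit_mass(state):
    dist = np.zeros(N_STATES)
    dist[state] = 1.0
    return dist


class TestScreeningStrategy:
    def test_schedule_semantics(self):
        assert ScreeningStrategy(42, "once").screening_cycles() == [0]
        assert ScreeningStrategy(42, "every_10y").screening_cycles() == [0, 10, 20, 30]
        assert ScreeningStrategy(42, "none").screening_cycles() == []
        # rounds stop once the cohort passes the stop age (74 by default)
        annual = ScreeningStrategy(72, "annual").screening_cycles()
        assert annual == [0, 1, 2]

    def test_validation(self):
        with pytest.raises(ValueError):
            ScreeningStrategy(42, "fortnightly")
        with pytest.raises(ValueError):
            ScreeningStrategy(39, "annual")
        with pytest.raises(ValueError):
            ScreeningStrategy(80, "annual", stop_age=74)
        with pytest.raises(ValueError):
            ScreeningStrategy(42, "annual", adherence_decay=0.0)


class TestScreeningRound:
    def test_zero_participation_is_a_no_op(self, params):
        p = params.with_value("participation_rate", 0.0)
        dist = unit_mass(S.NORMAL)
        out, ev = apply_screening_round(dist, p)
        assert np.array_equal(out, dist)
        assert ev["cost"] == 0.0 and ev["screens"] == 0.0

    def test_false_positive_colonoscopy_rate(self, params):
        # colonoscopies per screen on a lesion-free cohort:
        # (1 - specificity) x colonoscopy compliance
        _, ev = apply_screening_round(unit_mass(S.NORMAL), params)
        assert ev["colonoscopies"] / ev["screens"] == pytest.approx(0.2830 * 0.3892, abs=1e-6)
        assert ev["false_positive_colonoscopies"] == ev["colonoscopies"]

    def test_crc_detection_pathway_composition(self, params):
        # participation x CRC sensitivity x compliance x colonoscopy sensitivity
        _, ev = apply_screening_round(unit_mass(S.CRC1_U), params)
        assert ev["screen_detections"]["crc1"] == pytest.approx(
            0.5829 * 0.7778 * 0.3892 * 1.00, abs=1e-9
        )

    def test_mass_conserved_and_adherence_decay(self, params):
        dist = aged_distribution(params, 62)
        out, ev = apply_screening_round(dist, params, round_index=3, adherence_decay=0.9)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        _, ev0 = apply_screening_round(dist, params, round_index=0, adherence_decay=0.9)
        assert ev["screens"] == pytest.approx(ev0["screens"] * 0.9 ** 3)


class TestRunCohort:
    def test_degenerate_bookkeeping(self, params):
        # no deaths, utility 1, discount 0: QALYs = cohort size x horizon
        p = no_death_unit_utility(params)
        out = run_cohort(ScreeningStrategy(72, "none"), p, discount_rate=0.0)
        assert out.qalys == pytest.approx(COHORT_SIZE * 10, rel=1e-12)

    def test_two_cycle_hand_oracle(self, params):
        # entry 80, no screening: only background mortality (0.06802) kills,
        # and utilities are flattened to 0.943 so every alive state accrues
        # the same weight regardless of lesion progression
        p = params.with_value("utility_aa", 0.943)
        for stage in range(1, 5):
            p = p.with_value(f"survival5_crc{stage}", 1.0)
            p = p.with_value(f"utility_crc{stage}", 0.943)
        m, u, r = 0.06802, 0.943, 0.03
        out = run_cohort(ScreeningStrategy(80, "none"), p)
        q0 = (1 + (1 - m)) / 2 * u
        q1 = ((1 - m) + (1 - m) ** 2) / 2 * u / (1 + r)
        assert out.qalys == pytest.approx(COHORT_SIZE * (q0 + q1), rel=1e-9)
        assert out.other_deaths == pytest.approx(COHORT_SIZE * (1 - (1 - m) ** 2), rel=1e-9)
        assert out.crc_deaths == 0.0

    def test_mass_conservation_every_cycle(self, params):
        out = run_cohort(ScreeningStrategy(42, "annual"), params,
                         init=aged_distribution(params, 42))
        sums = out.trace_states.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) <= 1e-10)
        assert (out.trace_states >= -1e-10).all()

    def test_totals_equal_ledger_sums_and_reproducible(self, params):
        strat = ScreeningStrategy(52, "every_5y")
        a = run_cohort(strat, params)
        b = run_cohort(strat, params)
        assert a.qalys == b.qalys and a.cost == b.cost  # bit-reproducible
        assert a.cost == pytest.approx(
            sum(l.cost_discounted for l in a.ledgers) * COHORT_SIZE, rel=1e-12
        )
        assert a.colonoscopies == pytest.approx(
            sum(l.colonoscopies for l in a.ledgers) * COHORT_SIZE, rel=1e-12
        )

    def test_screening_beats_no_screening_on_crc_deaths(self, params):
        base = run_cohort(ScreeningStrategy(42, "none"), params)
        annual = run_cohort(ScreeningStrategy(42, "annual"), params)
        assert annual.crc_deaths < base.crc_deaths

    def test_discounting_monotonicity(self, params):
        strat = ScreeningStrategy(52, "every_3y")
        lo = run_cohort(strat, params, discount_rate=0.03)
        hi = run_cohort(strat, params, discount_rate=0.05)
        assert hi.qalys < lo.qalys and hi.cost < lo.cost

    def test_half_cycle_brackets_start_and_end_accrual(self, params):
        strat = ScreeningStrategy(57, "none")
        q = {m: run_cohort(strat, params, accrual=m).qalys for m in ("start", "half", "end")}
        assert q["end"] < q["half"] < q["start"]

    def test_zero_sensitivity_screening_collapses_to_baseline(self, params):
        p = (
            params.with_value("screen_sensitivity_adenoma", 0.0)
            .with_value("screen_sensitivity_crc", 0.0)
            .with_value("screen_specificity", 1.0)
        )
        init = aged_distribution(p, 52)
        base = run_cohort(ScreeningStrategy(52, "none"), p, init=init)
        blind = run_cohort(ScreeningStrategy(52, "every_2y"), p, init=init)
        assert blind.crc_deaths == pytest.approx(base.crc_deaths, abs=1e-9)
        assert blind.qalys == pytest.approx(base.qalys, rel=1e-12)
        assert blind.cost > base.cost  # screening costs with no health effect

    def test_preparation_cost_charged_once_for_screening_only(self, params):
        cheap = params.with_value("cost_preparation", 0.0)
        strat = ScreeningStrategy(72, "once")
        with_prep = run_cohort(strat, params)
        without = run_cohort(strat, cheap)
        assert with_prep.cost - without.cost == pytest.approx(13_572, rel=1e-9)
        none_a = run_cohort(ScreeningStrategy(72, "none"), params)
        none_b = run_cohort(ScreeningStrategy(72, "none"), cheap)
        assert none_a.cost == none_b.cost


class TestDeathsAverted:
    def test_self_comparison_is_undefined_ratio(self, params):
        out = run_cohort(ScreeningStrategy(62, "none"), params)
        da = deaths_averted(out, out)
        assert da.deaths_averted == 0.0 and da.colonoscopies_per_death_averted is None

    def test_requires_matching_entry_age(self, params):
        a = run_cohort(ScreeningStrategy(62, "none"), params)
        b = run_cohort(ScreeningStrategy(67, "none"), params)
        with pytest.raises(ValueError):
            deaths_averted(a, b)

    def test_monotone_in_frequency_with_colonoscopies(self, outcomes_52):
        base = outcomes_52["none"]
        averted, colos = [], []
        for f in ("once", "every_10y", "every_5y", "every_3y", "every_2y", "annual"):
            o = outcomes_52[f]
            averted.append(deaths_averted(base, o).deaths_averted)
            colos.append(o.colonoscopies)
        assert averted == sorted(averted)
        assert colos == sorted(colos)


class TestGrid:
    def test_shape_and_init_modes(self, params):
        grid = run_strategy_grid(params, entry_ages=[62], frequencies=["once", "annual"])
        assert set(grid[62]) == {"none", "once", "annual"}
        normal = run_strategy_grid(
            params, entry_ages=[62], frequencies=["once"], init_mode="normal"
        )
        # an aged entry cohort carries prevalent lesions, so one-off screening
        # detects something; a lesion-free cohort yields almost nothing
        aged_det = sum(grid[62]["once"].detections.values())
        normal_det = sum(normal[62]["once"].detections.values())
        assert aged_det > 10 * normal_det
        with pytest.raises(ValueError):
            run_strategy_grid(params, init_mode="fresh")
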