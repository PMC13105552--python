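import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import crcscreen as cs
from crcscreen.natural_history import (
    ALIVE,
    MAX_AGE,
    MIN_AGE,
    N_STATES,
    HealthState as S,
    aged_distribution,
    annual_mortality_from_survival,
    build_transition_matrix,
    calibrate_transitions,
    goodness_of_fit,
    lesion_prevalence,
)
from crcscreen.parameters import AgeBand


class TestAnnualMortality:
    @pytest.mark.parametrize(
        "survival, expected",
        [(1.0, 0.0), (0.916, 0.01740), (0.188, 0.28413)],
    )
    def test_closed_form(self, survival, expected):
        assert annual_mortality_from_survival(survival) == pytest.approx(expected, abs=1e-5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            annual_mortality_from_survival(1.2)

    @given(st.floats(min_value=0.01, max_value=0.98))
    def test_strictly_decreasing_in_survival(self, s):
        assert annual_mortality_from_survival(s) > annual_mortality_from_survival(s + 0.01)


class TestTransitionMatrix:
    @pytest.mark.parametrize("age", [40, 45, 54, 60, 74, 79, 82])
    def test_rows_sum_to_one(self, age, params):
        M = build_transition_matrix(age, params)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert (M >= 0).all()

    def test_onset_flow_composition(self, params):
        # normal -> NAA is onset conditioned on surviving background mortality
        M = build_transition_matrix(45, params)
        assert M[S.NORMAL, S.NAA_U] == pytest.approx((1 - 0.00226) * 0.0147, abs=1e-12)

    def test_death_states_absorbing(self, params):
        M = build_transition_matrix(60, params)
        assert M[S.DEATH_CRC, S.DEATH_CRC] == 1.0
        assert M[S.DEATH_OTHER, S.DEATH_OTHER] == 1.0

    def test_age_outside_model_range(self, params):
        with pytest.raises(ValueError):
            build_transition_matrix(39, params)
        with pytest.raises(ValueError):
            build_transition_matrix(83, params)

    def test_progression_is_irreversible(self, params):
        # no flow from a lesion state back to NORMAL or to a milder lesion
        M = build_transition_matrix(55, params)
        assert M[S.AA_U, S.NORMAL] == 0 and M[S.AA_U, S.NAA_U] == 0
        assert M[S.CRC2_U, S.CRC1_U] == 0


class TestPrevalenceStructure:
    def test_lifetime_cumulative_incidence_decreases_with_severity(self, params):
        # cumulative onset flows over the whole horizon: adenoma onset >=
        # progression to advanced adenoma >= progression to cancer
        from crcscreen.natural_history import TransitionModel

        model = TransitionModel(params)
        dist = np.zeros(N_STATES)
        dist[S.NORMAL] = 1.0
        onset = to_aa = to_crc = 0.0
        for age in range(MIN_AGE, MAX_AGE):
            M = model.matrix(age)
            onset += dist[S.NORMAL] * M[S.NORMAL, S.NAA_U]
            to_aa += dist[S.NAA_U] * M[S.NAA_U, S.AA_U] + dist[S.NAA_DU] * M[S.NAA_DU, S.AA_DU]
            to_crc += dist[S.AA_U] * M[S.AA_U, S.CRC1_U] + dist[S.AA_DU] * M[S.AA_DU, S.CRC1_DU]
            dist = dist @ M
        assert onset >= to_aa >= to_crc > 0

    def test_prevalence_rises_with_age_through_the_early_sixties(self, params):
        # lesion prevalence grows with age while the normal-epithelium pool
        # lasts; under the base case the NAA stock peaks in the mid-60s
        # (progression out of NAA is fast), so NAA is checked through 60-64
        # and AA/CRC through 65-69
        bands = [AgeBand(40, 49)] + [AgeBand(a, a + 4) for a in range(50, 70, 5)]
        prev = lesion_prevalence(params, bands)
        wide = prev.pivot_table(index="age_low", columns="state_class", values="rate")
        assert wide["naa"].iloc[:4].is_monotonic_increasing
        assert wide["aa"].is_monotonic_increasing
        assert wide["crc"].is_monotonic_increasing
        # severity ordering NAA >= AA >= CRC holds where screening operates
        young = wide.loc[wide.index <= 55]
        assert ((young["naa"] >= young["aa"]) & (young["aa"] >= young["crc"])).all()

    def test_aged_distribution_properties(self, params):
        young = aged_distribution(params, 42)
        old = aged_distribution(params, 72)
        for dist in (young, old):
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)
            assert dist[S.DEATH_CRC] == 0 and dist[S.DEATH_OTHER] == 0
        assert old[S.NORMAL] < young[S.NORMAL]  # more prevalent disease at 72


class TestCalibration:
    def test_recovers_generating_transitions(self, params):
        bands = [AgeBand(40, 49), AgeBand(50, 54), AgeBand(55, 59),
                 AgeBand(60, 64), AgeBand(65, 69)]
        truth = params
        for name, f in (("p_normal_to_naa", 1.2), ("p_naa_to_aa", 0.85),
                        ("p_aa_to_crc1", 1.25)):
            truth = truth.with_scaled_bands(name, f)
        targets = lesion_prevalence(truth, bands)
        result = calibrate_transitions(targets, params)
        assert result.objective < result.start_objective
        for family in ("p_normal_to_naa", "p_naa_to_aa", "p_aa_to_crc1"):
            fitted = dict((b.lower, v) for b, v in result.params.band_items(family))
            for band, true_val in truth.band_items(family):
                if band.lower > 69:
                    continue
                assert fitted[band.lower] == pytest.approx(true_val, rel=0.10)

    def test_zero_targets_drive_onset_to_lower_bounds(self, params):
        bands = [(40, 49), (50, 54), (55, 59)]
        targets = pd.DataFrame(
            [
                {"age_low": lo, "age_high": hi, "state_class": cls, "rate": 0.0}
                for lo, hi in bands
                for cls in ("naa", "aa", "crc")
            ]
        )
        result = calibrate_transitions(targets, params)
        for band, value in result.params.band_items("p_normal_to_naa"):
            if band.lower > 59:
                continue
            spec = params.spec("p_normal_to_naa", band.lower)
            assert value == pytest.approx(spec.ui_low, rel=1e-3)

    def test_rejects_bad_targets(self, params):
        bad = pd.DataFrame(
            [{"age_low": 40, "age_high": 49, "state_class": "naa", "rate": 1.5}]
        )
        with pytest.raises(ValueError):
            calibrate_transitions(bad, params)
        few = pd.DataFrame(
            [{"age_low": 40, "age_high": 49, "state_class": "naa", "rate": 0.1},
             {"age_low": 50, "age_high": 54, "state_class": "naa", "rate": 0.1}]
        )
        with pytest.raises(ValueError, match="three age bands"):
            calibrate_transitions(few, params)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        gof = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gof.rmse == 0.0 and gof.r_squared == 1.0

    def test_hand_computed_rmse(self):
        gof = goodness_of_fit([1.0, 2.0], [1.0, 4.0])
        assert gof.rmse == pytest.approx(1.41421, abs=1e-5)

    def test_constant_reference_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            goodness_of_fit([1.0, 2.0], [3.0, 3.0])

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            goodness_of_fit([1.0], [1.0])
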