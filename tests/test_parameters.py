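import io

import numpy as np
import pandas as pd
import pytest

from crcscreen.parameters import (
    AgeBand,
    ParameterSpec,
    build_distribution,
    default_parameters,
    load_parameter_table,
    sample_parameter_draw,
)


class TestPackagedTable:
    def test_base_case_values(self, params):
        assert params["participation_rate"] == 0.5829
        assert params["cost_treatment_aa"] == 1185
        assert params["colonoscopy_compliance"] == 0.3892
        assert params.value("p_normal_to_naa", 45) == 0.0147
        assert params.value("p_normal_to_naa", 77) == 0.0525
        assert params.value("p_normal_to_naa", 81) == 0.0606
        assert params.value("background_mortality", 47) == 0.00226
        assert params.value("utility_general", 57) == 0.955
        assert params["discount_rate"] == 0.03

    def test_age_band_lookup_beyond_last_band_uses_last(self, params):
        assert params.value("utility_general", 82) == 0.943

    def test_round_trip_is_exact(self, params):
        buf = io.StringIO()
        params.to_csv(buf)
        buf.seek(0)
        reloaded = load_parameter_table(buf)
        assert reloaded == params

    def test_yaml_table_loads_identically(self, params, tmp_path):
        import yaml

        records = params.to_frame().where(lambda df: df.notna(), None).to_dict("records")
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump({"parameters": records}))
        assert load_parameter_table(path) == params

    def test_missing_mandatory_parameter_rejected(self, params):
        df = params.to_frame()
        df = df[df.name != "participation_rate"]
        with pytest.raises(ValueError, match="participation_rate"):
            load_parameter_table(io.StringIO(df.to_csv(index=False)))

    def test_probability_above_one_rejected(self, params):
        df = params.to_frame()
        df.loc[df.name == "participation_rate", ["base", "ui_high"]] = 1.2
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            load_parameter_table(io.StringIO(df.to_csv(index=False)))

    def test_base_outside_ui_rejected(self):
        with pytest.raises(ValueError, match="outside UI"):
            ParameterSpec("x", base=0.9, ui_low=0.1, ui_high=0.5, distribution="uniform")

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            ParameterSpec("x", base=0.5, ui_low=0.1, ui_high=0.9, distribution="weibull")


class TestAgeBand:
    def test_membership_and_ordering(self):
        band = AgeBand(50, 54)
        assert 50 in band and 54 in band and 55 not in band
        with pytest.raises(ValueError):
            AgeBand(60, 50)


class TestBuildDistribution:
    def test_triangular_support(self):
        spec = ParameterSpec("compliance", 0.3892, 0.2690, 0.5290, "triangular",
                             units="probability")
        draws = build_distribution(spec).rvs(size=5000, random_state=np.random.default_rng(0))
        assert draws.min() >= 0.2690 and draws.max() <= 0.5290

    def test_fixed_is_degenerate(self):
        spec = ParameterSpec("discount", 0.03, 0.03, 0.03, "fixed", units="rate")
        dist = build_distribution(spec)
        assert dist.rvs(random_state=np.random.default_rng(1)) == 0.03
        assert dist.rvs(random_state=np.random.default_rng(2)) == 0.03

    def test_beta_method_of_moments_mean(self):
        # AA utility: mean over 10,000 seeded draws reproduces the base case
        spec = ParameterSpec("utility_aa", 0.83, 0.80, 0.90, "beta", units="utility")
        draws = build_distribution(spec).rvs(size=10_000, random_state=np.random.default_rng(42))
        assert draws.mean() == pytest.approx(0.83, abs=0.005)

    def test_uniform_discount_rate_mean(self):
        spec = ParameterSpec("discount_rate", 0.03, 0.0, 0.05, "uniform", units="rate")
        draws = build_distribution(spec).rvs(size=10_000, random_state=np.random.default_rng(7))
        assert draws.mean() == pytest.approx(0.025, abs=0.001)

    def test_gamma_beta_reproduce_moments(self):
        # method-of-moments families match (mean, sd) within Monte-Carlo error
        rng = np.random.default_rng(11)
        for spec in (
            ParameterSpec("cost_treatment_aa", 1185, 593, 1778, "gamma", units="usd"),
            ParameterSpec("symptom_rate_crc2", 0.25, 0.20, 0.50, "beta", units="probability"),
        ):
            draws = build_distribution(spec).rvs(size=100_000, random_state=rng)
            sd = (spec.ui_high - spec.ui_low) / 3.92
            assert draws.mean() == pytest.approx(spec.base, rel=0.01)
            assert draws.std() == pytest.approx(sd, rel=0.03)

    def test_gamma_and_beta_domain_errors(self):
        with pytest.raises(ValueError, match="gamma"):
            build_distribution(ParameterSpec("x", 0.0, -1.0, 1.0, "gamma"))
        with pytest.raises(ValueError, match="beta"):
            build_distribution(
                ParameterSpec("x", 1.0, 0.5, 1.0, "beta", units="probability")
            )


class TestJointDraws:
    def test_same_seed_is_identical(self, params):
        assert sample_parameter_draw(params, 123) == sample_parameter_draw(params, 123)

    def test_draws_respect_support(self, params):
        for seed in (0, 1, 2):
            drawn = sample_parameter_draw(params, seed)
            df = drawn.to_frame()
            probs = df[df.units.isin(["probability", "utility"])]
            assert probs.base.between(0.0, 1.0).all()
            assert (df[df.units == "usd"].base >= 0).all()

    def test_age_bands_drawn_independently(self, params):
        drawn = sample_parameter_draw(params, 5)
        values = [v for _, v in drawn.band_items("p_normal_to_naa")]
        bases = [v for _, v in params.band_items("p_normal_to_naa")]
        offsets = np.array(values) - np.array(bases)
        assert len(set(np.round(offsets, 12))) > 1  # not a single shared shift

    def test_base_case_inside_95pct_interval_of_draws(self, params):
        # the base case is each distribution's central tendency, so it should
        # sit inside the 2.5-97.5 percentile band for nearly all parameters
        rng = np.random.default_rng(99)
        inside = total = 0
        for _, row in params.to_frame().iterrows():
            if row.distribution == "fixed" or row.ui_low == row.ui_high:
                continue
            spec = ParameterSpec(row["name"], row.base, row.ui_low, row.ui_high,
                                 row.distribution, units=row.units)
            draws = build_distribution(spec).rvs(size=2000, random_state=rng)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            inside += lo <= row.base <= hi
            total += 1
        assert inside / total >= 0.9
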