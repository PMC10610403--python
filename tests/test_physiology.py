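"""Virtual-subject construction: anthropometry, organ weights, ontogeny."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lactpbpk import physiology as phys
from lactpbpk.physiology import (
    AnthropometryError, PopulationSpec, build_adult_subject,
    build_infant_subject, sample_population,
)


class TestAdult:
    def test_cardiac_output_reference_female(self):
        s = build_adult_subject(0, 28.0, 78.0, 27.7)
        assert s.cardiac_output == pytest.approx(416.46, abs=0.01)

    def test_male_coefficient_adds_fixed_offset(self):
        f = build_adult_subject(0, 28.0, 78.0, 27.7)
        m = build_adult_subject(1, 28.0, 78.0, 27.7)
        assert m.cardiac_output - f.cardiac_output == pytest.approx(0.446 * 60)

    def test_height_identity_when_weight_equals_bmi(self):
        assert phys.height_from_bmi(25.0, 25.0) == pytest.approx(1.0)
        s = build_adult_subject(0, 28.0, 78.0, 27.7)
        assert s.height == pytest.approx((78.0 / 27.7) ** 0.5)

    def test_organ_weights_plausible(self):
        w = build_adult_subject(0, 28.0, 78.0, 27.7).organ_weights
        assert 1.0 < w["brain"] < 1.6
        assert 1.0 < w["liver"] < 2.2
        assert 0.2 < w["heart"] < 0.45
        assert w["rest"] > 0
        assert w["venous"] + w["artery"] == pytest.approx(w["blood"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(age=st.floats(18, 60), weight=st.floats(55, 110),
           bmi=st.floats(19, 35), sex=st.integers(0, 1))
    def test_mass_closure(self, age, weight, bmi, sex):
        """All organ weights plus the rest remainder sum to body weight."""
        try:
            s = build_adult_subject(sex, age, weight, bmi)
        except AnthropometryError:
            return
        total = sum(s.organ_weights[o] for o in phys.ORGANS) + s.organ_weights["blood"]
        assert total == pytest.approx(weight, rel=1e-9)

    def test_cardiac_output_monotonic_in_weight_and_age(self):
        co = phys.cardiac_output
        assert co(0, 28, 80) > co(0, 28, 78)
        assert co(0, 30, 78) < co(0, 28, 78)

    def test_flow_fractions_budget(self):
        s = build_adult_subject(0, 28.0, 78.0, 27.7)
        arterial = (sum(s.blood_flow_fractions[o] for o in phys.ORGANS
                        if o not in ("lungs", "liver"))
                    + phys.HEPATIC_ARTERIAL_FRACTION + phys.BREAST_FLOW_FRACTION)
        assert arterial <= 1.0

    def test_impossible_anthropometry_raises(self):
        with pytest.raises(AnthropometryError):
            build_adult_subject(0, 60.0, 30.0, 35.0)  # organs exceed body weight


class TestInfant:
    @pytest.mark.parametrize("age,weight", [(0.0, 4.5), (0.5, 7.5), (1.0, 10.5)])
    def test_weight_from_age(self, age, weight):
        assert phys.infant_weight(age) == weight
        assert build_infant_subject(age).weight == weight

    def test_age_out_of_range(self):
        with pytest.raises(ValueError):
            build_infant_subject(1.5)

    def test_fup_identity_at_equal_albumin(self):
        assert phys.fup_child(0.0022, 40.0, 40.0) == pytest.approx(0.0022)

    def test_bp_round_trip_at_adult_physiology(self):
        """KpRBC inverted at adult hematocrit/fup returns the adult BP."""
        kprbc = phys.kp_rbc(0.667, 0.45, 0.0022)
        assert phys.bp_child(0.0022, 0.45, kprbc) == pytest.approx(0.667)

    def test_infant_binding_less_restrictive_than_adult(self):
        baby = build_infant_subject(1 / 12)
        assert baby.fup_child > 0.0022       # lower albumin -> more unbound
        assert 0 < baby.fup_child < 1
        assert baby.bp_child > 0

    def test_cyp_ontogeny_shape(self):
        birth = build_infant_subject(0.0)
        year = build_infant_subject(1.0)
        assert birth.fcyp2c9 == pytest.approx(0.21, abs=0.02)
        assert year.fcyp2c9 > birth.fcyp2c9
        # asymptote x + z approaches the adult level
        assert phys.fcyp(100.0, x=0.79, y=0.33, z=0.21, n=1.0) == pytest.approx(1.0, abs=0.01)

    def test_ontogeny_monotone_over_first_year(self):
        ages = np.linspace(0, 1, 13)
        f = [build_infant_subject(a).fcyp2c9 for a in ages]
        assert np.all(np.diff(f) >= 0)

    def test_infant_mass_closure(self):
        baby = build_infant_subject(0.25)
        total = sum(baby.organ_weights[o] for o in phys.ORGANS) + baby.organ_weights["blood"]
        assert total == pytest.approx(baby.weight, rel=1e-9)


class TestPopulation:
    def test_seeded_reproducibility(self):
        spec = PopulationSpec(n=20, seed=1)
        a = sample_population(spec)
        b = sample_population(spec)
        assert [d.subject.weight for d in a] == [d.subject.weight for d in b]
        assert [d.kp_breast_fraction for d in a] == [d.kp_breast_fraction for d in b]

    def test_zero_cv_degenerates_to_typical(self):
        spec = PopulationSpec(n=5, weight_cv=0.0, cyp_cv=0.0,
                              kp_breast_fraction_range=(0.5, 0.5),
                              milk_volume_sd_L=0.0, seed=3)
        draws = sample_population(spec)
        assert all(d.subject.weight == 78.0 for d in draws)
        assert all(d.cyp_multiplier == 1.0 for d in draws)

    def test_large_sample_mean_weight(self):
        draws = sample_population(PopulationSpec(n=10000, seed=7))
        mean = np.mean([d.subject.weight for d in draws])
        assert mean == pytest.approx(78.0, rel=0.01)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PopulationSpec(n=0)
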