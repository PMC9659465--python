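import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import broilerne as b
from broilerne.study_io import CageObservation, ChamberObservation, DietAssay


def make_cage(**kw):
    base = dict(run_id="r1", diet_id="d", replicate_id="c1", n_birds=8,
                days=3, bw_initial=356.0, bw_final=472.0,
                feed_intake_dm=1344.0, excreta_dm=500.0, excreta_ge=14.0,
                feed_n=32.0, excreta_n=40.0)
    base.update(kw)
    return CageObservation(**base)


def make_chamber(**kw):
    base = dict(run_id="r1", diet_id="d", chamber_id="ch1", n_birds=4,
                days=3, bw_initial=356.38, bw_final=472.30,
                feed_intake_dm=676.44, o2_consumed=300.0, co2_produced=300.0)
    base.update(kw)
    return ChamberObservation(**base)


class TestMetabolicWeight:
    def test_one_kg_is_unity(self):
        assert b.metabolic_weight(1000.0) == pytest.approx(1.0)

    def test_printed_reference_bird(self):
        assert b.metabolic_weight(414.34) == pytest.approx(0.5397, abs=5e-4)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            b.metabolic_weight(0.0)


class TestPerformance:
    def test_arithmetic_by_construction(self):
        obs = make_cage(bw_initial=300.0, bw_final=420.0, n_birds=4,
                        feed_intake_dm=720.0)
        perf = b.performance(obs)
        assert perf.abw == pytest.approx(360.0)
        assert perf.adg == pytest.approx(40.0)
        assert perf.fi == pytest.approx(60.0)
        assert perf.fcr == pytest.approx(1.5)

    def test_zero_gain_gives_absent_fcr(self, caplog):
        obs = make_cage(bw_initial=400.0, bw_final=400.0)
        assert b.performance(obs).fcr is None


class TestHeatProduction:
    def test_zero_gas_zero_heat(self):
        assert b.thp_from_gas(0.0, 0.0) == 0.0

    def test_unit_volumes_sum_coefficients(self):
        assert b.thp_from_gas(1.0, 1.0) == pytest.approx(21.1961)

    def test_worked_volumes(self):
        assert b.thp_from_gas(100.0, 99.0) == pytest.approx(2114.589, abs=2e-3)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            b.thp_from_gas(-1.0, 0.0)

    @given(o2=st.floats(0, 1e4), co2=st.floats(0, 1e4),
           scale=st.floats(1, 10))
    def test_linear_and_monotone(self, o2, co2, scale):
        base = b.thp_from_gas(o2, co2)
        assert b.thp_from_gas(scale * o2, scale * co2) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-9)
        assert b.thp_from_gas(o2 + 1, co2) > base
        assert b.thp_from_gas(o2, co2 + 1) > base

    def test_respiratory_quotient(self):
        assert b.respiratory_quotient(50.0, 50.0) == 1.0
        assert b.respiratory_quotient(100.0, 98.0) == pytest.approx(0.98)
        with pytest.raises(ValueError):
            b.respiratory_quotient(0.0, 10.0)


class TestDietAme:
    ASSAY = DietAssay(diet_id="d", dm=93.5, ge=18.8, cp=22.0)

    def test_zero_excreta_boundary(self):
        obs = make_cage(excreta_dm=0.0)
        ame, amen, _ = b.diet_ame(obs, self.ASSAY)
        assert ame == pytest.approx(self.ASSAY.ge)
        assert amen == pytest.approx(ame - 34.39 * obs.feed_n / 1000.0)

    def test_zero_retention_identity(self):
        obs = make_cage()
        # excreta N chosen so N out exactly equals N in
        obs = make_cage(excreta_n=obs.feed_n * obs.feed_intake_dm
                        / obs.excreta_dm)
        ame, amen, tnr = b.diet_ame(obs, self.ASSAY)
        assert amen == pytest.approx(ame, abs=1e-12)
        assert tnr == pytest.approx(0.0, abs=1e-12)

    @given(exc=st.floats(0, 900), exc_n=st.floats(0, 30))
    def test_n_correction_never_raises_ame(self, exc, exc_n):
        obs = make_cage(excreta_dm=exc, excreta_n=exc_n)
        ame, amen, _ = b.diet_ame(obs, self.ASSAY)
        tnr_kg = obs.feed_n - exc_n * exc / obs.feed_intake_dm
        if tnr_kg >= 0:
            assert amen <= ame + 1e-12


class TestEnergyBalance:
    def test_conservation_invariants(self):
        bal = b.energy_balance(make_chamber(), ame=13.29,
                               tnr_per_kg_feed=6.7)
        assert abs(bal.amei - bal.nei - bal.hi) < 1e-9
        assert abs(bal.re - (bal.amei - bal.thp)) < 1e-9
        assert abs(bal.re_fat - (bal.re - bal.re_protein)) < 1e-9
        assert bal.hi == bal.thp - bal.fhp

    def test_printed_reference_diet_worked_example(self):
        # ABW 414.34 g, FI 56.37 g DM/d, AME 13.29 MJ/kg DM -> AMEI 1.38;
        # THP 0.98 and RQ 1.00 back-solved into gas volumes -> HI 0.53
        mbw = b.metabolic_weight(414.34)
        thp_kj = 0.98 * mbw * 1000.0 * 4 * 3
        o2 = thp_kj / (16.1753 + 5.0208 * 1.00)
        obs = make_chamber(feed_intake_dm=56.37 * 3 * 4,
                           o2_consumed=o2, co2_produced=o2)
        bal = b.energy_balance(obs, ame=13.29)
        assert bal.amei == pytest.approx(1.38, abs=0.02)
        assert bal.thp == pytest.approx(0.98, abs=1e-6)
        assert bal.hi == pytest.approx(0.53, abs=0.01)
        assert bal.nei == pytest.approx(0.85, abs=0.02)

    def test_missing_tnr_leaves_protein_partition_absent(self):
        bal = b.energy_balance(make_chamber(), ame=13.0)
        assert bal.re_protein is None and bal.re_fat is None

    def test_negative_hi_flagged_not_clipped(self):
        obs = make_chamber(o2_consumed=10.0, co2_produced=10.0)
        bal = b.energy_balance(obs, ame=13.0)
        assert bal.hi < 0
        assert "negative_hi" in bal.flags


class TestDietNetEnergy:
    def test_zero_heat_increment_limit(self):
        de = b.diet_net_energy(13.29, 1.5, 1.5)
        assert de.ne == pytest.approx(13.29)

    def test_worked_ratio(self):
        de = b.diet_net_energy(13.29, 1.388, 0.938)
        assert de.ne == pytest.approx(8.98, abs=0.01)

    def test_printed_wheat1_utilization(self):
        # printed ingredient values: NE 9.34, AME 12.93 -> NE/AME 72.24%
        assert 100 * 9.34 / 12.93 == pytest.approx(72.24, abs=0.01)

    def test_non_positive_intake_rejected(self):
        with pytest.raises(ValueError):
            b.diet_net_energy(13.0, 0.0, 0.5)

    @given(ame=st.floats(5, 16), x=st.floats(0.1, 3))
    def test_identity_when_nei_equals_amei(self, ame, x):
        assert b.diet_net_energy(ame, x, x).ne == pytest.approx(
            ame, rel=1e-12)


def test_constants_must_be_positive():
    with pytest.raises(ValueError):
        b.EnergyConstants(fhp_coef=0.0)
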