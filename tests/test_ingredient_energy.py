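import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import broilerne as b
from broilerne import datasets
from broilerne.ingredient_energy import (PRINTED_SCHEME, SubstitutionScheme,
                                         ingredient_energy,
                                         substitution_levels,
                                         summarize_samples)


class TestSubstitutionScheme:
    def test_printed_constants(self):
        assert PRINTED_SCHEME.a_pct == 67.58
        assert PRINTED_SCHEME.b_pct == 31.32

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionScheme(a_pct=80.0, b_pct=30.0)
        with pytest.raises(ValueError):
            SubstitutionScheme(a_pct=0.0, b_pct=30.0)


class TestSubstitutionLevels:
    def test_two_ingredient_toy_diet(self):
        ref = b.DietFormulation(diet_id="r", role="reference",
                                inclusions=[("mix", 100.0)],
                                energy_yielding_ids={"mix"})
        test = b.DietFormulation(diet_id="t", role="test",
                                 inclusions=[("mix", 70.0), ("x", 30.0)],
                                 test_ingredient_id="x",
                                 energy_yielding_ids={"mix", "x"})
        # identical DM everywhere -> air-dry shares carry over
        scheme = substitution_levels(ref, test, [], default_dm=90.0)
        assert scheme.a_pct == pytest.approx(70.0)
        assert scheme.b_pct == pytest.approx(30.0)

    def test_study_formulation_approximates_printed_constants(self):
        diets = datasets.load_diet_formulations(["wheat_1"])
        ref = next(d for d in diets if d.diet_id == "ref")
        test = next(d for d in diets if d.diet_id == "diet_wheat_1")
        comps = datasets.load_ingredient_composition()
        scheme = substitution_levels(ref, test, comps)
        # minor-ingredient DM values are unpublished, so only approximate
        assert scheme.a_pct == pytest.approx(67.58, abs=1.5)
        assert scheme.b_pct == pytest.approx(31.32, abs=2.5)

    def test_reference_diet_rejected_as_test(self):
        ref = b.DietFormulation(diet_id="r", role="reference",
                                inclusions=[("mix", 100.0)])
        with pytest.raises(ValueError):
            substitution_levels(ref, ref, [])


class TestIngredientEnergy:
    @given(e_ref=st.floats(5, 18), x=st.floats(2, 18))
    def test_exact_algebraic_inverse(self, e_ref, x):
        a, bb = PRINTED_SCHEME.a_pct / 100, PRINTED_SCHEME.b_pct / 100
        e_test = e_ref * a + x * bb
        vals = ingredient_energy(e_test, e_test, e_test,
                                 e_ref, e_ref, e_ref, PRINTED_SCHEME)
        for got in (vals.ame, vals.amen, vals.ne):
            assert got == pytest.approx(x, rel=1e-10, abs=1e-10)

    def test_zero_case(self):
        e_ref = 13.0
        e_test = e_ref * PRINTED_SCHEME.a_pct / 100
        vals = ingredient_energy(e_test, e_test, e_test, e_ref, e_ref, e_ref,
                                 PRINTED_SCHEME)
        assert vals.ame == pytest.approx(0.0, abs=1e-12)

    @given(delta=st.floats(0.01, 2.0))
    def test_monotone_in_test_diet_energy(self, delta):
        base = ingredient_energy(12.0, 12.0, 8.0, 13.0, 13.0, 8.2,
                                 PRINTED_SCHEME)
        more = ingredient_energy(12.0 + delta, 12.0, 8.0, 13.0, 13.0, 8.2,
                                 PRINTED_SCHEME)
        assert more.ame > base.ame

    def test_ratios_from_ge(self):
        vals = ingredient_energy(12.0, 11.8, 8.5, 13.0, 12.8, 8.2,
                                 PRINTED_SCHEME, ingredient_id="x", ge=18.0)
        assert vals.ame_ge == pytest.approx(100 * vals.ame / 18.0)
        assert vals.ne_ame == pytest.approx(100 * vals.ne / vals.ame)


class TestSummaries:
    def test_printed_wheat_and_bran_ne_means(self):
        wheat = summarize_samples([9.34, 10.02, 10.27, 11.33, 10.49])
        bran = summarize_samples([5.37, 5.17, 4.87, 5.06, 4.88])
        assert wheat.mean == pytest.approx(10.29, abs=0.005)
        assert bran.mean == pytest.approx(5.07, abs=0.005)

    def test_printed_wheat_and_bran_ame_means(self):
        wheat = summarize_samples([12.93, 13.10, 13.09, 13.75, 13.32])
        bran = summarize_samples([7.72, 7.09, 6.97, 6.93, 6.85])
        assert wheat.mean == pytest.approx(13.24, abs=0.005)
        assert bran.mean == pytest.approx(7.11, abs=0.005)

    def test_wheat_dm_cv(self):
        s = summarize_samples([88.60, 91.20, 89.30, 83.20, 85.00, 87.80])
        assert s.mean == pytest.approx(87.52, abs=0.005)
        assert s.cv_pct == pytest.approx(3.35, abs=0.01)

    def test_single_value_has_absent_dispersion(self):
        s = summarize_samples([5.0])
        assert s.mean == 5.0 and s.sd is None and s.cv_pct is None

    @given(st.lists(st.floats(1, 100), min_size=2, max_size=20))
    def test_matches_two_pass_oracle(self, xs):
        s = summarize_samples(xs)
        mean = sum(xs) / len(xs)
        var = sum((x - mean) ** 2 for x in xs) / (len(xs) - 1)
        assert s.mean == pytest.approx(mean, rel=1e-9)
        assert s.sd == pytest.approx(math.sqrt(var), rel=1e-9, abs=1e-12)
        assert s.cv_pct == pytest.approx(100 * math.sqrt(var) / mean,
                                         rel=1e-9, abs=1e-12)

    def test_pooled_sem_from_replicates(self):
        reps = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]]
        s = summarize_samples([2.0, 3.0], replicates=reps)
        # MSE = pooled within variance = 1.0, n_h = 3
        assert s.sem == pytest.approx(math.sqrt(1.0 / 3.0))
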