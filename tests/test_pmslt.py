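"""Life-table engine: PIF, disease dynamics, discounting, ICER, oracle checks."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import lognorm, norm

from conftest import naive_population_run
from retailcea import pmslt
from retailcea.types import AGES, DiseaseSpec


class TestPIF:
    def test_discrete_two_group_hand_calculation(self):
        """Half the population at RR 2 shifted to a quarter: PIF = 1/6."""
        pif = pmslt.compute_pif_discrete([0.5, 0.5], [0.75, 0.25], [1.0, 2.0])
        assert pif == pytest.approx((1.5 - 1.25) / 1.5, abs=1e-12)
        assert pif == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_distributions_give_exact_zero(self):
        assert pmslt.compute_pif(27.0, 4.5, 0.0, 1.2) == 0.0

    def test_flat_risk_gives_exact_zero(self):
        assert pmslt.compute_pif(27.0, 4.5, -0.5, 1.0) == 0.0

    def test_positive_for_downshift_with_harmful_rr(self):
        assert pmslt.compute_pif(27.0, 4.5, -0.3, 1.15) > 0.0
        assert pmslt.compute_pif(27.0, 4.5, -0.3, 1.15) <= 1.0

    def test_sd_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share sd"):
            pmslt.compute_pif(27.0, 4.5, -0.3, 1.15, shifted_sd=5.0)

    @pytest.mark.parametrize("form", ["lognormal", "normal"])
    def test_quadrature_cross_check(self, form):
        """The fixed-grid integral matches adaptive quadrature on the same support."""
        mean, sd, delta, rr, tm = 27.0, 4.8, -0.33, 1.25, 21.0
        lo, hi = 10.0, 60.0

        def dist(m):
            if form == "lognormal":
                s2 = np.log1p((sd / m) ** 2)
                return lognorm(s=np.sqrt(s2), scale=np.exp(np.log(m) - s2 / 2))
            return norm(loc=m, scale=sd)

        def expect(m):
            f = dist(m)
            num = quad(lambda x: rr ** max(0.0, x - tm) * f.pdf(x), lo, hi, limit=300)[0]
            den = quad(f.pdf, lo, hi, limit=300)[0]
            return num / den

        oracle = (expect(mean) - expect(mean + delta)) / expect(mean)
        ours = pmslt.compute_pif(mean, sd, delta, rr, form=form)
        assert ours == pytest.approx(oracle, rel=2e-4)

    def test_broadcasting_matches_scalar_calls(self):
        means = np.array([24.0, 27.0, 30.0])
        got = pmslt.compute_pif(means, 4.0, -0.3, 1.2)
        want = [pmslt.compute_pif(m, 4.0, -0.3, 1.2) for m in means]
        np.testing.assert_allclose(got, want, rtol=1e-14)


class TestDiscounting:
    def test_zero_rate_is_arithmetic_sum(self):
        assert pmslt.discount_stream([3.0, 4.0, 5.0], 0.0) == pytest.approx(12.0)

    def test_single_step(self):
        assert pmslt.discount_stream([0.0, 100.0], 0.03) == pytest.approx(97.0874, abs=1e-4)

    def test_unit_stream_100_cycles_matches_direct_summation(self):
        direct = sum(1.0 / 1.03**t for t in range(100))
        assert pmslt.discount_stream(np.ones(100), 0.03) == pytest.approx(direct, abs=1e-9)
        assert direct == pytest.approx(32.54, abs=1e-2)


class TestICER:
    def test_dominant(self):
        assert pmslt.compute_icer(0.37e6, -4411.81e6) == "Dominant"

    def test_dominated(self):
        assert pmslt.compute_icer(-5.0, 10.0) == "Dominated"

    def test_ratio(self):
        assert pmslt.compute_icer(10.0, 100.0) == pytest.approx(10.0)

    def test_zero_halys_labelled_undefined(self):
        assert pmslt.compute_icer(0.0, 5.0) == "undefined (no health gain)"

    def test_no_numeric_icer_when_dominant(self):
        out = pmslt.compute_icer(1.0, -1.0)
        assert isinstance(out, str)


def _constant_disease(incidence, remission=0.0, case_fatality=0.0, dw=0.1,
                      cost=1000.0, rr=1.2, min_age=2, prevalence=0.0):
    ages = np.asarray(AGES, float)
    frames = []
    for sex in ("male", "female"):
        frames.append(pd.DataFrame({
            "age": ages.astype(int), "sex": sex,
            "incidence": np.full_like(ages, incidence),
            "prevalence": np.full_like(ages, prevalence),
            "case_fatality": np.full_like(ages, case_fatality),
            "remission": np.full_like(ages, remission),
            "disability_weight": np.full_like(ages, dw),
            "annual_cost_per_case": np.full_like(ages, cost),
            "rr_per_bmi_unit": np.full_like(ages, rr),
            "min_age": min_age,
        }))
    return DiseaseSpec("diabetes", pd.concat(frames, ignore_index=True), min_age=min_age)


def _flat_lifetable(acm=0.01):
    ages = np.asarray(AGES, float)
    frames = []
    for sex in ("male", "female"):
        frames.append(pd.DataFrame({
            "age": ages.astype(int), "sex": sex,
            "all_cause_mortality": np.full_like(ages, acm),
            "background_pyld": np.full_like(ages, 0.05)}))
    return pd.concat(frames, ignore_index=True)


class TestDiseaseSubmodel:
    def test_closed_form_prevalence_no_remission_no_fatality(self):
        """With r = f = 0, no background mortality and constant incidence i,
        alive prevalence after n cycles is 1 - (1 - i)^n."""
        i = 0.05
        spec = _constant_disease(incidence=i)
        traj = pmslt.run_disease_submodel(spec, {}, _flat_lifetable(0.0),
                                          "male", start_age=40, n_cycles=11)
        for n in range(11):
            assert traj.loc[n, "prevalence"] == pytest.approx(1 - (1 - i) ** n, abs=1e-9)

    def test_matches_brute_force_loop(self):
        """Four-state updates equal an independently coded per-year loop."""
        spec = _constant_disease(incidence=0.03, remission=0.01, case_fatality=0.02,
                                 prevalence=0.1, min_age=2)
        lt = _flat_lifetable(0.015)
        traj = pmslt.run_disease_submodel(spec, {50: 0.2}, lt, "female",
                                          start_age=45, n_cycles=10)
        s, c, dd, do = 0.9, 0.1, 0.0, 0.0
        for n in range(10):
            age = 45 + n
            assert traj.loc[n, "healthy"] == pytest.approx(s, abs=1e-12)
            assert traj.loc[n, "diseased"] == pytest.approx(c, abs=1e-12)
            assert traj.loc[n, "dead_disease"] == pytest.approx(dd, abs=1e-12)
            assert traj.loc[n, "dead_other"] == pytest.approx(do, abs=1e-12)
            i = 0.03 * (1 - (0.2 if age == 50 else 0.0))
            r, f = 0.01, 0.02
            m = max(0.0, 0.015 - f * 0.1)
            s, c, dd, do = (s - s * i + c * r - s * m,
                            c + s * i - c * r - c * f - c * m,
                            dd + c * f, do + (s + c) * m)

    def test_occupancies_conserved(self):
        spec = _constant_disease(incidence=0.04, remission=0.02, case_fatality=0.03,
                                 prevalence=0.2)
        traj = pmslt.run_disease_submodel(spec, {}, _flat_lifetable(0.02), "male",
                                          start_age=30)
        total = traj[["healthy", "diseased", "dead_disease", "dead_other"]].sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-9

    def test_null_pif_leaves_trajectory_unchanged(self):
        spec = _constant_disease(incidence=0.04, case_fatality=0.03, prevalence=0.2)
        lt = _flat_lifetable(0.02)
        a = pmslt.run_disease_submodel(spec, {}, lt, "male", start_age=30)
        b = pmslt.run_disease_submodel(spec, {a: 0.0 for a in range(30, 101)}, lt,
                                       "male", start_age=30)
        pd.testing.assert_frame_equal(a, b)

    def test_halving_incidence_weakly_decreases_prevalence(self):
        lt = _flat_lifetable(0.02)
        hi = pmslt.run_disease_submodel(_constant_disease(incidence=0.04), {}, lt,
                                        "male", start_age=30)
        lo = pmslt.run_disease_submodel(_constant_disease(incidence=0.02), {}, lt,
                                        "male", start_age=30)
        assert (lo["prevalence"] <= hi["prevalence"] + 1e-15).all()


class TestEngineAgainstNaiveOracle:
    def test_population_totals_match_to_1e9(self, toy_bundle):
        """Vectorised engine equals the scalar per-year loop on the toy."""
        impact = toy_bundle.population[["age", "sex"]].copy()
        impact["delta_bmi"] = -0.4
        model = pmslt.PMSLTModel(toy_bundle, discount_rate=0.03)
        got = model.evaluate(impact)
        want = naive_population_run(toy_bundle, impact, discount_rate=0.03)
        assert got["halys"] == pytest.approx(want["halys"], rel=1e-9)
        assert got["healthcare_cost"] == pytest.approx(want["healthcare_cost"], rel=1e-9)

    def test_cohort_life_table_matches_oracle_per_cycle(self, toy_bundle):
        base, inter = pmslt.run_cohort(60, "male", -0.4, toy_bundle, discount_rate=0.0)
        # oracle for the baseline arm survivors: explicit loop
        names = list(toy_bundle.diseases)
        lt = toy_bundle.lifetable
        lt_m = lt[lt["sex"] == "male"].set_index("age")
        dis = {n: toy_bundle.diseases[n].table.query("sex=='male'").set_index("age")
               for n in names}
        state = {n: [1 - dis[n].loc[60, "prevalence"], dis[n].loc[60, "prevalence"], 0, 0]
                 for n in names}
        l = 1.0
        for t in range(41):
            age = 60 + t
            assert base.loc[t, "survivors"] == pytest.approx(l, abs=1e-9)
            mort = float(lt_m.loc[age, "all_cause_mortality"])
            for n in names:
                s, c, dd, do = state[n]
                i = float(dis[n].loc[age, "incidence"])
                r = float(dis[n].loc[age, "remission"])
                f = float(dis[n].loc[age, "case_fatality"])
                m = max(0.0, mort - f * float(dis[n].loc[age, "prevalence"]))
                state[n] = [s - s * i + c * r - s * m, c + s * i - c * r - c * f - c * m,
                            dd + c * f, do + (s + c) * m]
            l *= 1.0 - mort

    def test_survivors_non_increasing_and_halys_below_life_years(self, toy_bundle):
        base, inter = pmslt.run_cohort(55, "female", -0.3, toy_bundle)
        assert (np.diff(base["survivors"]) <= 1e-15).all()
        assert (base["halys"] <= base["life_years"] + 1e-15).all()
        assert (inter["survivors"] >= base["survivors"] - 1e-15).all()

    def test_zero_shift_gives_identical_arms(self, toy_bundle):
        base, inter = pmslt.run_cohort(60, "male", 0.0, toy_bundle)
        pd.testing.assert_frame_equal(base, inter)


class TestPopulationRuns:
    def test_null_effect_zero_increments(self, bundle_small):
        impact = bundle_small.population[["age", "sex"]].copy()
        impact["delta_bmi"] = 0.0
        model = pmslt.PMSLTModel(bundle_small)
        res = model.evaluate(impact)
        assert res["halys"] == 0.0
        assert res["healthcare_cost"] == 0.0

    def test_larger_shift_gives_more_halys(self, bundle_small):
        model = pmslt.PMSLTModel(bundle_small)
        impact = bundle_small.population[["age", "sex"]].copy()
        impact["delta_bmi"] = -0.2
        one = model.evaluate(impact)["halys"]
        impact["delta_bmi"] = -0.4
        two = model.evaluate(impact)["halys"]
        assert two > one > 0

    def test_short_horizon_yields_fewer_halys(self, bundle_small):
        impact = bundle_small.population[["age", "sex"]].copy()
        impact["delta_bmi"] = -0.3
        life = pmslt.PMSLTModel(bundle_small).evaluate(impact)["halys"]
        ten = pmslt.PMSLTModel(bundle_small, horizon_years=10).evaluate(impact)["halys"]
        assert 0 < ten < life

    def test_discount_rate_ordering(self, bundle_small):
        impact = bundle_small.population[["age", "sex"]].copy()
        impact["delta_bmi"] = -0.3
        h = {r: pmslt.PMSLTModel(bundle_small, discount_rate=r).evaluate(impact)["halys"]
             for r in (0.03, 0.07, 0.10)}
        assert h[0.03] > h[0.07] > h[0.10]

    def test_conservation_error_within_1e9(self, bundle_small):
        impact = bundle_small.population[["age", "sex"]].copy()
        impact["delta_bmi"] = -0.3
        res = pmslt.PMSLTModel(bundle_small).evaluate(impact)
        assert res["conservation_error"] < 1e-9
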