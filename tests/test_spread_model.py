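import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synspread.spread_model import (
    ModelEvaluation,
    MultiplicityMix,
    TwoPopulationModel,
    evaluate,
    evaluate_mixture,
    labeling_probability,
    minimize_if_sf_over_R,
    solve_unitary_efficiency,
    sweep_curves,
    write_sweep_csv,
)

# Frozen oracle values, computed independently with scipy.optimize.brentq /
# bounded minimize_scalar on the displayed closed forms.
U_SOLVED_R10 = 0.361529034704957
U_SOLVED_R2 = 0.295840542120771
MIN_RATIO_U022 = 0.794596823014455
ARGMIN_R_U028 = 1.854723699720452


class TestLabelingProbability:
    def test_single_contact_reduces_to_u(self):
        assert labeling_probability(0.28, 1) == pytest.approx(0.28)

    def test_zero_efficiency(self):
        assert labeling_probability(0.0, 5) == 0.0

    def test_two_contacts(self):
        assert labeling_probability(0.28, 2) == pytest.approx(0.4816, abs=1e-12)

    def test_bounds(self):
        p = labeling_probability(0.1, 7)
        assert 0.1 <= p <= min(1.0, 0.7)

    @pytest.mark.parametrize("U", [-0.01, 1.01, float("nan")])
    def test_bad_u_raises(self, U):
        with pytest.raises(ValueError, match="U"):
            labeling_probability(U, 1)

    @pytest.mark.parametrize("M", [0, -1])
    def test_bad_m_raises(self, M):
        with pytest.raises(ValueError, match="M"):
            labeling_probability(0.3, M)


class TestTypes:
    def test_model_invariants(self):
        with pytest.raises(ValueError, match="R"):
            TwoPopulationModel(R=0, Ma=1, Mb=2, U=0.3)
        with pytest.raises(ValueError, match="Ma"):
            TwoPopulationModel(R=1, Ma=0, Mb=2, U=0.3)
        with pytest.raises(ValueError, match="U"):
            TwoPopulationModel(R=1, Ma=1, Mb=2, U=1.2)

    def test_mix_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MultiplicityMix([(1, 0.5), (2, 0.4)])

    def test_mix_distinct_m(self):
        with pytest.raises(ValueError, match="distinct"):
            MultiplicityMix([(2, 0.5), (2, 0.5)])

    def test_mix_empty(self):
        with pytest.raises(ValueError, match="non-empty"):
            MultiplicityMix([])

    def test_mix_mean(self):
        mix = MultiplicityMix([(1, 0.92), (2, 0.067), (3, 0.013)])
        assert mix.mean_multiplicity == pytest.approx(1.093)


class TestEvaluate:
    def test_printed_scenario(self):
        ev = evaluate(TwoPopulationModel(R=2, Ma=1, Mb=2, U=0.28))
        assert ev.IF == pytest.approx(0.3472, abs=1e-9)
        assert ev.SF == pytest.approx(0.3808, abs=1e-9)
        assert ev.ratio == pytest.approx(0.91, abs=0.005)

    def test_high_r_scenario(self):
        ev = evaluate(TwoPopulationModel(R=10, Ma=1, Mb=2, U=0.35))
        assert ev.ratio == pytest.approx(0.95, abs=0.01)

    @pytest.mark.parametrize("R,U", [(0.5, 0.1), (3.0, 0.7), (42.0, 0.999)])
    def test_equal_multiplicity_gives_equal_fractions(self, R, U):
        ev = evaluate(TwoPopulationModel(R=R, Ma=3, Mb=3, U=U))
        assert ev.IF == pytest.approx(ev.SF, abs=1e-14)
        assert ev.ratio == pytest.approx(1.0)

    def test_ratio_defined_at_zero_sf(self):
        ev = evaluate(TwoPopulationModel(R=2, Ma=1, Mb=2, U=0.0))
        assert ev.SF == 0.0 and ev.ratio == 1.0


class TestEvaluateMixture:
    def test_single_population_m1(self):
        ev = evaluate_mixture(MultiplicityMix([(1, 1.0)]), 0.4)
        assert ev.IF == pytest.approx(0.4) and ev.SF == pytest.approx(0.4)

    def test_matches_two_population_form(self):
        mix = MultiplicityMix([(1, 2 / 3), (2, 1 / 3)])
        ev = evaluate_mixture(mix, 0.28)
        ref = evaluate(TwoPopulationModel(R=2, Ma=1, Mb=2, U=0.28))
        assert ev.IF == pytest.approx(ref.IF, abs=1e-12)
        assert ev.SF == pytest.approx(ref.SF, abs=1e-12)

    def test_zero_efficiency(self):
        mix = MultiplicityMix([(1, 0.92), (2, 0.067), (3, 0.013)])
        ev = evaluate_mixture(mix, 0.0)
        assert ev.IF == 0.0 and ev.SF == 0.0


class TestSolveUnitaryEfficiency:
    def test_r10_scenario_frozen_oracle(self):
        assert solve_unitary_efficiency(0.4, 10, 1, 2) == pytest.approx(
            U_SOLVED_R10, abs=1e-8
        )

    def test_r2_scenario_frozen_oracle(self):
        assert solve_unitary_efficiency(0.4, 2, 1, 2) == pytest.approx(
            U_SOLVED_R2, abs=1e-8
        )

    def test_round_trip(self):
        sf = evaluate(TwoPopulationModel(R=3, Ma=1, Mb=3, U=0.22)).SF
        assert solve_unitary_efficiency(sf, 3, 1, 3) == pytest.approx(0.22, abs=1e-8)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.2, 1.5])
    def test_target_out_of_range(self, target):
        with pytest.raises(ValueError, match="SF_target"):
            solve_unitary_efficiency(target, 2, 1, 2)


class TestMinimizeRatio:
    def test_worst_case_scenario(self):
        _, ratio_star = minimize_if_sf_over_R(0.22, 1, 3, 0.01, 100.0)
        assert ratio_star == pytest.approx(MIN_RATIO_U022, abs=1e-6)
        assert round(ratio_star, 1) == 0.8

    def test_argmin_near_two(self):
        r_star, _ = minimize_if_sf_over_R(0.28, 1, 2, 0.01, 100.0)
        assert r_star == pytest.approx(ARGMIN_R_U028, rel=1e-4)
        assert r_star == pytest.approx(2.0, abs=0.3)

    def test_equal_multiplicity_flat(self):
        _, ratio_star = minimize_if_sf_over_R(0.5, 2, 2, 0.1, 10.0)
        assert ratio_star == pytest.approx(1.0)

    def test_invalid_bracket(self):
        with pytest.raises(ValueError, match="R_min"):
            minimize_if_sf_over_R(0.3, 1, 2, 5.0, 1.0)


class TestSweep:
    def test_degenerate_grid_equals_evaluate(self):
        df = sweep_curves([0.28], [2.0], 1, 2)
        assert len(df) == 1
        ref = evaluate(TwoPopulationModel(R=2, Ma=1, Mb=2, U=0.28))
        assert df.loc[0, "SF"] == pytest.approx(ref.SF)
        assert df.loc[0, "IF"] == pytest.approx(ref.IF)

    def test_hand_evaluated_ratio_column(self):
        df = sweep_curves([0.28], [1.0, 2.0, 3.0], 1, 2)
        assert [round(x, 3) for x in df["ratio"]] == [0.919, 0.912, 0.916]

    def test_sf_nondecreasing_in_u(self):
        df = sweep_curves([0.1, 0.2, 0.3, 0.4], [0.5, 2.0, 8.0], 1, 3)
        for _, sub in df.groupby("R"):
            sf = sub.sort_values("U")["SF"].to_numpy()
            assert np.all(np.diff(sf) >= 0)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            sweep_curves([], [1.0], 1, 2)

    def test_csv_header(self, tmp_path):
        df = sweep_curves([0.28], [1.0, 2.0], 1, 2)
        out = tmp_path / "sweep.csv"
        write_sweep_csv(df, out)
        assert out.read_text().splitlines()[0] == "U,R,Ma,Mb,SF,IF,ratio"


model_params = st.tuples(
    st.floats(min_value=0.01, max_value=100.0),
    st.integers(min_value=1, max_value=6),
    st.integers(min_value=1, max_value=6),
    st.floats(min_value=0.0, max_value=1.0),
)


class TestProperties:
    @given(model_params)
    def test_if_le_sf_with_equality_cases(self, params):
        R, Ma, Mb, U = params
        ev = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=U))
        assert 0.0 <= ev.IF <= ev.SF + 1e-12 <= 1.0 + 1e-12
        if Ma == Mb or U in (0.0, 1.0):
            assert ev.IF == pytest.approx(ev.SF, abs=1e-12)
        elif 0.01 <= U <= 0.99:  # away from float-precision corners
            assert ev.IF < ev.SF

    @given(model_params)
    def test_mixture_agrees_with_two_population(self, params):
        R, Ma, Mb, U = params
        ev = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=U))
        mix = MultiplicityMix.from_two_populations(R, Ma, Mb)
        evm = evaluate_mixture(mix, U)
        assert evm.IF == pytest.approx(ev.IF, abs=1e-12)
        assert evm.SF == pytest.approx(ev.SF, abs=1e-12)

    @given(
        st.tuples(
            st.floats(min_value=0.05, max_value=20.0),
            st.integers(min_value=1, max_value=5),
            st.integers(min_value=1, max_value=5),
            st.floats(min_value=0.01, max_value=0.99),
        )
    )
    @settings(max_examples=50)
    def test_solve_round_trip(self, params):
        R, Ma, Mb, U = params
        sf = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=U)).SF
        assert solve_unitary_efficiency(sf, R, Ma, Mb) == pytest.approx(U, abs=1e-8)

    @pytest.mark.parametrize("R,Ma,Mb", [(2.0, 1, 2), (0.5, 1, 3), (10.0, 2, 5)])
    def test_small_u_limit_matches_analytic_derivative(self, R, Ma, Mb):
        # d(IF)/dU at 0 = (R*Ma + Mb)/(R+1); d(SF)/dU at 0 = (R*Ma^2 + Mb^2)/(R*Ma + Mb)
        U = 1e-6
        ev = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=U))
        d_if = (R * Ma + Mb) / (R + 1.0)
        d_sf = (R * Ma**2 + Mb**2) / (R * Ma + Mb)
        assert ev.IF / U == pytest.approx(d_if, rel=1e-4)
        assert ev.SF / U == pytest.approx(d_sf, rel=1e-4)

    def test_boundary_values(self):
        for R, Ma, Mb in [(2.0, 1, 2), (7.0, 3, 1)]:
            ev0 = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=0.0))
            ev1 = evaluate(TwoPopulationModel(R=R, Ma=Ma, Mb=Mb, U=1.0))
            assert ev0.IF == 0.0 and ev0.SF == 0.0
            assert ev1.IF == pytest.approx(1.0) and ev1.SF == pytest.approx(1.0)
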