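import numpy as np
import pandas as pd
import pytest

from abcbind.errors import FitError
from abcbind.kinetics import (
    compare_curves,
    delta_table,
    fit_dose_response,
    fit_michaelis_menten,
    michaelis_menten,
    read_dose_response,
    vanadate_sensitive_activity,
    write_dose_response,
)
from abcbind.model import DoseResponse, KineticFit
from abcbind.synthetic import generate_mm_data

GRID7 = np.array([1.0, 5.0, 10.0, 50.0, 100.0, 400.0, 800.0])


def make_dose_response(pairs, substrate="digoxin"):
    return DoseResponse(
        substrate_id=substrate,
        data=pd.DataFrame(
            [(s, 1, a, b) for s, (a, b) in pairs],
            columns=["concentration_uM", "replicate",
                     "activity_no_vanadate", "activity_vanadate"],
        ),
    )


class TestVanadateDifferencing:
    def test_identical_pair_gives_zero(self):
        d = make_dose_response([(10.0, (4.2, 4.2))])
        assert vanadate_sensitive_activity(d)["activity"].iloc[0] == 0.0

    def test_simple_difference(self):
        d = make_dose_response([(10.0, (10.0, 3.5))])
        assert vanadate_sensitive_activity(d)["activity"].iloc[0] == pytest.approx(6.5)

    def test_elementwise_against_independent_loop(self):
        rng = np.random.default_rng(50)
        pairs = [
            (float(s), (float(rng.uniform(0, 30)), float(rng.uniform(0, 10))))
            for s in rng.uniform(0, 800, size=20)
        ]
        d = make_dose_response(pairs)
        out = vanadate_sensitive_activity(d)["activity"].to_numpy()
        oracle = [a - b for _, (a, b) in pairs]
        np.testing.assert_allclose(out, oracle)

    def test_negative_differences_retained(self):
        d = make_dose_response([(10.0, (1.0, 3.0))])
        assert vanadate_sensitive_activity(d)["activity"].iloc[0] == -2.0

    def test_unpaired_measurement_rejected(self):
        d = make_dose_response([(10.0, (5.0, np.nan))])
        with pytest.raises(ValueError, match="unpaired"):
            vanadate_sensitive_activity(d)


class TestMichaelisMentenFit:
    def test_noiseless_data_recovered_to_1e6(self):
        v = michaelis_menten(GRID7, 20.0, 10.0)
        fit = fit_michaelis_menten(GRID7, v)
        assert fit.vmax == pytest.approx(20.0, abs=1e-6)
        assert fit.km == pytest.approx(10.0, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_velocity_at_km_is_half_vmax(self):
        v = michaelis_menten(GRID7, 20.0, 10.0)
        fit = fit_michaelis_menten(GRID7, v)
        assert fit.velocity(fit.km) == pytest.approx(fit.vmax / 2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(51)
        v = michaelis_menten(GRID7, 15.0, 40.0) + rng.normal(0, 0.5, GRID7.size)
        base = fit_michaelis_menten(GRID7, v)
        scaled = fit_michaelis_menten(GRID7, 3.0 * v)
        assert scaled.vmax == pytest.approx(3.0 * base.vmax, rel=1e-6)
        assert scaled.km == pytest.approx(base.km, rel=1e-6)

    def test_km_within_2se_of_truth_in_90pct_of_simulations(self):
        """Coverage calibration of the curvature-based Km SE at 5% noise,
        7-point grid, 5 replicates."""
        vmax, km = 20.0, 10.0
        hits = 0
        n_sim = 200
        for seed in range(n_sim):
            rng = np.random.default_rng(1000 + seed)
            s = np.tile(GRID7, 5)
            v = michaelis_menten(s, vmax, km) + rng.normal(0, 0.05 * vmax, s.size)
            fit = fit_michaelis_menten(s, v)
            if abs(fit.km - km) <= 2 * fit.km_se:
                hits += 1
        assert hits / n_sim >= 0.90

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(FitError, match="distinct"):
            fit_michaelis_menten([0.0, 10.0, 10.0, 50.0], [0.0, 5.0, 5.1, 8.0])

    def test_all_zero_activities_rejected(self):
        with pytest.raises(FitError, match="zero"):
            fit_michaelis_menten(GRID7, np.zeros_like(GRID7))

    def test_dose_response_pipeline_with_zero_noise(self):
        d = generate_mm_data(12.54, 9.33, sigma_frac=0.0, seed=1)
        fit = fit_dose_response(d)
        assert fit.vmax == pytest.approx(12.54, abs=1e-6)
        assert fit.km == pytest.approx(9.33, abs=1e-6)

    def test_minimal_three_point_single_replicate_converges(self):
        d = generate_mm_data(
            12.0, 8.0, grid=(2.0, 20.0, 200.0), replicates=1,
            sigma_frac=0.0, seed=2,
        )
        fit = fit_dose_response(d)
        assert fit.km == pytest.approx(8.0, abs=1e-5)


class TestCompareCurves:
    def test_identical_noiseless_data_give_f_zero_p_one(self):
        v = michaelis_menten(GRID7, 20.0, 10.0)
        cc = compare_curves(GRID7, v, GRID7, v)
        assert cc.f_statistic == 0.0
        assert cc.p_value == 1.0

    def test_identical_noisy_data_give_f_near_zero(self):
        rng = np.random.default_rng(52)
        v = michaelis_menten(GRID7, 20.0, 10.0) + rng.normal(0, 1.0, GRID7.size)
        cc = compare_curves(GRID7, v, GRID7, v)
        assert cc.f_statistic == pytest.approx(0.0, abs=1e-6)
        assert cc.p_value > 0.99

    def test_twofold_km_difference_detected(self):
        rng = np.random.default_rng(53)
        grid8 = np.array([1.0, 5.0, 10.0, 25.0, 50.0, 100.0, 400.0, 800.0])
        va = michaelis_menten(grid8, 20.0, 10.0) + rng.normal(0, 1.0, 8)
        vb = michaelis_menten(grid8, 20.0, 20.0) + rng.normal(0, 1.0, 8)
        cc = compare_curves(grid8, va, grid8, vb)
        assert cc.df_num == 2
        assert cc.df_den == 12
        assert cc.p_value < 0.05

    def test_df_structure_matches_freed_parameter_count(self):
        # two 9-point data sets -> F with df (2, 14)
        grid9 = np.linspace(1, 800, 9)
        rng = np.random.default_rng(54)
        va = michaelis_menten(grid9, 20.0, 30.0) + rng.normal(0, 0.5, 9)
        vb = michaelis_menten(grid9, 22.0, 35.0) + rng.normal(0, 0.5, 9)
        cc = compare_curves(grid9, va, grid9, vb)
        assert (cc.df_num, cc.df_den) == (2, 14)


class TestDeltaTable:
    TRANSPORTERS = ("OfABCB1", "OfABCB2")

    def test_printed_score_and_km_deltas(self):
        scores = {
            "ouabain": {"OfABCB1": -7.8, "OfABCB2": -8.6},
            "digoxin": {"OfABCB1": -9.7, "OfABCB2": -10.4},
        }
        kms = {"digoxin": {"OfABCB1": 33.73, "OfABCB2": 9.33}}
        df = delta_table(scores, kms, self.TRANSPORTERS).set_index("substrate")
        assert df.loc["ouabain", "delta_score"] == pytest.approx(-0.8)
        assert df.loc["digoxin", "delta_score"] == pytest.approx(-0.7)
        assert df.loc["digoxin", "delta_km"] == pytest.approx(-24.40)
        assert np.isnan(df.loc["ouabain", "delta_km"])

    def test_equal_inputs_give_zero_delta(self):
        scores = {"x": {"OfABCB1": -8.0, "OfABCB2": -8.0}}
        kms = {"x": {"OfABCB1": 10.0, "OfABCB2": 10.0}}
        df = delta_table(scores, kms, self.TRANSPORTERS)
        assert df["delta_score"].iloc[0] == 0.0
        assert df["delta_km"].iloc[0] == 0.0

    def test_antisymmetric_under_transporter_swap(self):
        scores = {"x": {"OfABCB1": -8.0, "OfABCB2": -9.1}}
        kms = {"x": {"OfABCB1": 12.0, "OfABCB2": 30.0}}
        fwd = delta_table(scores, kms, self.TRANSPORTERS)
        rev = delta_table(scores, kms, self.TRANSPORTERS[::-1])
        assert fwd["delta_score"].iloc[0] == -rev["delta_score"].iloc[0]
        assert fwd["delta_km"].iloc[0] == -rev["delta_km"].iloc[0]

    def test_kinetic_fit_objects_accepted(self):
        fit = KineticFit(vmax=20.0, vmax_se=1.0, km=9.33, km_se=0.5,
                         rss=1.0, n_points=10)
        scores = {"digoxin": {"OfABCB1": -9.7, "OfABCB2": -10.4}}
        kms = {"digoxin": {"OfABCB1": 33.73, "OfABCB2": fit}}
        df = delta_table(scores, kms, self.TRANSPORTERS)
        assert df["delta_km"].iloc[0] == pytest.approx(-24.40)

    def test_missing_transporter_rejected(self):
        with pytest.raises(ValueError, match="both"):
            delta_table({"x": {"OfABCB1": -8.0}}, {}, self.TRANSPORTERS)


def test_dose_response_csv_round_trip(tmp_path):
    responses = [
        generate_mm_data(20.0, 10.0, seed=3, substrate_id="digoxin"),
        generate_mm_data(12.0, 40.0, seed=4, substrate_id="ouabain"),
    ]
    path = write_dose_response(tmp_path / "dr.csv", responses)
    back = read_dose_response(path)
    assert [d.substrate_id for d in back] == ["digoxin", "ouabain"]
    for orig, re in zip(responses, back):
        np.testing.assert_allclose(
            re.data["activity_no_vanadate"],
            orig.data["activity_no_vanadate"],
        )
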