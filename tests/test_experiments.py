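import numpy as np
import pytest
from scipy import stats as sps

import vascrad as vr
from vascrad.experiments import (EquilibriumRecord, critical_density_search,
                                 histogram_moments,
                                 organisation_correlation_analysis,
                                 random_family, regular_density_sweep,
                                 run_to_equilibrium,
                                 tumour_growth_experiment)
from vascrad.runio import substream
from vascrad.vessels import VesselPattern


@pytest.fixture(scope="module")
def small_params():
    return vr.default_parameters()


@pytest.fixture(scope="module")
def small_config(small_params):
    return vr.AutomatonConfig.from_params(small_params)


class TestHistogramMoments:
    def test_match_scipy_on_expanded_sample(self, rng):
        hist = np.zeros(100)
        hist[[10, 30, 70]] = [50, 30, 20]
        mids = (np.arange(100) + 0.5) * 0.01
        sample = np.repeat(mids, hist.astype(int))
        mean, std, skew = histogram_moments(hist, 0.01)
        assert mean == pytest.approx(sample.mean())
        assert std == pytest.approx(sample.std())
        assert skew == pytest.approx(sps.skew(sample))

    def test_empty_histogram_gives_nan(self):
        mean, std, skew = histogram_moments(np.zeros(100), 0.01)
        assert np.isnan(mean) and np.isnan(std) and np.isnan(skew)


class TestRunToEquilibrium:
    def test_unvascularised_domain_equilibrates_empty(self, small_params,
                                                      small_config):
        pattern = VesselPattern(N=15, coords=np.empty((0, 2)))
        rec = run_to_equilibrium(pattern, "healthy", small_params,
                                 small_config, substream(0, "empty"))
        assert rec.equilibrated
        assert rec.cellularity == 0.0
        assert np.isnan(rec.mean_L)  # fewer than 2 vessels
        assert np.isnan(rec.surviving_fraction)

    def test_identical_seeds_give_identical_records(self, small_params,
                                                    small_config):
        pattern = VesselPattern(N=21, coords=np.array([[6, 6], [14, 14]]))
        recs = [run_to_equilibrium(pattern, "tumour", small_params,
                                   small_config, substream(3, "det"))
                for _ in range(2)]
        assert recs[0].cell_count == recs[1].cell_count
        assert recs[0].survivors == recs[1].survivors
        assert np.array_equal(recs[0].histogram, recs[1].histogram)

    def test_dense_vessels_hold_carrying_capacity(self, small_params,
                                                  small_config):
        pattern = vr.generate_regular(15, spacing=4)
        rec = run_to_equilibrium(pattern, "healthy", small_params,
                                 small_config, substream(4, "dense"))
        assert rec.at_capacity
        assert rec.occupancy == pytest.approx(1.0)
        assert rec.survivors < rec.cell_count

    def test_histogram_mass_matches_cell_count(self, small_params,
                                               small_config):
        pattern = VesselPattern(N=21, coords=np.array([[10, 10]]))
        rec = run_to_equilibrium(pattern, "healthy", small_params,
                                 small_config, substream(5, "mass"))
        assert rec.histogram.sum() == pytest.approx(rec.cell_count)


class TestCriticalDensity:
    def test_disabled_death_gives_capacity_everywhere(self, small_config):
        # a vanishing hypoxic threshold makes death impossible, so every
        # density sustains a full lattice
        params = vr.default_parameters(c_ap_dim=5.14e-25)
        res = critical_density_search(params, small_config, N=20,
                                      master_seed=0, reps=1, k_min=2,
                                      k_max=3)
        assert all(row["at_capacity"] for row in res["scan"])
        assert np.isnan(res["theta_below"])

    def test_bracket_is_ordered_when_transition_exists(self, small_params,
                                                       small_config):
        res = critical_density_search(small_params, small_config, N=31,
                                      master_seed=1, reps=1, k_min=1,
                                      k_max=3)
        if not np.isnan(res["theta_below"]):
            assert res["theta_below"] < res["theta_above"]


class TestSweepsAndGrowth:
    def test_sweep_reports_realised_density(self, small_params,
                                            small_config):
        recs = regular_density_sweep([0.02], small_params, small_config,
                                     N=31, master_seed=0, reps=1)
        assert len(recs) == 1
        assert recs[0].theta == recs[0].v / 31**2

    def test_sterile_tumour_never_grows(self, small_config):
        params = vr.default_parameters(p_T=0.0)
        out = tumour_growth_experiment(params, small_config,
                                       theta_list=(0.01,), N=21,
                                       master_seed=0, t_end_days=4.0)
        (res,) = out.values()
        assert res["tumour_cells"][-1] == 1

    def test_growth_curve_time_axis_in_days(self, small_params,
                                            small_config):
        out = tumour_growth_experiment(small_params, small_config,
                                       theta_list=(0.02,), N=21,
                                       master_seed=0, t_end_days=3.0)
        (res,) = out.values()
        # one automaton step is one 16 h cell cycle
        assert res["time_days"][1] == pytest.approx(16 / 24)
        assert res["time_days"][-1] >= 3.0
        assert res["pattern"].coords.tolist().count([10, 10]) == 1


class TestFamilies:
    def test_same_seed_gives_identical_summaries(self, small_params,
                                                 small_config):
        fams = [random_family(3, small_params, small_config, n_reps=3,
                              N=21, master_seed=77) for _ in range(2)]
        assert fams[0].summary == fams[1].summary

    def test_family_frame_and_theta(self, small_params, small_config):
        fam = random_family(4, small_params, small_config, n_reps=3, N=21,
                            master_seed=5)
        df = fam.frame()
        assert len(df) == 3
        assert {"cellularity", "survivors", "mean_L"} <= set(df.columns)
        assert fam.theta == pytest.approx(4 / 441)

    def test_invalid_vessel_count_rejected(self, small_params,
                                           small_config):
        with pytest.raises(ValueError):
            random_family(0, small_params, small_config, n_reps=2, N=10)


def _fake_record(v, N, mean_L_value, survivors, cellularity):
    return EquilibriumRecord(
        v=v, N=N, theta=v / N**2, seed=0, initial="tumour",
        equilibrated=True, steps_to_equilibrium=10,
        cellularity=cellularity, occupancy=cellularity, at_capacity=False,
        cell_count=cellularity * N**2, histogram=np.zeros(100),
        mean_L=mean_L_value, survivors=survivors)


class TestCorrelationAnalysis:
    def _family(self, v, slope, rng):
        from vascrad.experiments import SimulationFamily
        ml = rng.normal(9.5, 1.0, size=20)
        surv = 1000 + slope * 80 * (ml - 9.5) + rng.normal(0, 20, size=20)
        recs = [_fake_record(v, 73, m, s, 0.5) for m, s in zip(ml, surv)]
        return SimulationFamily(v=v, N=73, records=recs,
                                summary={"n_valid": 20, "valid": True})

    def test_sign_change_and_peak_detection(self, rng):
        low = self._family(5, -1.0, rng)
        mid = self._family(50, -0.2, rng)
        high = self._family(200, +1.0, rng)
        # make the middle family the survivor peak
        for r in mid.records:
            r.survivors += 5000
        res = organisation_correlation_analysis([low, mid, high])
        assert res["sign_change"]
        assert res["peak_theta"] == pytest.approx(50 / 73**2)
        table = res["table"]
        assert np.sign(table.iloc[0]["r_survivors"]) != np.sign(
            table.iloc[-1]["r_survivors"])

    def test_constant_survivors_flagged_undefined(self, rng):
        fam = self._family(10, 0.0, rng)
        for r in fam.records:
            r.survivors = 123.0
        res = organisation_correlation_analysis([fam])
        assert not res["table"].iloc[0]["valid_survivors"]

    def test_small_families_are_skipped(self, rng):
        fam = self._family(10, 1.0, rng)
        fam.records = fam.records[:5]
        res = organisation_correlation_analysis([fam])
        assert len(res["table"]) == 0
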