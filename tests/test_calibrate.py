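"""Calibration workflow on the reduced fixture network."""

import numpy as np
import pandas as pd
import pytest

import seedflux as sf
from seedflux.calibrate import (
    CalibrationError,
    CalibrationTarget,
    default_observable,
    fit,
    identifiability_profile,
    residual_report,
    rough_tune,
    targets_from_frame,
)

SIM_KW = {"t_end_hr": 240.0, "dt_out_daf": 0.05}


def _truth_targets(model, inputs, observables=("C", "P", "Q"),
                   times=(1.0, 2.5, 5.0, 7.5, 10.0)):
    """Noise-free targets generated from the model itself."""
    traj = sf.simulate(model, sf.constant_enzymes(model), **SIM_KW)
    targets = []
    for obs in observables:
        series = default_observable(traj, obs)
        vals = np.interp(times, traj.times_daf, series)
        targets.append(CalibrationTarget(obs, np.array(times), vals))
    return targets


class TestFit:
    def test_self_consistency_at_truth(self, fixture_model, fixture_inputs):
        targets = _truth_targets(fixture_model, fixture_inputs)
        result = fit(
            fixture_model, sf.constant_enzymes(fixture_model),
            ["k_R2", "k_R3"], targets, n_starts=1, sim_kwargs=SIM_KW,
        )
        assert result.objective < 1e-8
        truth = [fixture_model.parameters[n].value
                 for n in result.parameter_names]
        np.testing.assert_allclose(result.values, truth, rtol=1e-3)

    def test_noiseless_recovery_from_perturbed_start(self, fixture_model,
                                                     fixture_inputs):
        targets = _truth_targets(fixture_model, fixture_inputs)
        truth = {n: fixture_model.parameters[n].value
                 for n in ("k_R2", "k_R3")}
        start = fixture_model.copy()
        start.parameters["k_R2"].value = truth["k_R2"] * 1.5
        start.parameters["k_R3"].value = truth["k_R3"] * 0.5
        result = fit(
            start, sf.constant_enzymes(start), ["k_R2", "k_R3"], targets,
            n_starts=1, max_nfev=120, sim_kwargs=SIM_KW,
        )
        for name, value in zip(result.parameter_names, result.values):
            assert value == pytest.approx(truth[name], rel=0.01), name

    def test_fixed_bounds_parameter_excluded(self, fixture_model):
        model = fixture_model.copy()
        prm = model.parameters["k_R4"]
        prm.bounds = (prm.value, prm.value)
        targets = _truth_targets(model, None)
        with pytest.warns(UserWarning, match="k_R4"):
            result = fit(
                model, sf.constant_enzymes(model), ["k_R2", "k_R4"],
                targets, n_starts=1, sim_kwargs=SIM_KW,
            )
        assert result.parameter_names == ["k_R2"]
        assert result.objective < 1e-8

    def test_empty_targets_rejected(self, fixture_model):
        with pytest.raises(Exception):
            fit(fixture_model, sf.constant_enzymes(fixture_model),
                ["k_R2"], [], n_starts=1)

    def test_best_objective_never_increases_across_starts(self, fixture_model):
        targets = _truth_targets(fixture_model, None)
        model = fixture_model.copy()
        model.parameters["k_R2"].value *= 2.0
        result = fit(
            model, sf.constant_enzymes(model), ["k_R2"], targets,
            n_starts=4, seed=11, max_nfev=20, sim_kwargs=SIM_KW,
        )
        trace = np.array(result.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_target_order_invariance(self, fixture_model):
        targets = _truth_targets(fixture_model, None)
        model = fixture_model.copy()
        model.parameters["k_R2"].value *= 1.3
        kw = dict(n_starts=1, max_nfev=15, sim_kwargs=SIM_KW)
        r1 = fit(model, sf.constant_enzymes(model), ["k_R2"], targets, **kw)
        r2 = fit(model, sf.constant_enzymes(model), ["k_R2"],
                 list(reversed(targets)), **kw)
        assert r1.objective == pytest.approx(r2.objective, rel=1e-9)

    def test_targets_from_frame_round_trip(self):
        df = pd.DataFrame(
            {
                "observable": ["C", "C", "P"],
                "time_daf": [1.0, 2.0, 1.5],
                "value": [0.1, 0.2, 0.3],
                "weight": [1.0, 2.0, 1.0],
            }
        )
        targets = targets_from_frame(df)
        assert [t.observable for t in targets] == ["C", "P"]
        np.testing.assert_allclose(targets[0].weights, [1.0, 2.0])

    def test_invalid_target_rejected(self):
        with pytest.raises(Exception):
            CalibrationTarget("C", [25.0], [1.0])  # beyond 21 DAF
        with pytest.raises(Exception):
            CalibrationTarget("C", [1.0], [1.0], [0.0])  # zero weight


class TestRoughTune:
    def test_unbounded_envelopes_accept_any_stable_model(self, fixture_model):
        tuned, violations = rough_tune(
            fixture_model, sf.constant_enzymes(fixture_model),
            {"C": (0.0, np.inf), "P": (0.0, np.inf)},
            sim_kwargs=SIM_KW,
        )
        assert violations == []
        assert tuned is fixture_model

    def test_structurally_impossible_envelope_reported(self, fixture_model):
        model = fixture_model.copy()
        prm = model.parameters["k_R3"]
        prm.bounds = (0.0, prm.bounds[1])
        prm.value = 0.0  # product P can never be produced
        with pytest.raises(CalibrationError, match="P"):
            rough_tune(
                model, sf.constant_enzymes(model),
                {"P": (0.05, np.inf)},
                tunable=["k_R2"], n_iter=3, sim_kwargs=SIM_KW,
            )

    def test_feasible_interval_matches_bisection_oracle(self, fixture_model):
        # the peak of P over the run grows monotonically with k_R3; the
        # envelope P <= p_cap therefore admits exactly k_R3 <= k*, with k*
        # found independently by bisection
        model = fixture_model.copy()
        p_cap = 0.28

        def peak_p(k):
            m = model.copy()
            m.parameters["k_R3"].value = k
            traj = sf.simulate(m, sf.constant_enzymes(m), **SIM_KW)
            return traj.state("P").max()

        lo, hi = 0.05, 0.3
        assert peak_p(lo) < p_cap < peak_p(hi)
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if peak_p(mid) < p_cap:
                lo = mid
            else:
                hi = mid
        k_star = 0.5 * (lo + hi)

        envelopes = {"P": (0.0, p_cap)}
        inside = model.copy()
        inside.parameters["k_R3"].value = k_star * 0.95
        _, violations = rough_tune(
            inside, sf.constant_enzymes(inside), envelopes,
            sim_kwargs=SIM_KW,
        )
        assert violations == []
        outside = model.copy()
        outside.parameters["k_R3"].value = k_star * 1.05
        with pytest.raises(CalibrationError):
            rough_tune(
                outside, sf.constant_enzymes(outside), envelopes,
                sim_kwargs=SIM_KW,
            )


class TestIdentifiability:
    def test_structural_nonidentifiability_flagged(self, fixture_model):
        # with the clamped substrate fixed, k_UPT and Km_UPT_S enter the
        # uptake flux only through k*S/(Km+S): the Km profile is flat once
        # k is re-optimized
        targets = _truth_targets(fixture_model, None)
        model = fixture_model.copy()
        result = fit(
            model, sf.constant_enzymes(model), ["k_UPT", "Km_UPT_S"],
            targets, n_starts=1, max_nfev=10, sim_kwargs=SIM_KW,
        )
        km = model.parameters["Km_UPT_S"].value
        profile = identifiability_profile(
            model, sf.constant_enzymes(model), result, "Km_UPT_S",
            [0.5 * km, km, 2.0 * km], targets, max_nfev=40,
            sim_kwargs=SIM_KW,
        )
        assert result.identifiability["Km_UPT_S"] is False
        assert profile["objective"].max() < 1e-3

    def test_controlling_parameter_flagged_identifiable(self, fixture_model):
        targets = _truth_targets(fixture_model, None)
        model = fixture_model.copy()
        result = fit(
            model, sf.constant_enzymes(model), ["k_R3"], targets,
            n_starts=1, max_nfev=10, sim_kwargs=SIM_KW,
        )
        k = model.parameters["k_R3"].value
        identifiability_profile(
            model, sf.constant_enzymes(model), result, "k_R3",
            [0.5 * k, k, 2.0 * k], targets, sim_kwargs=SIM_KW,
        )
        assert result.identifiability["k_R3"] is True

    def test_single_point_grid_warns(self, fixture_model):
        targets = _truth_targets(fixture_model, None)
        result = fit(
            fixture_model, sf.constant_enzymes(fixture_model), ["k_R3"],
            targets, n_starts=1, max_nfev=5, sim_kwargs=SIM_KW,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            identifiability_profile(
                fixture_model, sf.constant_enzymes(fixture_model), result,
                "k_R3", [fixture_model.parameters["k_R3"].value], targets,
                sim_kwargs=SIM_KW,
            )


def test_residual_report_lists_all_observables(fixture_model):
    targets = _truth_targets(fixture_model, None)
    result = fit(
        fixture_model, sf.constant_enzymes(fixture_model), ["k_R3"],
        targets, n_starts=1, max_nfev=5, sim_kwargs=SIM_KW,
    )
    report = residual_report(result)
    assert set(report["observable"]) == {"C", "P", "Q"}
    assert (report["rmse_log10"] >= 0).all()
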