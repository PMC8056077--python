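"""Transcript normalization, ribosome proxy and enzyme-level dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seedflux as sf
from seedflux.expression import (
    ConfigurationError,
    InputError,
    MappingError,
    TURNOVER_KDEG,
    kdeg_from_half_life,
)


class TestStageGrid:
    def test_default_grid_has_seven_increasing_times(self):
        grid = sf.DEFAULT_STAGE_GRID
        assert len(grid.stage_names) == 7
        assert grid.stage_times[0] == 0.0
        assert grid.stage_times[-1] <= 21.0
        assert np.all(np.diff(grid.times_daf) > 0)

    @pytest.mark.parametrize(
        "times",
        [
            (0, 1, 2, 3, 4, 5),  # six stages
            (1, 2, 3, 4, 5, 6, 7),  # first not zero
            (0, 2, 1, 4, 6, 10, 18),  # not increasing
            (0, 1, 2, 4, 6, 10, 22),  # beyond horizon
        ],
    )
    def test_invalid_grids_rejected(self, times):
        names = tuple(f"s{i}" for i in range(len(times)))
        with pytest.raises(ConfigurationError):
            sf.StageGrid(names, tuple(float(t) for t in times))


class TestNormalizeMrna:
    def test_single_gene_scaled_by_first_stage(self, toy_atlas):
        prof = sf.normalize_mrna(toy_atlas, {"g1": "E1"})
        np.testing.assert_allclose(
            prof.loc["E1"].to_numpy()[:3], [1.0, 2.0, 0.5]
        )

    def test_multi_gene_sum_then_scale(self, toy_atlas):
        prof = sf.normalize_mrna(toy_atlas, {"g2": "E", "g3": "E"})
        # sums (2000, 4000) at the first two stages
        np.testing.assert_allclose(prof.loc["E"].to_numpy()[:2], [1.0, 2.0])

    def test_first_stage_always_one(self, toy_atlas):
        prof = sf.normalize_mrna(
            toy_atlas, {"g1": "A", "g2": "B", "g3": "B"}
        )
        np.testing.assert_allclose(prof.iloc[:, 0], 1.0)

    def test_zero_guard_warns_and_defines_profile(self):
        stages = list(sf.DEFAULT_STAGE_GRID.stage_names)
        atlas = pd.DataFrame(
            [[0.0, 10.0, 20.0, 0.0, 0.0, 0.0, 0.0]],
            index=["g"], columns=stages,
        )
        with pytest.warns(UserWarning, match="zero first-stage"):
            prof = sf.normalize_mrna(atlas, {"g": "E"})
        np.testing.assert_allclose(
            prof.loc["E"].to_numpy()[:3], [1.0, 11.0, 21.0]
        )

    def test_negative_intensity_rejected(self, toy_atlas):
        bad = toy_atlas.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(InputError):
            sf.normalize_mrna(bad, {"g1": "E1"})

    def test_unmapped_gene_rejected(self, toy_atlas):
        with pytest.raises(MappingError):
            sf.normalize_mrna(toy_atlas, {"nope": "E1"})


class TestRibosomeSignal:
    def test_constant_genes_give_unit_signal(self, toy_atlas):
        sig = sf.ribosome_signal(toy_atlas, ["r1"], [1.0])
        np.testing.assert_allclose(sig.profile, 1.0)

    def test_linearity_on_doubled_stage(self, toy_atlas):
        atlas = toy_atlas.copy()
        atlas.loc["r1", atlas.columns[3]] *= 2
        sig = sf.ribosome_signal(atlas, ["r1"], [1.0])
        assert sig.profile[3] == pytest.approx(2.0)

    def test_weighted_sum_matches_hand_computation(self):
        # three genes, three informative stages; hand-computed oracle
        stages = list(sf.DEFAULT_STAGE_GRID.stage_names)
        rows = {
            "ra": [100.0, 200.0, 300.0, 100, 100, 100, 100],
            "rb": [50.0, 25.0, 75.0, 50, 50, 50, 50],
            "rc": [10.0, 20.0, 5.0, 10, 10, 10, 10],
        }
        atlas = pd.DataFrame.from_dict(rows, orient="index").set_axis(
            stages, axis=1
        )
        weights = [2.0, 4.0, 0.0]  # low-expressed gene weighted out
        sig = sf.ribosome_signal(atlas, ["ra", "rb", "rc"], weights)
        manual = (
            2.0 * np.array(rows["ra"]) + 4.0 * np.array(rows["rb"])
        )
        np.testing.assert_allclose(sig.profile, manual / manual[0])

    def test_empty_gene_list_rejected(self, toy_atlas):
        with pytest.raises(InputError):
            sf.ribosome_signal(toy_atlas, [])

    def test_default_threshold_weighting(self, toy_atlas):
        sig = sf.ribosome_signal(toy_atlas, ["r1", "g3"])
        # g3 mean 1000 < 2000 threshold -> weight 0
        assert sig.gene_weights["g3"] == 0.0
        assert sig.gene_weights["r1"] == 1.0


class TestTurnoverClasses:
    @pytest.mark.parametrize(
        "label,k_deg,k_syn",
        [("fast", 0.03, 0.055), ("average", 0.02, 0.045), ("slow", 0.01, 0.035)],
    )
    def test_synthesis_balances_degradation_and_growth(self, label, k_deg, k_syn):
        cls = sf.derive_rate_constants(label, mu0=0.025)
        assert cls.k_deg == pytest.approx(k_deg)
        assert cls.k_syn == pytest.approx(k_syn)
        assert cls.k_syn == pytest.approx(cls.k_deg + 0.025)

    def test_half_life_conversion(self):
        # a 23.1-hour half-life corresponds to the fast degradation class
        assert kdeg_from_half_life(23.1) == pytest.approx(
            TURNOVER_KDEG["fast"], rel=1e-3
        )

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            sf.derive_rate_constants("hyperfast")


class TestInterpolation:
    def test_exact_at_stage_times(self):
        prof = [1.0, 2.0, 1.5, 3.0, 0.5, 1.0, 2.0]
        fn = sf.interpolate_stage_profile(prof)
        np.testing.assert_allclose(
            fn(sf.DEFAULT_STAGE_GRID.times_hr), prof, atol=1e-12
        )

    def test_constant_profile_everywhere(self):
        fn = sf.interpolate_stage_profile([2.0] * 7)
        ts = np.linspace(0, 21 * 24, 100)
        np.testing.assert_allclose(fn(ts), 2.0)

    def test_monotone_segment_stays_bounded(self):
        # increasing knots -> pchip never overshoots the knot range
        prof = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        fn = sf.interpolate_stage_profile(prof)
        ts = np.linspace(0, sf.DEFAULT_STAGE_GRID.times_hr[-1], 300)
        vals = fn(ts)
        assert np.all(vals >= 1.0 - 1e-12) and np.all(vals <= 7.0 + 1e-12)

    def test_constant_extrapolation_beyond_last_stage(self):
        prof = [1, 2, 3, 4, 5, 6, 7.0]
        fn = sf.interpolate_stage_profile(prof)
        assert fn(21 * 24.0) == pytest.approx(7.0)

    def test_negative_query_rejected(self):
        fn = sf.interpolate_stage_profile([1.0] * 7)
        with pytest.raises(InputError):
            fn(-1.0)


class TestEnzymeOde:
    def test_unit_steady_state_for_balanced_constants(self):
        # k_syn = k_deg + mu forces E* = 1 under unit inputs
        t, e = sf.simulate_enzyme(
            1.0, lambda t: 1.0, lambda t: 1.0, 0.055, 0.03,
            lambda t: 0.025, (0.0, 400.0), np.array([0.0, 400.0]),
        )
        assert e[-1] == pytest.approx(1.0, rel=1e-6)

    def test_doubled_mrna_doubles_steady_state(self):
        t, e = sf.simulate_enzyme(
            2.0, lambda t: 2.0, lambda t: 1.0, 0.055, 0.03,
            lambda t: 0.025, (0.0, 400.0), np.array([0.0, 400.0]),
        )
        assert e[-1] == pytest.approx(2.0, rel=1e-6)

    def test_pure_decay_without_mrna(self):
        ts = np.linspace(0, 100, 11)
        t, e = sf.simulate_enzyme(
            1.0, lambda t: 0.0, lambda t: 1.0, 0.045, 0.02,
            lambda t: 0.005, (0.0, 100.0), ts,
        )
        np.testing.assert_allclose(e, np.exp(-0.025 * ts), rtol=1e-6)

    @given(
        mrna=st.floats(0.2, 5.0),
        label=st.sampled_from(["fast", "average", "slow"]),
    )
    @settings(max_examples=10, deadline=None)
    def test_steady_state_matches_closed_form(self, mrna, label):
        cls = sf.derive_rate_constants(label)
        total = cls.k_deg + 0.025
        t_end = 10.0 / total
        t, e = sf.simulate_enzyme(
            0.0, lambda t: mrna, lambda t: 1.0, cls.k_syn, cls.k_deg,
            lambda t: 0.025, (0.0, t_end), np.array([0.0, t_end]),
        )
        expected = cls.k_syn * mrna / total
        assert e[-1] == pytest.approx(expected, rel=1e-3)

    def test_linearity_in_mrna_scaling(self):
        ts = np.linspace(0, 300, 31)
        mrna = sf.interpolate_stage_profile([1, 2, 3, 2, 1, 0.5, 0.3])
        _, e1 = sf.simulate_enzyme(
            1.0, mrna, lambda t: 1.0, 0.045, 0.02, lambda t: 0.02,
            (0.0, 300.0), ts,
        )
        _, e3 = sf.simulate_enzyme(
            3.0, lambda t: 3.0 * mrna(t), lambda t: 1.0, 0.045, 0.02,
            lambda t: 0.02, (0.0, 300.0), ts,
        )
        np.testing.assert_allclose(e3, 3.0 * e1, rtol=1e-6)

    def test_fast_class_equilibrates_before_slow(self):
        # time to 95% of steady state orders as fast < average < slow
        times = {}
        for label in ("fast", "average", "slow"):
            cls = sf.derive_rate_constants(label)
            ts = np.linspace(0, 600, 1201)
            _, e = sf.simulate_enzyme(
                0.0, lambda t: 1.0, lambda t: 1.0, cls.k_syn, cls.k_deg,
                lambda t: 0.025, (0.0, 600.0), ts,
            )
            target = 0.95 * cls.k_syn / (cls.k_deg + 0.025)
            times[label] = ts[np.argmax(e >= target)]
        assert times["fast"] < times["average"] < times["slow"]


def test_enzyme_trajectories_levels_nonnegative_and_aligned(default_model,
                                                           reference_inputs):
    enz = sf.enzyme_trajectories(
        reference_inputs.normalized_profiles,
        reference_inputs.rb_profile,
        default_model.enzyme_turnover,
        default_model.growth.mu,
    )
    assert enz.levels.shape == (len(enz.enzyme_ids), len(enz.times_hr))
    assert np.all(enz.levels >= 0)
    # every enzyme starts from its stage-1 steady state (unit inputs -> ~1)
    start = enz(0.0)
    np.testing.assert_allclose(start, 1.0, rtol=0.15)
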