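import math

import numpy as np
import pytest

from alcs import SelectionParameters, build_schedule, required_time, trajectory, initial_state
from alcs import stage_simulator as ss
from alcs.exceptions import InvalidParameterError
from alcs.synthetic_data import ScenarioSpec, homogenization_config


def noiseless_config(params, schedule, **kw):
    return ss.SimulationConfig(params=params, schedule=schedule, rng_seed=0, **kw)


class TestDeterministicKinetics:
    def test_matches_closed_forms_at_stage_boundaries(self, ecoli_params, ecoli_schedule):
        """No capacity, no noise: the simulator IS the closed-form model + dilutions."""
        results = ss.run(noiseless_config(ecoli_params, ecoli_schedule))
        state = initial_state(ecoli_params)
        for res, stage in zip(results, ecoli_schedule.stages):
            expected = trajectory(ecoli_params, state, stage.duration)
            got = res.states[0][-1]
            assert got.viable_transformed == pytest.approx(
                expected.viable_transformed, rel=1e-10
            )
            assert got.viable_nontransformed == pytest.approx(
                expected.viable_nontransformed, rel=1e-10
            )
            # dilute for the next stage
            state = type(expected)(
                time=expected.time,
                viable_transformed=expected.viable_transformed * ecoli_schedule.dilution,
                viable_nontransformed=expected.viable_nontransformed * ecoli_schedule.dilution,
                dead=expected.dead * ecoli_schedule.dilution,
            )

    def test_final_selectivity_of_default_run(self, ecoli_params, ecoli_schedule):
        results = ss.run(noiseless_config(ecoli_params, ecoli_schedule))
        final = results[-1].composition
        assert final.pct_viable_transformed_of_viable >= 98.0
        assert 100 - final.pct_viable_transformed_of_viable <= 2.0

    def test_transfer_preserves_composition(self, ecoli_heatshock_params, ecoli_schedule):
        """Uniform dilution: percentages just before and after a transfer agree."""
        results = ss.run(noiseless_config(ecoli_heatshock_params, ecoli_schedule))
        for before, after in zip(results, results[1:]):
            comp_before = before.compositions[0]
            first_state = after.states[0][0]
            total = first_state.total
            assert 100 * first_state.viable_transformed / total == pytest.approx(
                comp_before.pct_viable_transformed, rel=1e-10
            )
            assert 100 * first_state.dead / total == pytest.approx(
                comp_before.pct_dead, rel=1e-10
            )

    def test_composition_sums_to_100(self, ecoli_heatshock_params, ecoli_schedule):
        results = ss.run(noiseless_config(ecoli_heatshock_params, ecoli_schedule))
        for res in results:
            assert sum(res.composition.as_tuple()) == pytest.approx(100.0)

    def test_no_death_growth_only(self, ecoli_schedule):
        """mu2 = 0: total viable follows f*c0*exp(mu1 t) + (1-f)*c0 between transfers."""
        p = SelectionParameters(mu1=0.25, k=0.0, f=1e-4, initial_total=1e4)
        results = ss.run(noiseless_config(p, ecoli_schedule))
        first = results[0]
        t = first.times - first.times[0]
        expected = 1.0 * np.exp(0.25 * t) + 9999.0
        viable = np.array([s.viable_total for s in first.states[0]])
        np.testing.assert_allclose(viable, expected, rtol=1e-10)


class TestCapacityAndReproducibility:
    def test_seeded_runs_are_bit_identical(self, ecoli_heatshock_params, ecoli_schedule):
        spec = ScenarioSpec(rng_seed=7, organism="ecoli")
        cfg = homogenization_config(spec, schedule=ecoli_schedule)
        a, b = ss.run(cfg), ss.run(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.backscatter, rb.backscatter)
            np.testing.assert_array_equal(ra.gfp, rb.gfp)
            assert ra.compositions == rb.compositions

    def test_carrying_capacity_never_exceeded(self, ecoli_schedule):
        p = SelectionParameters(mu1=0.25, mu2=-0.7, f=0.1, initial_total=1e4)
        cfg = noiseless_config(
            p, ecoli_schedule, carrying_capacity=2e4, mu1_liquid=1.5
        )
        results = ss.run(cfg)
        for res in results:
            for rep in res.states:
                for st in rep:
                    assert st.viable_total <= 2e4 * (1 + 1e-9)

    def test_capacity_slows_growth_below_exponential(self, ecoli_params, ecoli_schedule):
        capped = ss.run(
            noiseless_config(ecoli_params, ecoli_schedule, carrying_capacity=1e4)
        )
        free = ss.run(noiseless_config(ecoli_params, ecoli_schedule))
        assert (
            capped[-1].states[0][-1].viable_transformed
            < free[-1].states[0][-1].viable_transformed
        )

    def test_seed_mandatory_for_stochastic_configs(self, ecoli_params, ecoli_schedule):
        with pytest.raises(InvalidParameterError, match="seed"):
            ss.SimulationConfig(
                params=ecoli_params, schedule=ecoli_schedule, noise_sd=0.1
            )


class TestApparentGrowthRates:
    def test_noiseless_late_stage_mean_approaches_mu1(self, ecoli_params):
        """With the non-transformed pool gone, the viable log-slope is mu1."""
        from alcs.selection_model import SelectionRequirement

        gen = ecoli_params.generation_time
        req = SelectionRequirement(8 * gen, 8.0, 8)  # run past the 5-gen design
        sched = build_schedule(req, gen)
        results = ss.run(noiseless_config(ecoli_params, sched))
        stats = ss.apparent_growth_rates(results[-1], source="viable")
        assert stats["mean"] == pytest.approx(0.25, rel=1e-3)
        assert stats["sd_percent"] is None  # single replicate: SD missing

    def test_single_replicate_sd_missing(self, ecoli_params, ecoli_schedule):
        results = ss.run(noiseless_config(ecoli_params, ecoli_schedule))
        assert ss.apparent_growth_rates(results[0])["sd_percent"] is None

    def test_flat_trace_rates_excluded_from_sd(self, ecoli_heatshock_params, ecoli_schedule):
        """First-stage biomass is flat (dead-conserving kinetics): rates fall
        below the 0.01/h threshold and carry no SD information."""
        spec = ScenarioSpec(rng_seed=5, organism="ecoli")
        cfg = homogenization_config(spec, schedule=ecoli_schedule)
        results = ss.run(cfg)
        first = ss.apparent_growth_rates(results[0])
        last = ss.apparent_growth_rates(results[-1])
        assert first["n_included"] < cfg.n_replicates  # some flat traces dropped
        assert last["n_included"] == cfg.n_replicates
        assert abs(first["mean"]) < 0.1
        assert last["mean"] > 0.5

    def test_homogenization_cv_decreases_over_stages(self):
        """Across-replicate CV of apparent rates shrinks from first to last
        stage as the transformed pool takes over (pooled over 20 seeds)."""
        rates = {0: [], 3: []}
        for seed in range(20):
            spec = ScenarioSpec(rng_seed=seed, organism="ecoli")
            results = ss.run(homogenization_config(spec))
            for idx in rates:
                rates[idx].extend(ss.stage_log_slopes(results[idx]).tolist())

        def pooled_cv(values):
            arr = np.array(values)
            inc = arr[arr > ss.SD_RATE_THRESHOLD]
            return 100 * inc.std(ddof=1) / inc.mean()

        assert pooled_cv(rates[0]) >= pooled_cv(rates[3])


class TestBackscatterProxy:
    def test_zero_cells_sit_at_detection_floor(self):
        states = [ss.PopulationState(time=0.0, viable_transformed=0, viable_nontransformed=0)]
        sig = ss.backscatter_proxy(states, gain=2.0, detection_limit=5.0)
        assert sig[0] == 5.0

    def test_linearity_above_floor(self, ecoli_params):
        s1 = ss.PopulationState(time=0.0, viable_transformed=100, viable_nontransformed=0)
        s2 = ss.PopulationState(time=0.0, viable_transformed=200, viable_nontransformed=0)
        sig = ss.backscatter_proxy([s1, s2], gain=1.0, detection_limit=1.0)
        assert sig[1] == pytest.approx(2 * sig[0])

    def test_gain_must_be_positive(self):
        with pytest.raises(InvalidParameterError):
            ss.backscatter_proxy([], gain=0.0, detection_limit=1.0)


def test_results_frame_is_tidy(ecoli_params, ecoli_schedule):
    results = ss.run(noiseless_config(ecoli_params, ecoli_schedule, n_replicates=2))
    df = ss.results_to_frame(results)
    assert set(df.columns) >= {
        "stage", "replicate", "time_h", "viable_transformed", "backscatter", "gfp"
    }
    assert len(df) == 4 * 2 * 12
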