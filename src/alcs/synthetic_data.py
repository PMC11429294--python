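"""Seeded generators for every input the selection pipeline consumes.

The generators emulate the study conditions the analysis assumes:

* organism presets freeze the plate-derived growth rates (0.25, 0.15 and
  0.19 1/h for *E. coli*, *P. putida* and *C. glutamicum*), the k = -2.8
  death-rate rule, f = 1e-4 and s = 0.02;
* the *E. coli* heat-shock preset starts with 43 % of all cells already
  dead and ~0.01 % of viable cells transformed;
* colony-area series grow exponentially with multiplicative lognormal
  area noise (default 2 % relative);
* stage-wise gated fractions come from the stage simulator's ground truth
  with configurable additive percentage noise (default 2 percentage
  points);
* dilution-series scenarios span the 7-120 initial-transformed-cell
  validity window, with a carrying capacity and a realized liquid growth
  rate above the plate-derived design rate so that high inocula saturate
  (oxygen limitation) while low inocula stay exponential.

All randomness flows through one seeded generator per scenario; a fixed
seed reproduces every output bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .fitter import FractionObservations
from .plate_growth import ColonyAreaSeries
from .planner import StageSchedule, build_schedule
from .selection_model import (
    SelectionParameters,
    initial_state,
    required_time,
)
from .stage_simulator import SimulationConfig, run


@dataclass(frozen=True)
class OrganismPreset:
    """Frozen per-organism study conditions."""

    name: str
    mu1: float                  # 1/h, plate-derived
    k: float                    # mu2/mu1
    f: float                    # transformed fraction at start
    s: float                    # selection criterion
    cell_footprint_mm2: float
    initial_dead_fraction: float
    resting_multiplier: float


PRESETS: dict[str, OrganismPreset] = {
    "ecoli": OrganismPreset("ecoli", 0.25, -2.8, 1e-4, 0.02, 2.2e-6, 0.43, 1.0),
    "pputida": OrganismPreset("pputida", 0.15, -2.8, 1e-4, 0.02, 2.0e-6, 0.0, 1.0),
    "cglutamicum": OrganismPreset("cglutamicum", 0.19, -2.8, 1e-4, 0.02, 2.0e-6, 0.0, 2.0),
}

#: Default starting viable cell count: 1e4 cells puts one transformed cell
#: in the first well at f = 1e-4.
DEFAULT_INITIAL_TOTAL = 1e4

#: Defaults of the dilution-series scenario: realized liquid growth rate
#: (plates underestimate liquid growth), carrying capacity per well
#: (oxygen limitation at high density), observation noise and floor.
DILUTION_MU1_LIQUID = 1.0
DILUTION_CAPACITY = 5e6
DILUTION_NOISE_SD = 0.05
DILUTION_DETECTION_LIMIT = 1e3

#: Defaults of the growth-homogenization scenario: a realized liquid
#: growth rate well above the plate-derived design rate (rich medium at
#: 37 C), ~12 % replicate-to-replicate heterogeneity, 15 % relative
#: backscatter noise and a detection floor below the inoculum biomass.
#: Early stages are then flat (dead-dominated biomass, rates are noise
#: around zero) while the final stage shows clean exponential growth, so
#: the across-replicate scatter of apparent rates collapses over the run.
HOMOGENIZATION_MU1_LIQUID = 1.2
HOMOGENIZATION_HETEROGENEITY_SD = 0.12
HOMOGENIZATION_NOISE_SD = 0.15
HOMOGENIZATION_DETECTION_LIMIT = 1e3


@dataclass(frozen=True)
class ScenarioSpec:
    """One reproducible synthetic scenario."""

    rng_seed: int
    organism: str = "ecoli"
    params: SelectionParameters = None  # derived from the preset when omitted
    initial_transformed_cfu: int | None = None
    area_noise_sd: float = 0.02          # relative lognormal on colony areas
    fraction_noise_pct_sd: float = 2.0   # additive percentage points on fractions
    cell_footprint_mm2: float = None     # from preset when omitted

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise InvalidParameterError("rng_seed is mandatory")
        if self.organism != "custom" and self.organism not in PRESETS:
            raise InvalidParameterError(
                f"unknown organism {self.organism!r}; valid: {sorted(PRESETS)} or 'custom'"
            )
        if self.params is None:
            if self.organism == "custom":
                raise InvalidParameterError("custom scenarios must supply params")
            pre = PRESETS[self.organism]
            object.__setattr__(
                self,
                "params",
                SelectionParameters(
                    mu1=pre.mu1,
                    k=pre.k,
                    f=pre.f,
                    s=pre.s,
                    initial_total=DEFAULT_INITIAL_TOTAL,
                    initial_dead_fraction=pre.initial_dead_fraction,
                ),
            )
        if self.cell_footprint_mm2 is None:
            fp = PRESETS[self.organism].cell_footprint_mm2 if self.organism in PRESETS else 2e-6
            object.__setattr__(self, "cell_footprint_mm2", fp)
        if self.area_noise_sd < 0 or self.fraction_noise_pct_sd < 0:
            raise InvalidParameterError("noise SDs must be non-negative")

    def default_schedule(self) -> StageSchedule:
        """Schedule implied by the scenario's own parameters."""
        pre = PRESETS.get(self.organism)
        return build_schedule(
            required_time(self.params),
            self.params.generation_time,
            resting_multiplier=pre.resting_multiplier if pre else 1.0,
            organism_label=self.organism,
        )


def generate_colony_series(
    spec: ScenarioSpec,
    n_timepoints: int = 6,
    n_replicates: int = 3,
    *,
    t_max: float = 25.0,
    n0_cells: float = 1e3,
) -> list[ColonyAreaSeries]:
    """Colony-area time series: footprint * N0 * exp(mu1 t) * lognormal noise."""
    if n_timepoints < 2:
        raise InvalidParameterError("n_timepoints must be >= 2")
    rng = np.random.default_rng(spec.rng_seed)
    times = np.linspace(0.0, t_max, n_timepoints)
    clean = spec.cell_footprint_mm2 * n0_cells * np.exp(spec.params.mu1 * times)
    series = []
    for r in range(n_replicates):
        noise = (
            rng.lognormal(0.0, spec.area_noise_sd, size=n_timepoints)
            if spec.area_noise_sd > 0
            else 1.0
        )
        series.append(
            ColonyAreaSeries(
                organism_label=spec.organism,
                timepoints=times,
                cfu_area=clean * noise,
                cell_footprint=spec.cell_footprint_mm2,
                replicate_id=f"r{r + 1}",
            )
        )
    return series


def generate_stage_fractions(
    spec: ScenarioSpec,
    schedule: StageSchedule | None = None,
    *,
    noise_pct_sd: float | None = None,
) -> tuple[FractionObservations, pd.DataFrame]:
    """Gated population fractions at t = 0 and at each stage end.

    Ground truth comes from a noise-free simulator run; the returned
    ``FractionObservations`` carry additive Gaussian noise (in percentage
    points, clipped to [0, 100]) on the viable-only percentages, while the
    full four-way composition table is renormalized to sum to 100 % per
    sampling point.
    """
    if schedule is None:
        schedule = spec.default_schedule()
    sd = spec.fraction_noise_pct_sd if noise_pct_sd is None else noise_pct_sd
    rng = np.random.default_rng(spec.rng_seed)

    config = SimulationConfig(params=spec.params, schedule=schedule, rng_seed=spec.rng_seed)
    results = run(config)

    s0 = initial_state(spec.params)
    f = spec.params.f
    pools0 = np.array(
        [s0.viable_transformed, s0.viable_nontransformed, f * s0.dead, (1 - f) * s0.dead]
    )
    comps = [100.0 * pools0 / pools0.sum()]
    times = [0.0]
    for res in results:
        comps.append(np.array(res.composition.as_tuple()))
        times.append(float(res.times[-1]))

    rows = []
    for stage_idx, (t, c) in enumerate(zip(times, comps)):
        if sd > 0:
            noisy = np.clip(c + rng.normal(0.0, sd, size=4), 0.0, None)
            c = 100.0 * noisy / noisy.sum() if noisy.sum() > 0 else c
        rows.append(
            {
                "stage": stage_idx,
                "time_h": t,
                "pct_viable_transformed": c[0],
                "pct_viable_nontransformed": c[1],
                "pct_dead_transformed": c[2],
                "pct_dead_nontransformed": c[3],
            }
        )
    table = pd.DataFrame(rows)

    viable_t, viable_nt = [], []
    for t, c in zip(times, comps):
        viable = c[0] + c[1]
        pct_t = 100.0 * c[0] / viable if viable > 0 else 0.0
        if sd > 0:
            pct_t_obs = float(np.clip(pct_t + rng.normal(0.0, sd), 0.0, 100.0))
            pct_nt_obs = float(np.clip((100.0 - pct_t) + rng.normal(0.0, sd), 0.0, 100.0))
        else:
            pct_t_obs, pct_nt_obs = pct_t, 100.0 - pct_t
        viable_t.append(pct_t_obs)
        viable_nt.append(pct_nt_obs)

    obs = FractionObservations(
        times=np.array(times),
        pct_viable_transformed=np.array(viable_t),
        pct_viable_nontransformed=np.array(viable_nt),
    )
    return obs, table


def homogenization_config(
    spec: ScenarioSpec,
    *,
    n_replicates: int = 6,
    schedule: StageSchedule | None = None,
) -> SimulationConfig:
    """Simulation config of the growth-homogenization scenario.

    Replicate wells share the schedule but draw individual transformed
    growth rates; apparent per-stage rates computed from the noisy
    backscatter traces start as pure noise around zero and converge to the
    replicate's true rate once the transformed pool dominates.
    """
    if schedule is None:
        schedule = spec.default_schedule()
    return SimulationConfig(
        params=spec.params,
        schedule=schedule,
        mu1_liquid=HOMOGENIZATION_MU1_LIQUID,
        mu_heterogeneity_sd=HOMOGENIZATION_HETEROGENEITY_SD,
        n_replicates=n_replicates,
        noise_sd=HOMOGENIZATION_NOISE_SD,
        backscatter_detection_limit=HOMOGENIZATION_DETECTION_LIMIT,
        rng_seed=spec.rng_seed,
    )


def generate_dilution_series(
    spec: ScenarioSpec,
    initial_cfus: list[int],
    *,
    schedule: StageSchedule | None = None,
    carrying_capacity: float = DILUTION_CAPACITY,
    mu1_liquid: float = DILUTION_MU1_LIQUID,
    noise_sd: float = DILUTION_NOISE_SD,
    detection_limit: float = DILUTION_DETECTION_LIMIT,
) -> list[SimulationConfig]:
    """One simulation config per initial transformed cell count.

    Everything except the inoculum size is identical across configs, so the
    set isolates the effect of the starting cell number (the 7-120 cell
    robustness window).
    """
    if any(c < 0 for c in initial_cfus):
        raise InvalidParameterError("initial CFU counts must be non-negative")
    if schedule is None:
        schedule = spec.default_schedule()
    configs = []
    for count in initial_cfus:
        params = spec.params.with_initial_total(count / spec.params.f)
        configs.append(
            SimulationConfig(
                params=params,
                schedule=schedule,
                carrying_capacity=carrying_capacity,
                mu1_liquid=mu1_liquid,
                noise_sd=noise_sd,
                backscatter_detection_limit=detection_limit,
                rng_seed=spec.rng_seed,
            )
        )
    return configs
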