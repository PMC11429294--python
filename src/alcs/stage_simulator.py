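"""Stage-wise simulation of a liquid clone-selection run.

Within each stage the three pools (viable transformed, viable
non-transformed, dead) follow the selection model; at each stage boundary
every pool is multiplied by the dilution factor of the 1:2 transfer, which
leaves all composition percentages unchanged.  On top of the deterministic
kinetics the simulator reproduces the features the microbioreactor readout
actually shows:

* an optional carrying capacity (shared logistic brake on the viable
  pools) standing in for oxygen limitation at high cell densities,
* per-replicate growth-rate heterogeneity (one mu1 draw per well lineage,
  Gaussian truncated at zero),
* a backscatter proxy — biomass signal with a detection-limit floor and
  multiplicative lognormal noise — plus a GFP proxy for the transformed
  pool,
* an optional ``mu1_liquid``: the realized growth rate in liquid medium,
  which typically exceeds the plate-derived design rate (plates see only
  quasi-2D colony growth), making the designed schedule conservative.

Apparent per-stage growth rates are computed with the same log-slope
estimator used for plates, either on the observed backscatter trace (what
the instrument software reports; flat traces below the detection limit
yield noisy near-zero rates) or on the true viable count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import InvalidParameterError
from .plate_growth import log_slope
from .planner import StageSchedule
from .selection_model import PopulationState, SelectionParameters, initial_state

#: Replicate rates at or below this value [1/h] are excluded from the
#: across-replicate SD (flat, noise-dominated traces carry no rate signal).
SD_RATE_THRESHOLD = 0.01

_OVERFLOW_CAP = 1e30


@dataclass(frozen=True)
class StageComposition:
    """Four-way population split at one sampling point, in % of all cells."""

    pct_viable_transformed: float
    pct_viable_nontransformed: float
    pct_dead_transformed: float
    pct_dead_nontransformed: float

    @property
    def pct_dead(self) -> float:
        return self.pct_dead_transformed + self.pct_dead_nontransformed

    @property
    def pct_viable_transformed_of_viable(self) -> float:
        """Transformed share among viable cells only (the gating convention)."""
        viable = self.pct_viable_transformed + self.pct_viable_nontransformed
        return math.nan if viable == 0 else 100.0 * self.pct_viable_transformed / viable

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.pct_viable_transformed,
            self.pct_viable_nontransformed,
            self.pct_dead_transformed,
            self.pct_dead_nontransformed,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one reproducible simulation run needs."""

    params: SelectionParameters
    schedule: StageSchedule
    carrying_capacity: float | None = None
    mu1_liquid: float | None = None
    mu_heterogeneity_sd: float = 0.0
    n_replicates: int = 1
    backscatter_gain: float = 1.0
    gfp_gain: float = 1.0
    backscatter_detection_limit: float = 0.0
    noise_sd: float = 0.0
    composition_noise_sd: float = 0.0
    rng_seed: int | None = None
    samples_per_stage: int = 12
    sd_rate_threshold: float = SD_RATE_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.mu_heterogeneity_sd < 0 or self.noise_sd < 0 or self.composition_noise_sd < 0:
            raise InvalidParameterError("noise/heterogeneity SDs must be non-negative")
        if self.carrying_capacity is not None and self.carrying_capacity <= 0:
            raise InvalidParameterError("carrying_capacity must be positive")
        if not (self.backscatter_gain > 0) or not (self.gfp_gain > 0):
            raise InvalidParameterError("gains must be positive")
        if self.samples_per_stage < 2:
            raise InvalidParameterError("samples_per_stage must be >= 2")
        stochastic = (
            self.mu_heterogeneity_sd > 0 or self.noise_sd > 0 or self.composition_noise_sd > 0
        )
        if stochastic and self.rng_seed is None:
            raise InvalidParameterError("rng_seed is mandatory when noise or heterogeneity > 0")


@dataclass
class StageResult:
    """Per-stage time series, observation proxies and end-of-stage composition."""

    stage_index: int
    times: np.ndarray                       # absolute h, shape (T,)
    states: list[list[PopulationState]]     # [replicate][timepoint]
    backscatter: np.ndarray                 # observed signal, shape (R, T)
    gfp: np.ndarray                         # observed signal, shape (R, T)
    compositions: list[StageComposition]    # per replicate, at stage end
    composition: StageComposition = field(init=False)  # mean across replicates
    apparent_growth_rate: np.ndarray = field(init=False)  # backscatter-based, (R,)

    def __post_init__(self) -> None:
        mean = np.mean([c.as_tuple() for c in self.compositions], axis=0)
        self.composition = StageComposition(*mean)
        self.apparent_growth_rate = stage_log_slopes(self, source="backscatter")


def _evolve(
    c1: float,
    c2: float,
    dead_t: float,
    dead_nt: float,
    mu1: float,
    mu2: float,
    times_rel: np.ndarray,
    capacity: float | None,
) -> np.ndarray:
    """Pool trajectories over one stage; columns (c1, c2, dead_t, dead_nt)."""
    if capacity is None:
        c1s = c1 * np.exp(mu1 * times_rel)
        c2s = c2 * np.exp(mu2 * times_rel)
        deaths = np.maximum(0.0, c2 - c2s)
        return np.column_stack(
            [c1s, c2s, np.full_like(c1s, dead_t), dead_nt + deaths]
        )

    def rhs(_t, y):
        y1, y2, _dt, _dn = y
        brake = 1.0 - (y1 + y2) / capacity
        d1 = mu1 * y1 * brake
        d2 = mu2 * y2 * brake
        death_flux = -d2 if mu2 < 0 else 0.0
        return [d1, d2, 0.0, death_flux]

    sol = solve_ivp(
        rhs,
        (times_rel[0], times_rel[-1]),
        [c1, c2, dead_t, dead_nt],
        t_eval=times_rel,
        method="RK45",
        rtol=1e-10,
        atol=1e-12 * max(1.0, c1 + c2 + dead_t + dead_nt),
    )
    out = sol.y.T.copy()
    np.clip(out, 0.0, None, out=out)
    return out


def _noisy_composition(
    pools: np.ndarray, sd: float, rng: np.random.Generator | None
) -> StageComposition:
    """Percent composition of the four pools, with optional logistic-normal noise."""
    total = pools.sum()
    if total <= 0:
        return StageComposition(0.0, 0.0, 0.0, 0.0)
    p = pools / total
    if sd > 0 and rng is not None:
        nonzero = p > 0
        logp = np.where(nonzero, np.log(np.where(nonzero, p, 1.0)), -np.inf)
        logp = logp + rng.normal(0.0, sd, size=4)
        w = np.exp(logp - logp.max())
        p = w / w.sum()
    return StageComposition(*(100.0 * p))


def run(config: SimulationConfig) -> list[StageResult]:
    """Simulate every stage for every replicate; deterministic given the seed."""
    rng = np.random.default_rng(config.rng_seed)
    p = config.params
    sched = config.schedule
    base_mu1 = p.mu1 if config.mu1_liquid is None else config.mu1_liquid

    mu1s = np.full(config.n_replicates, base_mu1, dtype=float)
    if config.mu_heterogeneity_sd > 0:
        for i in range(config.n_replicates):
            for _ in range(1000):  # truncate the Gaussian at zero by resampling
                draw = rng.normal(base_mu1, config.mu_heterogeneity_sd)
                if draw > 0:
                    mu1s[i] = draw
                    break
            else:
                raise InvalidParameterError("could not draw a positive mu1")

    s0 = initial_state(p)
    # Initial dead pool split transformed/non-transformed in proportion f.
    pools = np.tile(
        [s0.viable_transformed, s0.viable_nontransformed, p.f * s0.dead, (1 - p.f) * s0.dead],
        (config.n_replicates, 1),
    )

    results: list[StageResult] = []
    overflow_warned = False
    for i, stage in enumerate(sched.stages):
        times_rel = np.linspace(0.0, stage.duration, config.samples_per_stage)
        times_abs = stage.start_time + times_rel
        traj = np.empty((config.n_replicates, config.samples_per_stage, 4))
        for r in range(config.n_replicates):
            traj[r] = _evolve(
                *pools[r], mu1s[r], p.mu2, times_rel, config.carrying_capacity
            )
        if np.any(traj > _OVERFLOW_CAP):
            if not overflow_warned:
                warnings.warn(
                    "pool counts capped at overflow limit; consider enabling a "
                    "carrying capacity",
                    stacklevel=2,
                )
                overflow_warned = True
            np.clip(traj, None, _OVERFLOW_CAP, out=traj)

        total = traj.sum(axis=2)
        back = np.maximum(
            config.backscatter_gain * total, config.backscatter_detection_limit
        )
        gfp = np.maximum(
            config.gfp_gain * traj[:, :, 0], config.backscatter_detection_limit
        )
        if config.noise_sd > 0:
            back = back * rng.lognormal(0.0, config.noise_sd, size=back.shape)
            gfp = gfp * rng.lognormal(0.0, config.noise_sd, size=gfp.shape)

        states = [
            [
                PopulationState(
                    time=times_abs[j],
                    viable_transformed=traj[r, j, 0],
                    viable_nontransformed=traj[r, j, 1],
                    dead=traj[r, j, 2] + traj[r, j, 3],
                )
                for j in range(config.samples_per_stage)
            ]
            for r in range(config.n_replicates)
        ]
        comps = [
            _noisy_composition(
                traj[r, -1],
                config.composition_noise_sd,
                rng if config.composition_noise_sd > 0 else None,
            )
            for r in range(config.n_replicates)
        ]
        results.append(
            StageResult(
                stage_index=i,
                times=times_abs,
                states=states,
                backscatter=back,
                gfp=gfp,
                compositions=comps,
            )
        )
        pools = traj[:, -1, :].copy()
        if i < len(sched.transfers):
            pools *= sched.dilution
    return results


def stage_log_slopes(result: StageResult, source: str = "backscatter") -> np.ndarray:
    """Per-replicate apparent growth rate [1/h] over one stage.

    ``source="backscatter"`` fits the observed signal trace (the rate the
    instrument software would report); ``source="viable"`` fits the true
    total viable count.
    """
    if source == "backscatter":
        series = result.backscatter
    elif source == "viable":
        series = np.array(
            [[st.viable_total for st in rep] for rep in result.states]
        )
    else:
        raise InvalidParameterError(f"unknown source {source!r}")
    return np.array([log_slope(result.times, row) for row in series])


def apparent_growth_rates(
    result: StageResult,
    *,
    source: str = "backscatter",
    threshold: float = SD_RATE_THRESHOLD,
) -> dict:
    """Mean rate and across-replicate scatter for one stage.

    ``mean`` averages all replicates.  The SD considers only replicates
    whose rate exceeds ``threshold`` (flat traces carry no rate
    information) and is reported as a percent of the included replicates'
    mean (a coefficient of variation); it is None when fewer than two
    replicates qualify.
    """
    rates = stage_log_slopes(result, source=source)
    finite = rates[np.isfinite(rates)]
    mean = float(finite.mean()) if finite.size else math.nan
    included = finite[finite > threshold]
    if included.size >= 2 and included.mean() != 0:
        sd_percent = float(100.0 * included.std(ddof=1) / included.mean())
    else:
        sd_percent = None
    return {"mean": mean, "sd_percent": sd_percent, "n_included": int(included.size)}


def backscatter_proxy(
    states: list[PopulationState], gain: float, detection_limit: float
) -> np.ndarray:
    """Noise-free biomass signal for a state series: max(gain * total, floor)."""
    if not (gain > 0):
        raise InvalidParameterError("gain must be positive")
    totals = np.array([s.total for s in states])
    return np.maximum(gain * totals, detection_limit)


def results_to_frame(results: list[StageResult]) -> pd.DataFrame:
    """Tidy long-format table of a run (one row per replicate x timepoint)."""
    rows = []
    for res in results:
        for r, rep in enumerate(res.states):
            for j, st in enumerate(rep):
                rows.append(
                    {
                        "stage": res.stage_index + 1,
                        "replicate": r + 1,
                        "time_h": st.time,
                        "viable_transformed": st.viable_transformed,
                        "viable_nontransformed": st.viable_nontransformed,
                        "dead": st.dead,
                        "backscatter": res.backscatter[r, j],
                        "gfp": res.gfp[r, j],
                    }
                )
    return pd.DataFrame(rows)
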