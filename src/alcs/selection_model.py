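"""Two-subpopulation growth/death model of antibiotic clone selection.

After transformation, a culture contains a small fraction ``f`` of
transformed cells (index 1) carrying the antibiotic-resistance plasmid and
a large fraction ``1 - f`` of non-transformed cells (index 2).  In
selective liquid medium the transformed pool grows exponentially at rate
``mu1 > 0`` while the non-transformed pool dies at a constant non-survival
rate ``mu2 < 0``::

    dc_x1/dt = mu1 * c_x1          c_x1(t) = c_x10 * exp(mu1 * t)
    dc_x2/dt = mu2 * c_x2          c_x2(t) = c_x20 * exp(mu2 * t)

Selection is complete when the non-transformed pool has shrunk to a target
proportion ``s`` of the transformed pool (s = 0.02 means 50:1).  The
required cultivation time follows in closed form,

    t_req = ln(s * f / (1 - f)) / (mu2 - mu1),

and dividing by the generation time ln2/mu1 converts it into a number of
generations, which is how the liquid-handling schedule is expressed.  In
generation units the requirement depends only on the dimensionless ratio
k = mu2/mu1 (k = -2.8 transfers the *E. coli* death assumption to other
hosts):

    n_gen = ln((1 - f) / (s * f)) / ((1 - k) * ln 2)

Dead cells are tracked explicitly as a third pool: each non-transformed
death is conserved into it, so flow-cytometry-style compositions
(viable/dead, GFP+/-) are computable at any time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, NoSelectionPossibleError

LN2 = math.log(2.0)


def death_rate_from_k(mu1: float, k: float) -> float:
    """Non-survival rate mu2 = k * mu1 [1/h] from the dimensionless ratio k.

    The ratio k = mu2/mu1 (-2.8 measured for *E. coli*) ports the death
    assumption to hosts where only mu1 was measured.
    """
    if not (mu1 > 0):
        raise InvalidParameterError(f"mu1 must be positive, got {mu1}")
    return k * mu1


@dataclass(frozen=True)
class SelectionParameters:
    """Rates and fractions defining one selection problem.

    Exactly one of ``mu2`` (absolute non-survival rate, 1/h) or ``k``
    (= mu2/mu1) is given; the other is derived.  ``initial_total`` is the
    viable cell count c_x0 at the start of selection; a pre-existing dead
    pool (e.g. 43 % of the population killed by heat shock) is expressed as
    ``initial_dead_fraction`` of the total including dead, so
    dead0 = d/(1-d) * c_x0.
    """

    mu1: float
    mu2: float | None = None
    k: float | None = None
    f: float = 1e-4
    s: float = 0.02
    initial_total: float = 1.0
    initial_dead_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (self.mu1 > 0):
            raise InvalidParameterError(f"mu1 must be positive, got {self.mu1}")
        if (self.mu2 is None) == (self.k is None):
            raise InvalidParameterError("exactly one of mu2 or k must be supplied")
        if self.mu2 is None:
            object.__setattr__(self, "mu2", death_rate_from_k(self.mu1, self.k))
        else:
            object.__setattr__(self, "k", self.mu2 / self.mu1)
        if not (0 < self.f < 1):
            raise InvalidParameterError(f"f must lie in (0, 1), got {self.f}")
        if not (0 < self.s < 1):
            raise InvalidParameterError(f"s must lie in (0, 1), got {self.s}")
        if self.initial_total < 0:
            raise InvalidParameterError("initial_total must be non-negative")
        if not (0 <= self.initial_dead_fraction < 1):
            raise InvalidParameterError("initial_dead_fraction must lie in [0, 1)")
        if self.mu1 <= self.mu2:
            raise NoSelectionPossibleError(
                f"selection requires mu1 > mu2, got mu1={self.mu1}, mu2={self.mu2}"
            )
        if self.mu2 > 0:
            warnings.warn(
                "mu2 > 0: non-transformed cells grow; selection is dilution-driven only",
                stacklevel=2,
            )

    def with_initial_total(self, initial_total: float) -> "SelectionParameters":
        """Copy with a different starting viable cell count."""
        return SelectionParameters(
            mu1=self.mu1,
            mu2=self.mu2,
            f=self.f,
            s=self.s,
            initial_total=initial_total,
            initial_dead_fraction=self.initial_dead_fraction,
        )

    @property
    def generation_time(self) -> float:
        """Doubling time of the transformed pool, ln2/mu1 [h]."""
        return LN2 / self.mu1


@dataclass(frozen=True)
class PopulationState:
    """Cell pools at one time point (counts, dimensionless)."""

    time: float
    viable_transformed: float
    viable_nontransformed: float
    dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("viable_transformed", "viable_nontransformed", "dead"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")

    @property
    def viable_total(self) -> float:
        return self.viable_transformed + self.viable_nontransformed

    @property
    def total(self) -> float:
        return self.viable_total + self.dead

    @property
    def viable_transformed_fraction(self) -> float:
        """Transformed share among viable cells, c_x1/(c_x1 + c_x2)."""
        v = self.viable_total
        return math.nan if v == 0 else self.viable_transformed / v

    @property
    def selection_ratio(self) -> float:
        """Transformed : non-transformed ratio c_x1/c_x2 (inf when c_x2 = 0)."""
        if self.viable_nontransformed == 0:
            return math.inf
        return self.viable_transformed / self.viable_nontransformed


@dataclass(frozen=True)
class SelectionRequirement:
    """Cultivation time and generation count needed to reach the criterion s."""

    t_required: float
    n_generations_required: float
    n_generations_scheduled: int
    already_selected: bool = False


def initial_state(params: SelectionParameters) -> PopulationState:
    """Population pools at t = 0: the Eq.-style split c_x10 = f*c_x0."""
    c0 = params.initial_total
    d = params.initial_dead_fraction
    dead0 = d / (1.0 - d) * c0
    return PopulationState(
        time=0.0,
        viable_transformed=params.f * c0,
        viable_nontransformed=(1.0 - params.f) * c0,
        dead=dead0,
    )


def trajectory(
    params: SelectionParameters, state0: PopulationState, t: float
) -> PopulationState:
    """Closed-form state after ``t`` hours of undisturbed batch selection.

    Non-transformed deaths are conserved into the dead pool:
    dead(t) = dead0 + (c_x20 - c_x2(t)).
    """
    if t < 0:
        raise InvalidParameterError(f"t must be non-negative, got {t}")
    c1 = state0.viable_transformed * math.exp(params.mu1 * t)
    c2 = state0.viable_nontransformed * math.exp(params.mu2 * t)
    dead = state0.dead + max(0.0, state0.viable_nontransformed - c2)
    return PopulationState(
        time=state0.time + t,
        viable_transformed=c1,
        viable_nontransformed=c2,
        dead=dead,
    )


def required_time(params: SelectionParameters) -> SelectionRequirement:
    """Cultivation time to reach c_x2/c_x1 = s, and its generation count.

    t_req = ln(s*f/(1-f)) / (mu2 - mu1).  The generation count rounds UP to
    whole stages so that the schedule meets or exceeds t_req.  When the
    starting composition already satisfies the criterion (s*f/(1-f) >= 1)
    the requirement is zero and flagged.
    """
    arg = params.s * params.f / (1.0 - params.f)
    if arg >= 1.0:
        warnings.warn(
            "starting composition already meets the selection criterion; t_required = 0",
            stacklevel=2,
        )
        return SelectionRequirement(0.0, 0.0, 0, already_selected=True)
    t_req = math.log(arg) / (params.mu2 - params.mu1)
    n_gen = t_req / (LN2 / params.mu1)
    return SelectionRequirement(
        t_required=t_req,
        n_generations_required=n_gen,
        n_generations_scheduled=math.ceil(round(n_gen, 9)),
    )


def required_generations_closed_form(k: float, f: float, s: float) -> float:
    """Generations needed, in closed form: ln((1-f)/(s*f)) / ((1-k) * ln2).

    Independent of mu1 - the schedule length in generation units is fixed by
    k, f and s alone.  Clamped to 0 (with a warning) when the start already
    satisfies the criterion.
    """
    if k >= 1:
        raise NoSelectionPossibleError(f"selection requires k < 1, got k={k}")
    if not (0 < f < 1) or not (0 < s < 1):
        raise InvalidParameterError("f and s must lie in (0, 1)")
    n = math.log((1.0 - f) / (s * f)) / ((1.0 - k) * LN2)
    if n < 0:
        warnings.warn("starting composition already meets the criterion", stacklevel=2)
        return 0.0
    return n


def requirement_report(params: SelectionParameters, req: SelectionRequirement) -> dict:
    """JSON-ready summary of a selection requirement."""
    return {
        "mu1_per_h": params.mu1,
        "mu2_per_h": params.mu2,
        "k": params.k,
        "f": params.f,
        "s": params.s,
        "generation_time_h": params.generation_time,
        "t_required_h": req.t_required,
        "n_generations_required": req.n_generations_required,
        "n_generations_scheduled": req.n_generations_scheduled,
        "already_selected": req.already_selected,
    }
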