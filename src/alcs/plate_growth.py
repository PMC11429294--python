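"""Growth-rate estimation from colony areas on agar plates.

Transformed clones growing on selective agar are photographed at regular
intervals and the total colony-forming-unit (CFU) area is segmented from
each image.  Dividing that area by the average footprint of a single cell
(e.g. 2.2e-6 mm^2 for *E. coli*) converts it into a cell-number estimate;
the exponential growth rate mu is then the slope of ln(cell number) versus
time, and the generation time is ln2/mu.  These plate-derived rates are the
design inputs of the liquid clone-selection model: because colonies grow
quasi-two-dimensionally, they tend to underestimate liquid growth, which
makes the resulting selection schedule conservative.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InsufficientDataError, InvalidParameterError

LN2 = math.log(2.0)

#: Average single-cell footprints on agar [mm^2], used to convert CFU area
#: into cell numbers.
CELL_FOOTPRINT_MM2 = {
    "ecoli": 2.2e-6,
    "pputida": 2.0e-6,
    "cglutamicum": 2.0e-6,
}


@dataclass(frozen=True)
class ColonyAreaSeries:
    """One replicate plate: CFU area sampled over time.

    Parameters
    ----------
    organism_label
        Free-text organism / strain label.
    timepoints
        Sampling times in hours, strictly increasing, at least two.
    cfu_area
        Total CFU area per timepoint in mm^2 (relative areas are fine: a
        constant scale factor does not change the log slope).
    cell_footprint
        Average area of a single cell in mm^2, > 0.
    replicate_id
        Identifier of the plate/well replicate.
    """

    organism_label: str
    timepoints: np.ndarray
    cfu_area: np.ndarray
    cell_footprint: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", np.asarray(self.timepoints, dtype=float))
        object.__setattr__(self, "cfu_area", np.asarray(self.cfu_area, dtype=float))
        if self.timepoints.ndim != 1 or self.timepoints.size < 2:
            raise InvalidParameterError("need at least two timepoints")
        if self.cfu_area.shape != self.timepoints.shape:
            raise InvalidParameterError("cfu_area and timepoints must have equal length")
        if not np.all(np.diff(self.timepoints) > 0):
            raise InvalidParameterError("timepoints must be strictly increasing")
        if np.any(self.cfu_area < 0):
            raise InvalidParameterError("cfu_area must be non-negative")
        if not (self.cell_footprint > 0):
            raise InvalidParameterError("cell_footprint must be positive")


@dataclass(frozen=True)
class GrowthEstimate:
    """Growth rate mu [1/h] with its generation time ln2/mu [h].

    ``generation_time`` is NaN when mu <= 0 (no finite doubling time);
    ``sd_mu`` is the across-replicate standard deviation when the estimate
    aggregates several plates.
    """

    mu: float
    generation_time: float
    sd_mu: float | None = None
    n_replicates: int = 1


def estimate_cell_number(area: float, cell_footprint: float):
    """Cell number from CFU area: ``area / cell_footprint``.

    Linear in ``area`` and inverse-linear in ``cell_footprint``; accepts
    scalars or arrays.
    """
    if not np.all(np.asarray(cell_footprint) > 0):
        raise InvalidParameterError("cell_footprint must be positive")
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise InvalidParameterError("area must be non-negative")
    out = area / cell_footprint
    return float(out) if out.ndim == 0 else out


def log_slope(times: np.ndarray, counts: np.ndarray, *, min_points: int = 2) -> float:
    """Slope of ln(counts) versus time, dropping non-positive counts.

    Two usable points give the difference quotient; more give the ordinary
    least-squares slope.  Returns NaN when fewer than ``min_points`` counts
    are positive.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = counts > 0
    if keep.sum() < min_points:
        return math.nan
    t, y = times[keep], np.log(counts[keep])
    if t.size == 2:
        return float((y[1] - y[0]) / (t[1] - t[0]))
    return float(np.polyfit(t, y, 1)[0])


def estimate_growth_rate(series: ColonyAreaSeries) -> GrowthEstimate:
    """Estimate mu from one colony-area series.

    Zero-area timepoints (empty early plate images) are dropped from the
    log fit with a warning.  A non-increasing series yields mu <= 0, which
    is returned with a warning and a NaN generation time.
    """
    counts = estimate_cell_number(series.cfu_area, series.cell_footprint)
    counts = np.asarray(counts, dtype=float)
    n_zero = int((counts <= 0).sum())
    if n_zero:
        warnings.warn(
            f"{series.replicate_id}: dropping {n_zero} zero-area timepoint(s) from log fit",
            stacklevel=2,
        )
    if (counts > 0).sum() < 2:
        raise InsufficientDataError(
            f"{series.replicate_id}: need >=2 timepoints with positive counts"
        )
    mu = log_slope(series.timepoints, counts)
    if mu <= 0:
        warnings.warn(
            f"{series.replicate_id}: non-positive growth rate mu={mu:.4g} /h",
            stacklevel=2,
        )
        return GrowthEstimate(mu=mu, generation_time=math.nan)
    return GrowthEstimate(mu=mu, generation_time=LN2 / mu)


def generation_time(mu: float) -> float:
    """Population doubling time ln2/mu [h]; requires mu > 0."""
    if not (mu > 0):
        raise InvalidParameterError(f"mu must be positive for a finite doubling time, got {mu}")
    return LN2 / mu


def aggregate_replicates(estimates: list[GrowthEstimate]) -> GrowthEstimate:
    """Mean +- SD of per-replicate growth rates (Table-2-style report)."""
    if not estimates:
        raise InsufficientDataError("no replicate estimates to aggregate")
    mus = np.array([e.mu for e in estimates], dtype=float)
    mean_mu = float(mus.mean())
    sd = float(mus.std(ddof=1)) if mus.size > 1 else None
    gen = LN2 / mean_mu if mean_mu > 0 else math.nan
    return GrowthEstimate(mu=mean_mu, generation_time=gen, sd_mu=sd, n_replicates=mus.size)


def check_consistency(mu: float, measured_generation_time: float, *, rtol: float = 0.25) -> bool:
    """Flag a supplied (mu, generation time) pair that violates ln2/mu.

    Returns True when consistent within ``rtol`` relative; warns otherwise
    (published tables occasionally carry inconsistent pairs).
    """
    expected = generation_time(mu)
    ok = abs(measured_generation_time - expected) <= rtol * expected
    if not ok:
        warnings.warn(
            f"generation time {measured_generation_time:.3g} h inconsistent with "
            f"ln2/mu = {expected:.3g} h (mu = {mu:.3g} /h)",
            stacklevel=2,
        )
    return ok


def read_colony_series_csv(
    path: str | Path, cell_footprint: float, organism_label: str = ""
) -> list[ColonyAreaSeries]:
    """Read replicate colony-area series from a CSV.

    Expected columns: ``replicate_id,time_h,cfu_area_mm2`` (header row,
    comma-separated, '.' decimal).  The per-organism cell footprint comes
    from configuration, not from the file.
    """
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"replicate_id", "time_h", "cfu_area_mm2"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise InvalidParameterError(
                f"colony CSV must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        for row in reader:
            rows.setdefault(row["replicate_id"], []).append(
                (float(row["time_h"]), float(row["cfu_area_mm2"]))
            )
    out = []
    for rid, pts in rows.items():
        pts.sort()
        t, a = zip(*pts)
        out.append(
            ColonyAreaSeries(
                organism_label=organism_label,
                timepoints=np.array(t),
                cfu_area=np.array(a),
                cell_footprint=cell_footprint,
                replicate_id=rid,
            )
        )
    return out


def growth_report(estimate: GrowthEstimate) -> dict:
    """JSON-ready report of a growth estimate."""
    return {
        "mu_per_h": estimate.mu,
        "generation_time_h": estimate.generation_time,
        "sd_mu_per_h": estimate.sd_mu,
        "n_replicates": estimate.n_replicates,
    }
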