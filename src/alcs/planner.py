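"""Stage schedule and liquid-handling worklist for a selection run.

The selection requirement (a number of generations) is turned into a
concrete serial-passage plan: the first well runs for two generation times
(one extra generation absorbs the post-transformation lag; slow hosts can
stretch it further with a resting multiplier), every subsequent well runs
for one generation time, and each stage boundary is a 1:2 transfer — 500 uL
of culture into 500 uL of fresh selective medium in a 1 mL well.  The run
starts by inoculating 50 uL of the transformation approach into 950 uL of
medium.  A five-generation requirement therefore becomes four wells and
three transfers.
"""

from __future__ import annotations

import json
import math
import string
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .exceptions import InvalidParameterError, LayoutError
from .selection_model import SelectionRequirement

#: (rows, columns) of supported plate formats; the 48-well FlowerPlate is 6x8.
PLATE_FORMATS = {48: (6, 8), 96: (8, 12), 384: (16, 24)}


@dataclass(frozen=True)
class Stage:
    well_id: str
    start_time: float          # h
    duration: float            # h
    duration_generations: float


@dataclass(frozen=True)
class Transfer:
    time: float                # h
    source_well: str
    dest_well: str
    transfer_volume_ul: float
    fresh_medium_volume_ul: float


@dataclass(frozen=True)
class StageSchedule:
    """Ordered stages and transfers of one selection run."""

    organism_label: str
    generation_time: float
    stages: tuple[Stage, ...]
    transfers: tuple[Transfer, ...]
    inoculum_volume_ul: float = 50.0
    initial_medium_volume_ul: float = 950.0
    first_stage_generations: float = 2.0
    resting_multiplier: float = 1.0
    dilution: float = 0.5
    working_volume_ul: float = 1000.0

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def total_time(self) -> float:
        last = self.stages[-1]
        return last.start_time + last.duration

    @property
    def total_generations(self) -> float:
        return sum(s.duration_generations for s in self.stages)


def build_schedule(
    requirement: SelectionRequirement,
    generation_time: float,
    *,
    first_stage_generations: float = 2.0,
    resting_multiplier: float = 1.0,
    dilution: float = 0.5,
    working_volume_ul: float = 1000.0,
    inoculum_volume_ul: float = 50.0,
    organism_label: str = "",
    well_ids: list[str] | None = None,
) -> StageSchedule:
    """Expand a selection requirement into stages and transfers.

    The first stage counts ``first_stage_generations`` toward the
    requirement but lasts ``first_stage_generations * resting_multiplier``
    generation times (the multiplier adds pure resting time for hosts with
    long lag phases and does not advance the generation count).  One-
    generation stages are appended until the counted generations reach
    ``requirement.n_generations_scheduled``.
    """
    if not (generation_time > 0):
        raise InvalidParameterError("generation_time must be positive")
    if first_stage_generations < 1:
        raise InvalidParameterError("first_stage_generations must be >= 1")
    if resting_multiplier < 1:
        raise InvalidParameterError("resting_multiplier must be >= 1")
    if not (0 < dilution < 1):
        raise InvalidParameterError(f"dilution must lie in (0, 1), got {dilution}")
    n_target = max(1, requirement.n_generations_scheduled)

    durations_gen = [first_stage_generations * resting_multiplier]
    counted = first_stage_generations
    while counted < n_target:
        durations_gen.append(1.0)
        counted += 1.0

    n_stages = len(durations_gen)
    if well_ids is None:
        well_ids = [f"A{i + 1}" for i in range(n_stages)]
    elif len(well_ids) < n_stages:
        raise InvalidParameterError(f"need {n_stages} well ids, got {len(well_ids)}")

    stages, transfers = [], []
    t = 0.0
    for i, dg in enumerate(durations_gen):
        dur = dg * generation_time
        stages.append(Stage(well_ids[i], start_time=t, duration=dur, duration_generations=dg))
        t += dur
        if i < n_stages - 1:
            transfers.append(
                Transfer(
                    time=t,
                    source_well=well_ids[i],
                    dest_well=well_ids[i + 1],
                    transfer_volume_ul=dilution * working_volume_ul,
                    fresh_medium_volume_ul=(1.0 - dilution) * working_volume_ul,
                )
            )
    return StageSchedule(
        organism_label=organism_label,
        generation_time=generation_time,
        stages=tuple(stages),
        transfers=tuple(transfers),
        inoculum_volume_ul=inoculum_volume_ul,
        initial_medium_volume_ul=working_volume_ul - inoculum_volume_ul,
        first_stage_generations=first_stage_generations,
        resting_multiplier=resting_multiplier,
        dilution=dilution,
        working_volume_ul=working_volume_ul,
    )


def plate_layout(
    n_selections: int, plate_format: int = 48, wells_per_selection: int = 4
) -> dict[int, list[str]]:
    """Assign contiguous row-major well runs to parallel selections.

    A 48-well plate with the default 4-well schedule holds 12 parallel
    selections; a 96-well plate holds 24.
    """
    if plate_format not in PLATE_FORMATS:
        raise InvalidParameterError(
            f"plate_format must be one of {sorted(PLATE_FORMATS)}, got {plate_format}"
        )
    if n_selections < 1 or wells_per_selection < 1:
        raise InvalidParameterError("n_selections and wells_per_selection must be >= 1")
    rows, cols = PLATE_FORMATS[plate_format]
    capacity = rows * cols // wells_per_selection
    if n_selections > capacity:
        raise LayoutError(
            f"{n_selections} selections x {wells_per_selection} wells exceed the "
            f"{plate_format}-well plate capacity of {capacity} selections"
        )
    letters = string.ascii_uppercase
    layout: dict[int, list[str]] = {}
    idx = 0
    for sel in range(1, n_selections + 1):
        wells = []
        for _ in range(wells_per_selection):
            r, c = divmod(idx, cols)
            wells.append(f"{letters[r]}{c + 1}")
            idx += 1
        layout[sel] = wells
    return layout


def export_worklist(schedules) -> pd.DataFrame:
    """One pipetting row per event: the inoculation plus every transfer.

    Accepts one schedule or a sequence of parallel schedules (with distinct
    well ids).  Rows are ordered deterministically by time, then destination
    well.
    """
    if isinstance(schedules, StageSchedule):
        schedules = [schedules]
    rows = []
    for sched in schedules:
        first = sched.stages[0]
        rows.append(
            {
                "time_h": 0.0,
                "event": "inoculate",
                "source": "transformation_approach",
                "dest": first.well_id,
                "volume_ul": sched.inoculum_volume_ul,
                "fresh_medium_ul": sched.initial_medium_volume_ul,
            }
        )
        for tr in sched.transfers:
            rows.append(
                {
                    "time_h": tr.time,
                    "event": "transfer",
                    "source": tr.source_well,
                    "dest": tr.dest_well,
                    "volume_ul": tr.transfer_volume_ul,
                    "fresh_medium_ul": tr.fresh_medium_volume_ul,
                }
            )
    df = pd.DataFrame(rows, columns=["time_h", "event", "source", "dest", "volume_ul", "fresh_medium_ul"])
    return df.sort_values(["time_h", "dest"], kind="stable").reset_index(drop=True)


def schedule_from_worklist(
    worklist: pd.DataFrame,
    generation_time: float,
    *,
    organism_label: str = "",
    resting_multiplier: float = 1.0,
) -> StageSchedule:
    """Rebuild a single-selection schedule from its exported worklist.

    The worklist carries no explicit end-of-run event, so the last stage is
    assumed to span one generation time (the standard rule).  Only
    single-selection worklists (exactly one ``inoculate`` row) are accepted.
    """
    ino = worklist[worklist["event"] == "inoculate"]
    if len(ino) != 1:
        raise InvalidParameterError("worklist must contain exactly one inoculation row")
    ino = ino.iloc[0]
    trs = worklist[worklist["event"] == "transfer"].sort_values("time_h")
    if len(trs) == 0:
        first_duration = 2.0 * resting_multiplier * generation_time
    else:
        first_duration = float(trs.iloc[0]["time_h"])
    fsg = first_duration / (generation_time * resting_multiplier)
    n_counted = fsg + len(trs)
    req = SelectionRequirement(
        t_required=first_duration + len(trs) * generation_time,
        n_generations_required=n_counted,
        n_generations_scheduled=math.ceil(round(n_counted, 9)),
    )
    if len(trs):
        volume = float(trs.iloc[0]["volume_ul"])
        working = volume + float(trs.iloc[0]["fresh_medium_ul"])
        dilution = volume / working
    else:
        dilution, working = 0.5, float(ino["volume_ul"] + ino["fresh_medium_ul"])
    well_ids = [ino["dest"], *trs["dest"].tolist()]
    return build_schedule(
        req,
        generation_time,
        first_stage_generations=fsg,
        resting_multiplier=resting_multiplier,
        dilution=dilution,
        working_volume_ul=working,
        inoculum_volume_ul=float(ino["volume_ul"]),
        organism_label=organism_label,
        well_ids=well_ids,
    )


def schedule_to_json(schedule: StageSchedule, path: str | Path | None = None) -> str:
    """Serialize a schedule; writes to ``path`` when given."""
    text = json.dumps(asdict(schedule), indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def schedule_from_json(source: str | Path) -> StageSchedule:
    """Inverse of :func:`schedule_to_json` (accepts a path or a JSON string)."""
    p = Path(source) if not str(source).lstrip().startswith("{") else None
    data = json.loads(p.read_text() if p else source)
    data["stages"] = tuple(Stage(**s) for s in data["stages"])
    data["transfers"] = tuple(Transfer(**t) for t in data["transfers"])
    return StageSchedule(**data)
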