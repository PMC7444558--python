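"""Health states, the transition multigraph, and individual trajectories.

Six mutually exclusive states describe where a person with diagnosed COPD is
at any moment:

* ``DX``  — in the community, post diagnosis
* ``EDC`` — in the emergency department for a COPD-related reason
* ``EDO`` — in the emergency department for a non-COPD-related reason
* ``HC``  — hospitalized for a COPD-related reason
* ``HO``  — hospitalized for a non-COPD-related reason
* ``MO``  — dead (all causes; absorbing)

Transitions out of community and hospital states are time-to-event
("parametric") arcs; ED visits resolve the same day through a multinomial
choice among community, hospital and death, because an ED stay is assumed
never to span midnight.  The default structure has 9 parametric arcs and
2 x 4 same-day arcs: 17 direct transitions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DX", "EDC", "EDO", "HC", "HO", "MO",
    "STATES", "ED_STATES", "HOSPITAL_STATES",
    "TransitionStructure", "Trajectory", "StructureError",
    "EVENT_STATE", "EVENT_TYPES",
    "trajectories_to_frame", "frame_to_trajectories",
]

DX = "DX"
EDC = "EDC"
EDO = "EDO"
HC = "HC"
HO = "HO"
MO = "MO"

STATES: Tuple[str, ...] = (DX, EDC, EDO, HC, HO, MO)
ED_STATES: FrozenSet[str] = frozenset({EDC, EDO})
HOSPITAL_STATES: FrozenSet[str] = frozenset({HC, HO})

# recurrent-event types tallied by the time-dependent counters
EVENT_STATE: Dict[str, str] = {
    "copd_ed": EDC,
    "other_ed": EDO,
    "copd_hosp": HC,
    "other_hosp": HO,
}
EVENT_TYPES: Tuple[str, ...] = tuple(EVENT_STATE)


class StructureError(ValueError):
    """A trajectory or model set is inconsistent with the transition structure."""


_DEFAULT_PARAMETRIC = frozenset({
    (DX, EDC), (DX, EDO), (DX, HC), (DX, HO), (DX, MO),
    (HC, DX), (HC, MO),
    (HO, DX), (HO, MO),
})
_DEFAULT_INSTANT = {
    EDC: (DX, HC, HO, MO),
    EDO: (DX, HC, HO, MO),
}


@dataclass(frozen=True)
class TransitionStructure:
    """Directed multigraph of states: parametric arcs plus same-day ED arcs."""

    parametric_arcs: FrozenSet[Tuple[str, str]] = _DEFAULT_PARAMETRIC
    instant_arcs: Tuple[Tuple[str, Tuple[str, ...]], ...] = tuple(
        sorted(_DEFAULT_INSTANT.items())
    )

    def __post_init__(self) -> None:
        for frm, to in self.parametric_arcs:
            if frm not in STATES or to not in STATES:
                raise StructureError(f"unknown state in arc {frm}->{to}")
            if frm == MO:
                raise StructureError("death is absorbing; no outgoing arcs from MO")
        inst = dict(self.instant_arcs)
        for origin, dests in inst.items():
            if origin not in ED_STATES:
                raise StructureError(f"instant arcs must originate in an ED state, got {origin}")
            for d in dests:
                if (origin, d) in self.parametric_arcs:
                    raise StructureError(f"arc {origin}->{d} is both parametric and instant")
        # every non-absorbing state that appears in the structure needs an exit
        present = {s for arc in self.parametric_arcs for s in arc}
        present.update(inst)
        present.update(d for dests in inst.values() for d in dests)
        for s in present - {MO}:
            if not self.parametric_exits(s) and s not in inst:
                raise StructureError(f"state {s} has no exit")

    @property
    def instant_destinations(self) -> Dict[str, Tuple[str, ...]]:
        return dict(self.instant_arcs)

    def parametric_exits(self, state: str) -> List[Tuple[str, str]]:
        """Parametric exit arcs from ``state``, in a fixed sorted order."""
        return sorted(a for a in self.parametric_arcs if a[0] == state)

    @property
    def n_transitions(self) -> int:
        return len(self.parametric_arcs) + sum(
            len(d) for _, d in self.instant_arcs
        )

    @classmethod
    def default(cls) -> "TransitionStructure":
        return cls()


@dataclass
class Trajectory:
    """One simulated or observed event history.

    ``times``/``states`` record each state *entry* (days since diagnosis,
    non-decreasing, starting at (0, DX)); same-day ED resolutions appear as
    repeated times.  ``horizon`` is the administrative end of follow-up; a
    subject not dead by then is censored there.
    """

    subject_id: int
    times: List[float] = field(default_factory=lambda: [0.0])
    states: List[str] = field(default_factory=lambda: [DX])
    horizon: float = float("inf")

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")
        if not self.times or self.times[0] != 0.0 or self.states[0] != DX:
            raise ValueError("a trajectory starts at (0, DX)")
        if any(b < a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("entry times must be non-decreasing")
        if MO in self.states[:-1]:
            raise ValueError("nothing may follow death")

    @property
    def died(self) -> bool:
        return self.states[-1] == MO

    @property
    def death_time(self) -> Optional[float]:
        return self.times[-1] if self.died else None

    @property
    def end_time(self) -> float:
        """Death time if dead, else the censoring horizon."""
        return self.times[-1] if self.died else self.horizon

    def event_times(self, event_type: str) -> List[float]:
        """Entry times to the state counted by ``event_type``."""
        state = EVENT_STATE[event_type]
        return [t for t, s in zip(self.times, self.states) if s == state]

    def hospital_stays(self, state: str) -> List[Tuple[float, float, str]]:
        """(entry, exit, next_state) per completed stay in a hospital state."""
        if state not in HOSPITAL_STATES:
            raise ValueError(f"{state} is not a hospital state")
        stays = []
        for i, (t, s) in enumerate(zip(self.times, self.states)):
            if s != state:
                continue
            if i + 1 < len(self.times):
                stays.append((t, self.times[i + 1], self.states[i + 1]))
        return stays

    def state_at(self, t: float) -> str:
        """State occupied at time t (right-continuous; last entry at or before t)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(idx, 0)]


def trajectories_to_frame(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Long-format view: one row per state entry (subject, time_days, state)."""
    rows = []
    for tr in trajectories:
        for t, s in zip(tr.times, tr.states):
            rows.append((tr.subject_id, t, s))
        rows.append((tr.subject_id, tr.end_time, "END" if not tr.died else MO))
    df = pd.DataFrame(rows, columns=["subject", "time_days", "state"])
    return df.drop_duplicates(ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame, horizon: float) -> List[Trajectory]:
    """Rebuild trajectories from the long format written by the writer."""
    out = []
    for sid, grp in df.groupby("subject", sort=True):
        grp = grp.sort_values("time_days", kind="stable")
        times, states = [], []
        for _, row in grp.iterrows():
            if row["state"] == "END":
                continue
            times.append(float(row["time_days"]))
            states.append(str(row["state"]))
        out.append(Trajectory(int(sid), times, states, horizon=horizon))
    return out
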