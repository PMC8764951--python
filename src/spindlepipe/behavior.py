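"""Scoring of the two behavioural assays from event tables.

Cold allodynia (acetone test): five acetone applications per session, three
minutes apart; the score is the number of hind-paw withdrawals (0–5).

Elevated plus maze (EPM): a five-minute session on a plus-shaped maze with two
open and two closed arms.  The animal starts at the center; the input is the
ordered sequence of zone-entry events annotated upstream (the all-four-paws
entry criterion is assumed already applied by the annotator).  Scores are
per-zone occupancy times, arm entries, and percent time in the closed arm
(denominator: the full 300 s session).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZONES",
    "BEHAVIOR_DAYS",
    "AcetoneSession",
    "EpmSession",
    "EpmMetrics",
    "allodynia_score",
    "epm_metrics",
    "read_acetone_tsv",
    "write_acetone_tsv",
    "read_epm_tsv",
    "write_epm_tsv",
]

ZONES = ("OPEN", "CLOSED", "CENTER")
BEHAVIOR_DAYS = ("DAY3", "DAY6")
N_TRIALS = 5
EPM_SESSION_LENGTH = 300.0


@dataclass
class AcetoneSession:
    """One animal's acetone-test session: five 0/1 withdrawal indicators."""

    animal_id: str
    day: str
    trials: tuple
    inter_trial_interval: float = 180.0

    def __post_init__(self) -> None:
        self.trials = tuple(int(t) for t in self.trials)
        if any(t not in (0, 1) for t in self.trials):
            raise ValueError(f"withdrawal indicators must be 0/1, got {self.trials}")


@dataclass
class EpmSession:
    """One animal's EPM session: ordered (timestamp s, zone) entry events."""

    animal_id: str
    day: str
    events: list = field(default_factory=list)
    session_length: float = EPM_SESSION_LENGTH

    def __post_init__(self) -> None:
        self.events = [(float(t), str(z).upper()) for t, z in self.events]


@dataclass
class EpmMetrics:
    open_time: float
    closed_time: float
    center_time: float
    open_entries: int
    closed_entries: int
    pct_closed: float


def allodynia_score(session: AcetoneSession) -> int:
    """Withdrawal frequency: the sum of the five trial indicators."""
    if len(session.trials) != N_TRIALS:
        raise ValueError(
            f"acetone session needs exactly {N_TRIALS} trials, got {len(session.trials)}"
        )
    return int(sum(session.trials))


def epm_metrics(session: EpmSession) -> EpmMetrics:
    """Zone occupancy and arm entries from the event sequence.

    Each zone is held from its entry timestamp until the next event; the last
    zone is held to the end of the session, so the three occupancy times sum
    to the session length exactly.  An entry is a transition into an arm zone
    from a different zone.
    """
    events = session.events
    length = session.session_length
    if not events:
        raise ValueError("EPM session has no events")
    times = np.array([t for t, _ in events], dtype=float)
    zones = [z for _, z in events]
    unknown = sorted(set(zones) - set(ZONES))
    if unknown:
        raise ValueError(f"unknown EPM zones {unknown}; expected {list(ZONES)}")
    if times[0] != 0.0 or zones[0] != "CENTER":
        raise ValueError("EPM session must start with a (0, CENTER) event")
    if np.any(np.diff(times) <= 0):
        raise ValueError("EPM event timestamps must be strictly increasing")
    if times[-1] > length:
        raise ValueError(
            f"EPM event at {times[-1]:g} s lies beyond the {length:g} s session"
        )

    occupancy = dict.fromkeys(ZONES, 0.0)
    bounds = np.append(times, length)
    for i, zone in enumerate(zones):
        occupancy[zone] += bounds[i + 1] - bounds[i]

    open_entries = sum(
        1 for i, z in enumerate(zones) if z == "OPEN" and (i == 0 or zones[i - 1] != z)
    )
    closed_entries = sum(
        1 for i, z in enumerate(zones) if z == "CLOSED" and (i == 0 or zones[i - 1] != z)
    )
    return EpmMetrics(
        open_time=occupancy["OPEN"],
        closed_time=occupancy["CLOSED"],
        center_time=occupancy["CENTER"],
        open_entries=open_entries,
        closed_entries=closed_entries,
        pct_closed=occupancy["CLOSED"] / length * 100.0,
    )


# ---------------------------------------------------------------------------
# Tab-separated session tables
# ---------------------------------------------------------------------------

def write_acetone_tsv(sessions, path) -> None:
    rows = [
        {"animal_id": s.animal_id, "day": s.day,
         **{f"trial{i + 1}": v for i, v in enumerate(s.trials)}}
        for s in sessions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_acetone_tsv(path):
    frame = pd.read_csv(path, sep="\t")
    trial_cols = [f"trial{i + 1}" for i in range(N_TRIALS)]
    return [
        AcetoneSession(
            animal_id=str(row["animal_id"]),
            day=str(row["day"]),
            trials=tuple(int(row[c]) for c in trial_cols),
        )
        for _, row in frame.iterrows()
    ]


def write_epm_tsv(sessions, path) -> None:
    rows = [
        {"animal_id": s.animal_id, "day": s.day, "time_s": t, "zone": z}
        for s in sessions
        for t, z in s.events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_epm_tsv(path):
    frame = pd.read_csv(path, sep="\t")
    sessions = []
    for (animal, day), grp in frame.groupby(["animal_id", "day"], sort=False):
        sessions.append(
            EpmSession(
                animal_id=str(animal),
                day=str(day),
                events=list(zip(grp["time_s"], grp["zone"])),
            )
        )
    return sessions
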