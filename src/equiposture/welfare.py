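"""Rule-based scoring of behaviour observations into welfare indicators.

Three per-horse indicators are derived from stall observations:

* **SB/ARB** (stereotypic / abnormal repetitive behaviour), binary: a
  behaviour qualifies when its sequence was repeated at least 3 times
  successively and such a bout was observed at least 5 times; a horse
  scores 1 if any behaviour qualifies.
* **Depressed-like posture**, binary: 1 if the characteristic immobile,
  flat-necked, environment-indifferent stance was seen at least once.
* **Ear position** category: the "favourite" posture over 10 foraging
  scans — forward or backward when that position reaches at least 60%
  of scans, otherwise neutral (asymmetric/lateral scans count neutral).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

EAR_CATEGORIES = ("forward", "backward", "neutral")

#: Bouts must repeat the sequence at least this many times successively.
MIN_SUCCESSIVE_REPEATS = 3
#: A behaviour must be observed in at least this many qualifying bouts.
MIN_QUALIFYING_EVENTS = 5
#: A favourite ear posture must cover at least this fraction of scans.
EAR_MAJORITY_FRACTION = 0.6
#: Number of instantaneous ear-position scans collected per horse.
N_EAR_SCANS = 10


@dataclass
class ObservationStream:
    """Time-ordered behaviour observations for one horse."""

    horse_id: str
    events: list[tuple[str, int]] = field(default_factory=list)  # (label, run_length)
    ear_scans: list[str] = field(default_factory=list)
    depressed_seen: int = 0
    total_hours: float = 18.0

    def __post_init__(self) -> None:
        for label, run in self.events:
            if run < 1:
                raise ValueError(f"run_length must be >= 1, got {run} for {label!r}")


@dataclass
class WelfareRecord:
    """Per-horse welfare indicators and management covariates."""

    horse_id: str
    sb_arb: int = 0
    depressed: int = 0
    ear_category: str = "neutral"
    type_of_equid: str = "horse"        # pony | horse
    proportion: str = "meso"            # dolicho | meso | brachy
    hay_meals: int = 1
    paddock_time: float = 0.0           # percent of time
    paddock_social: str = "group"       # alone | group
    visible_conspecifics: int = 0
    work_hours: float = 0.0             # per week

    def __post_init__(self) -> None:
        if self.sb_arb not in (0, 1) or self.depressed not in (0, 1):
            raise ValueError("sb_arb and depressed must be binary")
        if self.ear_category not in EAR_CATEGORIES:
            raise ValueError(f"ear_category must be one of {EAR_CATEGORIES}")


def score_sb_arb(stream: ObservationStream) -> int:
    """1 iff some behaviour label has at least 5 bouts of >= 3 successive
    repeats each; 0 otherwise. Monotone in added observations."""
    qualifying = Counter(
        label for label, run in stream.events if run >= MIN_SUCCESSIVE_REPEATS
    )
    return int(any(n >= MIN_QUALIFYING_EVENTS for n in qualifying.values()))


def score_depressed(stream: ObservationStream) -> int:
    """1 iff the depressed-like posture was seen at least once."""
    return int(stream.depressed_seen >= 1)


def categorize_ear_position(scans: list[str]) -> str:
    """Favourite ear posture over exactly 10 scans: 'forward' or
    'backward' when reaching >= 60% of scans, else 'neutral'."""
    if len(scans) != N_EAR_SCANS:
        raise ValueError(f"expected exactly {N_EAR_SCANS} scans, got {len(scans)}")
    bad = set(scans) - set(EAR_CATEGORIES)
    if bad:
        raise ValueError(f"unknown ear positions {sorted(bad)}")
    counts = Counter(scans)
    threshold = EAR_MAJORITY_FRACTION * N_EAR_SCANS
    for cat in ("forward", "backward"):
        if counts[cat] >= threshold:
            return cat
    return "neutral"


def prevalence(flags: list[int]) -> tuple[float, int]:
    """Percentage of positive flags: (raw percentage, half-up rounded
    integer percent as printed in prevalence tables)."""
    if not flags:
        raise ValueError("prevalence of an empty list is undefined")
    raw = 100.0 * sum(1 for f in flags if f) / len(flags)
    return raw, int(math.floor(raw + 0.5))


# ---------------------------------------------------------------------------
# Delimited-text interfaces

WELFARE_COLUMNS = [
    "horse_id", "sb_arb", "depressed", "ear_category", "type_of_equid",
    "proportion", "hay_meals", "paddock_time", "paddock_social",
    "visible_conspecifics", "work_hours",
]


def records_to_frame(records: list[WelfareRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in WELFARE_COLUMNS} for r in records]
    )


def write_welfare_csv(records: list[WelfareRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_welfare_csv(path: str) -> list[WelfareRecord]:
    df = pd.read_csv(path)
    missing = set(WELFARE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"welfare table missing columns {sorted(missing)}")
    return [
        WelfareRecord(
            horse_id=str(row.horse_id),
            sb_arb=int(row.sb_arb),
            depressed=int(row.depressed),
            ear_category=str(row.ear_category),
            type_of_equid=str(row.type_of_equid),
            proportion=str(row.proportion),
            hay_meals=int(row.hay_meals),
            paddock_time=float(row.paddock_time),
            paddock_social=str(row.paddock_social),
            visible_conspecifics=int(row.visible_conspecifics),
            work_hours=float(row.work_hours),
        )
        for row in df.itertuples()
    ]


def write_streams_csv(streams: list[ObservationStream], events_path: str, scans_path: str) -> None:
    """Write behaviour streams: an event table (horse_id, timestamp, label,
    run_length) and a per-horse scan table (ear scans, depressed sightings)."""
    ev_rows = []
    for s in streams:
        for t, (label, run) in enumerate(s.events):
            ev_rows.append(
                {"horse_id": s.horse_id, "timestamp": t, "label": label, "run_length": run}
            )
    pd.DataFrame(ev_rows, columns=["horse_id", "timestamp", "label", "run_length"]).to_csv(
        events_path, index=False
    )
    pd.DataFrame(
        [
            {
                "horse_id": s.horse_id,
                "ear_scans": "|".join(s.ear_scans),
                "depressed_seen": s.depressed_seen,
                "total_hours": s.total_hours,
            }
            for s in streams
        ]
    ).to_csv(scans_path, index=False)


def read_streams_csv(events_path: str, scans_path: str) -> list[ObservationStream]:
    ev = pd.read_csv(events_path)
    sc = pd.read_csv(scans_path)
    streams = []
    for row in sc.itertuples():
        hid = str(row.horse_id)
        sub = ev[ev.horse_id.astype(str) == hid].sort_values("timestamp")
        events = [(str(r.label), int(r.run_length)) for r in sub.itertuples()]
        scans = str(row.ear_scans).split("|") if isinstance(row.ear_scans, str) and row.ear_scans else []
        streams.append(
            ObservationStream(
                horse_id=hid,
                events=events,
                ear_scans=scans,
                depressed_seen=int(row.depressed_seen),
                total_hours=float(row.total_hours),
            )
        )
    return streams
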