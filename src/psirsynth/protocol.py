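"""Acquisition protocols and their heartbeat schedules.

A protocol is an ordered list of preparation events, each of which costs
one acquisition heartbeat plus a number of idle recovery heartbeats. The
default mSASHA protocol (3 anchors, 6 T2-prepared SR images at TE 55 ms,
21 plain SR images at TS 300 ms) acquires 30 images in 45 heartbeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

from .signal_models import PREP_KINDS

__all__ = [
    "PreparationEvent",
    "ProtocolSpec",
    "default_msasha_protocol",
    "bb_psir_moco_protocol",
    "db_psir_moco_protocol",
    "heartbeat_cost",
    "acquisition_times",
    "load_protocol",
]

#: Event kinds that have a closed-form mSASHA signal.
MSASHA_KINDS = PREP_KINDS
#: Kinds accepted in a protocol; IR kinds describe conventional LGE
#: protocols whose heartbeat accounting we track but whose frames we do
#: not simulate.
EVENT_KINDS = PREP_KINDS + ("IR", "IR+T2prep")

_DEFAULT_RECOVERY = {"anchor": 3, "SR": 0, "SR+T2prep": 1, "IR": 1, "IR+T2prep": 1}


@dataclass(frozen=True)
class PreparationEvent:
    """One magnetisation preparation + single-shot readout.

    ``recovery_beats`` counts idle heartbeats before the acquisition beat;
    defaults follow the stated protocol (3 for anchors, 1 for T2-prepared
    images, 0 for plain SR).
    """

    kind: str
    ts: float = 300.0
    te_prep: float | None = None
    recovery_beats: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.ts < 0:
            raise ValueError("ts must be non-negative")
        if self.te_prep is not None and self.te_prep < 0:
            raise ValueError("te_prep must be non-negative")
        if self.kind.endswith("T2prep") and self.te_prep is None:
            raise ValueError(f"{self.kind} events require te_prep")
        if self.recovery_beats is None:
            object.__setattr__(self, "recovery_beats", _DEFAULT_RECOVERY[self.kind])
        if self.recovery_beats < 0:
            raise ValueError("recovery_beats must be non-negative")

    @property
    def beats(self) -> int:
        """Heartbeat cost of this event (recovery + 1 acquisition beat)."""
        return self.recovery_beats + 1

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "ts": self.ts,
            "te_prep": self.te_prep,
            "recovery_beats": self.recovery_beats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreparationEvent":
        return cls(
            kind=d["kind"],
            ts=float(d.get("ts", 300.0)),
            te_prep=None if d.get("te_prep") is None else float(d["te_prep"]),
            recovery_beats=None if d.get("recovery_beats") is None else int(d["recovery_beats"]),
        )


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered acquisition protocol with its heartbeat interval.

    ``rr`` is the heartbeat (R-R) interval in ms; 1000 ms (60 bpm) is the
    default. ``ir_timing`` carries TI or TD1/TD2/TE for conventional LGE
    protocols and is None for mapping protocols.
    """

    name: str
    events: tuple[PreparationEvent, ...]
    rr: float = 1000.0
    ir_timing: dict | None = None

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("protocol must contain at least one event")
        if self.rr <= 0:
            raise ValueError("rr must be positive")
        object.__setattr__(self, "events", tuple(self.events))

    @property
    def n_images(self) -> int:
        return len(self.events)

    def kinds(self) -> np.ndarray:
        return np.array([e.kind for e in self.events])

    def recovery_durations(self) -> np.ndarray:
        """Effective saturation-to-readout delay per event, ms.

        Anchor frames recover for ``recovery_beats * RR + TS``; SR frames
        (with or without T2 preparation) are read out TS after the
        saturation in the acquisition beat.
        """
        out = np.empty(self.n_images)
        for i, e in enumerate(self.events):
            out[i] = e.recovery_beats * self.rr + e.ts if e.kind == "anchor" else e.ts
        return out

    def te_preps(self) -> np.ndarray:
        """T2-preparation echo time per event, ms (0 where absent)."""
        return np.array([0.0 if e.te_prep is None else e.te_prep for e in self.events])

    def with_events(self, events: Iterable[PreparationEvent]) -> "ProtocolSpec":
        return replace(self, events=tuple(events))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "rr": self.rr,
            "ir_timing": self.ir_timing,
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            name=d.get("name", "protocol"),
            rr=float(d.get("rr", 1000.0)),
            ir_timing=d.get("ir_timing"),
            events=tuple(PreparationEvent.from_dict(e) for e in d["events"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_msasha_protocol(
    ts: float = 300.0,
    te_prep: float = 55.0,
    rr: float = 1000.0,
    n_anchor: int = 3,
    n_t2prep: int = 6,
    n_sr: int = 21,
) -> ProtocolSpec:
    """The post-contrast mSASHA protocol: 30 images over 45 heartbeats.

    3 anchor images with 3 recovery beats each, 6 SR+T2prep images at a
    fixed TE of 55 ms with 1 recovery beat each, and 21 SR images at
    TS = 300 ms with no recovery beats.
    """
    events = (
        [PreparationEvent("anchor", ts=ts) for _ in range(n_anchor)]
        + [PreparationEvent("SR+T2prep", ts=ts, te_prep=te_prep) for _ in range(n_t2prep)]
        + [PreparationEvent("SR", ts=ts) for _ in range(n_sr)]
    )
    return ProtocolSpec(name="msasha-default", events=tuple(events), rr=rr)


def bb_psir_moco_protocol(rr: float = 1000.0, ti: float = 300.0) -> ProtocolSpec:
    """Conventional bright-blood PSIR MOCO: 8 images in 16 beats.

    Each IR image is paired with a proton-density beat, accounted for here
    as one recovery beat per event.
    """
    events = tuple(PreparationEvent("IR", ts=0.0, recovery_beats=1) for _ in range(8))
    return ProtocolSpec(name="bb-psir-moco", events=events, rr=rr, ir_timing={"ti": ti})


def db_psir_moco_protocol(
    rr: float = 1000.0, td1: float = 300.0, td2: float = 100.0, te_prep: float = 30.0
) -> ProtocolSpec:
    """Conventional dark-blood PSIR MOCO: 16 images in 32 beats."""
    events = tuple(
        PreparationEvent("IR+T2prep", ts=0.0, te_prep=te_prep, recovery_beats=1)
        for _ in range(16)
    )
    return ProtocolSpec(
        name="db-psir-moco",
        events=events,
        rr=rr,
        ir_timing={"td1": td1, "td2": td2, "te_prep": te_prep},
    )


def heartbeat_cost(protocol: ProtocolSpec) -> int:
    """Total heartbeats to acquire the protocol (recovery + acquisition)."""
    return int(sum(e.beats for e in protocol.events))


def acquisition_times(protocol: ProtocolSpec) -> np.ndarray:
    """Absolute start time of each acquisition beat, ms.

    Events are scheduled back to back: each event's acquisition beat
    follows its recovery beats. The last acquisition starts at
    ``(heartbeat_cost - 1) * RR``.
    """
    beats_before = np.cumsum([e.beats for e in protocol.events])
    # acquisition beat is the last beat of each event
    return (beats_before - 1) * protocol.rr


_BUILTINS = {
    "msasha-default": default_msasha_protocol,
    "bb-psir-moco": bb_psir_moco_protocol,
    "db-psir-moco": db_psir_moco_protocol,
}


def load_protocol(name_or_path: str) -> ProtocolSpec:
    """Resolve a builtin protocol name or a YAML protocol file."""
    if name_or_path in _BUILTINS:
        return _BUILTINS[name_or_path]()
    return ProtocolSpec.from_yaml(name_or_path)
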