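"""Trace-conditioning stimulus protocol.

The paradigm pairs a conditioned stimulus (a short tone pattern) with either
a musical stimulus (MUS) or a noxious pressure stimulus (NOC).  Sixteen
trials are delivered in two consecutive eight-trial sequences:

* sequence A tests acquisition of the conditioned response — three noxious
  stimuli are actually delivered (NOC1..NOC3) and the eighth trial
  (``NOC_STAR``) presents the noxious-associated tones alone;
* sequence B tests extinction — every trial is tones-only (labels carry a
  ``*`` suffix).

A five-minute quiet baseline precedes stimulation, and consecutive trials
are separated by a 25-s inter-stimulus interval so each skin-conductance
wave can resolve before the next tone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd
import yaml

__all__ = [
    "Kind",
    "Sequence",
    "PitchClass",
    "NoteDuration",
    "StimulusEvent",
    "TonePattern",
    "ProtocolTimeline",
    "TimeWindow",
    "SEQUENCE_A_LABELS",
    "SEQUENCE_B_LABELS",
    "DEFAULT_ISI_S",
    "DEFAULT_BASELINE_S",
    "DEFAULT_SEARCH_WINDOW_S",
    "MUSIC_FADEOUT_S",
    "NOXIOUS_MAX_PRESSURE_S",
    "build_protocol",
    "load_protocol_config",
    "tone_pattern",
    "epoch_window",
    "read_events",
    "write_events",
]


class Kind(str, enum.Enum):
    MUSIC = "MUSIC"
    NOXIOUS = "NOXIOUS"


class Sequence(str, enum.Enum):
    A = "A"
    B = "B"


class PitchClass(str, enum.Enum):
    GRAVE = "GRAVE"
    ACUTE_FIFTH = "ACUTE_FIFTH"


class NoteDuration(str, enum.Enum):
    SHORT = "SHORT"
    LONG = "LONG"


#: Sequence A: stimuli delivered after the tones, except the starred trial.
SEQUENCE_A_LABELS = (
    "MUS1", "NOC1", "MUS2", "MUS3", "NOC2", "MUS4", "NOC3", "NOC_STAR",
)
#: Sequence B: tones only, probing extinction of the conditioned response.
SEQUENCE_B_LABELS = (
    "MUS1*", "NOC1*", "NOC2*", "MUS2*", "NOC3*", "MUS3*", "NOC4*", "MUS4*",
)

DEFAULT_ISI_S = 25.0
DEFAULT_BASELINE_S = 300.0
DEFAULT_SEARCH_WINDOW_S = 10.0

# Delivery metadata: the music fades out over its last 5 s and the nail-bed
# pressure is capped at 5 s.  Neither alters event timing; the synthetic
# generator uses them to shape responses.
MUSIC_FADEOUT_S = 5.0
NOXIOUS_MAX_PRESSURE_S = 5.0


def _kind_of(label: str) -> Kind:
    return Kind.NOXIOUS if label.startswith("NOC") else Kind.MUSIC


def _tone_only(label: str) -> bool:
    return label == "NOC_STAR" or label.endswith("*")


@dataclass(frozen=True)
class StimulusEvent:
    """One trial: tone-pattern onset plus what (if anything) follows it."""

    label: str
    kind: Kind
    tone_only: bool
    sequence: Sequence
    onset: float  # seconds from recording start, at tone onset
    position: int  # 1-based index in the 16-trial series


@dataclass(frozen=True)
class TonePattern:
    """Symbolic description of the announcing tones for one stimulus kind."""

    notes: tuple[tuple[PitchClass, NoteDuration], ...]
    inter_tone_interval: float  # seconds


@dataclass(frozen=True)
class TimeWindow:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"TimeWindow requires end > start, got [{self.start}, {self.end}]")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ProtocolTimeline:
    """The full 16-trial design plus its preceding baseline."""

    baseline_duration: float
    isi: float
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ev = self.events
        if len(ev) != 16:
            raise ValueError(f"protocol requires 16 events, got {len(ev)}")
        labels = [e.label for e in ev]
        if len(set(labels)) != 16:
            raise ValueError("event labels must be unique")
        n_a = sum(e.sequence is Sequence.A for e in ev)
        if n_a != 8:
            raise ValueError(f"expected 8 sequence-A events, got {n_a}")
        last_a = max(i for i, e in enumerate(ev) if e.sequence is Sequence.A)
        first_b = min(i for i, e in enumerate(ev) if e.sequence is Sequence.B)
        if last_a > first_b:
            raise ValueError("sequence A must precede sequence B entirely")
        for i, e in enumerate(ev):
            if e.position != i + 1:
                raise ValueError(f"event {e.label}: position {e.position} != {i + 1}")
            if e.tone_only != _tone_only(e.label):
                raise ValueError(f"event {e.label}: inconsistent tone_only flag")
            if i > 0 and not e.onset > ev[i - 1].onset:
                raise ValueError(f"onsets not strictly increasing at {e.label}")
            if i > 0 and e.onset - ev[i - 1].onset < self.isi - 1e-9:
                raise ValueError(f"spacing below isi={self.isi} before {e.label}")
        if ev[0].onset < self.baseline_duration - 1e-9:
            raise ValueError("first onset precedes end of baseline")

    # Segment spans used for RR annotation and feature epoching.
    @property
    def sequence_b_start(self) -> float:
        return min(e.onset for e in self.events if e.sequence is Sequence.B)

    @property
    def end_time(self) -> float:
        return self.events[-1].onset + self.isi

    def event(self, label: str) -> StimulusEvent:
        for e in self.events:
            if e.label == label:
                return e
        raise KeyError(label)

    def next_onset_after(self, event: StimulusEvent) -> float:
        """Onset of the following trial, or the end of the recording span."""
        if event.position < 16:
            return self.events[event.position].onset
        return self.end_time


def build_protocol(isi: float = DEFAULT_ISI_S, baseline: float = DEFAULT_BASELINE_S) -> ProtocolTimeline:
    """Construct the canonical 16-trial timeline with uniform spacing.

    Onsets are deterministic: event ``k`` (1-based) starts at
    ``baseline + (k - 1) * isi``.
    """
    if isi <= 0:
        raise ValueError(f"isi must be positive, got {isi}")
    if baseline < 0:
        raise ValueError(f"baseline must be nonnegative, got {baseline}")
    events = []
    for k, label in enumerate(SEQUENCE_A_LABELS + SEQUENCE_B_LABELS):
        seq = Sequence.A if k < 8 else Sequence.B
        events.append(
            StimulusEvent(
                label=label,
                kind=_kind_of(label),
                tone_only=_tone_only(label),
                sequence=seq,
                onset=baseline + k * isi,
                position=k + 1,
            )
        )
    return ProtocolTimeline(baseline_duration=baseline, isi=isi, events=events)


def tone_pattern(kind: Kind) -> TonePattern:
    """Announcing tones: two short grave notes; the noxious pattern appends
    one long note a fifth above. Inter-tone interval is 1 s."""
    if kind is Kind.MUSIC:
        notes = ((PitchClass.GRAVE, NoteDuration.SHORT),) * 2
    elif kind is Kind.NOXIOUS:
        notes = ((PitchClass.GRAVE, NoteDuration.SHORT),) * 2 + (
            (PitchClass.ACUTE_FIFTH, NoteDuration.LONG),
        )
    else:
        raise ValueError(f"unknown stimulus kind: {kind!r}")
    return TonePattern(notes=notes, inter_tone_interval=1.0)


def epoch_window(event: StimulusEvent, search: float = DEFAULT_SEARCH_WINDOW_S) -> TimeWindow:
    """Peak-search window: ``search`` seconds from stimulus administration."""
    if search <= 0:
        raise ValueError(f"search window must be positive, got {search}")
    return TimeWindow(start=event.onset, end=event.onset + search)


def load_protocol_config(path) -> dict:
    """Read a YAML protocol config; keys isi_s, baseline_s,
    search_window_s, all optional, defaulting to the canonical values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"protocol config {path}: expected a mapping")
    unknown = set(raw) - {"isi_s", "baseline_s", "search_window_s"}
    if unknown:
        raise ValueError(f"protocol config {path}: unknown key(s) {sorted(unknown)}")
    return {
        "isi_s": float(raw.get("isi_s", DEFAULT_ISI_S)),
        "baseline_s": float(raw.get("baseline_s", DEFAULT_BASELINE_S)),
        "search_window_s": float(raw.get("search_window_s", DEFAULT_SEARCH_WINDOW_S)),
    }


_EVENT_COLUMNS = ["onset_s", "label", "kind", "tone_only", "sequence"]


def write_events(timeline: ProtocolTimeline, path) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset for e in timeline.events],
            "label": [e.label for e in timeline.events],
            "kind": [e.kind.value for e in timeline.events],
            "tone_only": [int(e.tone_only) for e in timeline.events],
            "sequence": [e.sequence.value for e in timeline.events],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path, baseline: float | None = None, isi: float | None = None) -> ProtocolTimeline:
    """Read an events table (TSV) back into a validated timeline.

    ``baseline`` and ``isi`` default to what the onsets imply: the first
    onset and the minimal inter-onset gap.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path}: missing column(s) {missing}")
    if len(df) != 16:
        raise ValueError(f"events file {path}: protocol requires 16 events, got {len(df)}")
    onsets = df["onset_s"].to_numpy(dtype=float)
    for i in range(1, len(onsets)):
        if not onsets[i] > onsets[i - 1]:
            raise ValueError(f"events file {path}: non-monotone onset at row {i + 1}")
    labels = df["label"].tolist()
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"events file {path}: duplicate label(s) {dup}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            events.append(
                StimulusEvent(
                    label=str(row.label),
                    kind=Kind(row.kind),
                    tone_only=bool(int(row.tone_only)),
                    sequence=Sequence(row.sequence),
                    onset=float(row.onset_s),
                    position=i + 1,
                )
            )
        except ValueError as exc:
            raise ValueError(f"events file {path}: row {i + 1}: {exc}") from exc
    if isi is None:
        isi = float(min(onsets[1:] - onsets[:-1]))
    if baseline is None:
        baseline = float(onsets[0])
    return ProtocolTimeline(baseline_duration=baseline, isi=isi, events=events)
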