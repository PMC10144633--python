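"""Keystroke-dynamics features from a prompted-sentence typing log.

A subject types a displayed sentence (48-54 characters including spaces);
the press/release event log yields four features:

KSR  keystroke count — total presses (all keys, including backspace) used
     to complete the string; extra presses are the fatigue signal
CRE  character errors — positionwise mismatches between the final typed
     string and the target (shorter string padded with a sentinel)
AVD  absolute difference between the ASCII code sums of typed and target;
     zero under any character transposition, so it separates "wrong
     characters" from "right characters in a hurry"
TST  total string time in seconds, first press to last release
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import InvalidParameterError, ParseError, ValidationError

__all__ = [
    "KeystrokeEvent",
    "KeystrokeLog",
    "KeystrokeFeatureVector",
    "parse_keystroke_log",
    "write_keystroke_log",
    "replay_typed_string",
    "keystroke_features",
    "KEYSTROKE_FEATURE_NAMES",
]

KEYSTROKE_FEATURE_NAMES = ("KSR", "CRE", "AVD", "TST")

#: Named keys accepted in the CSV ``key`` column besides single characters.
NAMED_KEYS = {"space": " ", "backspace": "\b"}


@dataclass(frozen=True)
class KeystrokeEvent:
    timestamp_ms: float
    kind: str  # "press" | "release"
    key: str  # single printable char, "space" or "backspace"

    def __post_init__(self):
        if self.kind not in ("press", "release"):
            raise ValidationError(f"event kind must be press/release, got {self.kind!r}")
        if len(self.key) != 1 and self.key not in NAMED_KEYS:
            raise ValidationError(f"unrecognised key {self.key!r}")


@dataclass(frozen=True)
class KeystrokeLog:
    """Ordered press/release events plus the sentence the subject was shown."""

    events: tuple[KeystrokeEvent, ...]
    target: str

    def __post_init__(self):
        if not self.target:
            raise ValidationError("target sentence must be non-empty")
        times = [e.timestamp_ms for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("event timestamps must be non-decreasing")
        down: set[str] = set()
        for e in self.events:
            if e.kind == "press":
                down.add(e.key)
            elif e.key not in down:
                raise ValidationError(
                    f"release of {e.key!r} at {e.timestamp_ms} ms without prior press"
                )
            else:
                down.discard(e.key)

    @property
    def presses(self) -> tuple[KeystrokeEvent, ...]:
        return tuple(e for e in self.events if e.kind == "press")


@dataclass(frozen=True)
class KeystrokeFeatureVector:
    KSR: float
    CRE: float
    AVD: float
    TST: float

    def as_array(self):
        import numpy as np

        return np.array(
            [getattr(self, n) for n in KEYSTROKE_FEATURE_NAMES], dtype=float
        )


def parse_keystroke_log(path: str | Path, target: str) -> KeystrokeLog:
    """Read a keystroke CSV (header ``timestamp_ms,kind,key``) and validate it."""
    path = Path(path)
    events: list[KeystrokeEvent] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty keystroke log") from None
        if [c.strip() for c in header] != ["timestamp_ms", "kind", "key"]:
            raise ParseError(f"{path}: bad header {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: expected 3 fields, got {len(row)}", lineno)
            ts, kind, key = row
            try:
                timestamp = float(ts)
            except ValueError:
                raise ParseError(f"{path}: bad timestamp {ts!r}", lineno) from None
            events.append(KeystrokeEvent(timestamp_ms=timestamp, kind=kind, key=key))
    if not events:
        raise ValidationError(f"{path}: no events in keystroke log")
    return KeystrokeLog(events=tuple(events), target=target)


def write_keystroke_log(log: KeystrokeLog, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["timestamp_ms", "kind", "key"])
        for e in log.events:
            writer.writerow([f"{e.timestamp_ms:.3f}", e.kind, e.key])


def replay_typed_string(events: Iterable[KeystrokeEvent]) -> str:
    """Reconstruct the final visible string from press events.

    Printable keys append a character; backspace removes the last one (a
    no-op on an empty buffer). Release events do not change the buffer.
    """
    buf: list[str] = []
    for e in events:
        if e.kind != "press":
            continue
        if e.key == "backspace":
            if buf:
                buf.pop()
        elif e.key == "space":
            buf.append(" ")
        else:
            buf.append(e.key)
    return "".join(buf)


def character_errors(typed: str, target: str) -> int:
    """Positionwise mismatch count; the shorter string is padded."""
    n = max(len(typed), len(target))
    return sum(
        1
        for i in range(n)
        if (typed[i] if i < len(typed) else None)
        != (target[i] if i < len(target) else None)
    )


def ascii_value_difference(typed: str, target: str) -> int:
    """|sum of ASCII codes of typed - sum for target|; transposition-invariant."""
    return abs(sum(ord(c) for c in typed) - sum(ord(c) for c in target))


def keystroke_features(log: KeystrokeLog) -> KeystrokeFeatureVector:
    """Compute (KSR, CRE, AVD, TST) from a validated log."""
    presses = log.presses
    if not presses:
        raise InvalidParameterError("log contains no press events")
    typed = replay_typed_string(log.events)
    releases = [e for e in log.events if e.kind == "release"]
    last = releases[-1].timestamp_ms if releases else log.events[-1].timestamp_ms
    tst = (last - presses[0].timestamp_ms) / 1000.0
    return KeystrokeFeatureVector(
        KSR=float(len(presses)),
        CRE=float(character_errors(typed, log.target)),
        AVD=float(ascii_value_difference(typed, log.target)),
        TST=tst,
    )
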