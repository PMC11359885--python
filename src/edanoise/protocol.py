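"""Stimulus protocols: timelines of dB-labelled noise events.

A protocol is the common clock shared by the signal generator and the
response extractor: each event marks the onset of a brief noise stimulus
(sound pressure level in dB SPL) followed by a relaxation period that lets
the electrodermal channels return to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["NoiseEvent", "StimulusProtocol", "build_protocol", "DEFAULT_LABELS"]

#: Conventional labels for the five-level graded protocol.
DEFAULT_LABELS = {
    70.0: "house electric fan",
    75.0: "industrial noise",
    80.0: "adult walking",
    85.0: "intensive care unit",
    90.0: "ambulance siren",
}


class ProtocolError(ValueError):
    """Invalid protocol construction."""


@dataclass(frozen=True)
class NoiseEvent:
    """One noise stimulus: onset (s from recording start), duration, level."""

    onset_s: float
    duration_s: float
    level_db: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ProtocolError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ProtocolError(f"duration_s must be > 0, got {self.duration_s}")
        if not 0.0 <= self.level_db <= 140.0:
            raise ProtocolError(
                f"level_db must lie in [0, 140] dB SPL, got {self.level_db}"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping sequence of noise events plus rest structure."""

    events: tuple[NoiseEvent, ...]
    pre_baseline_s: float
    post_event_rest_s: float
    total_s: float

    def __post_init__(self) -> None:
        ev = self.events
        for a, b in zip(ev, ev[1:]):
            tol = 1e-9 * max(1.0, abs(a.offset_s))  # float-accumulation slack
            if b.onset_s < a.offset_s - tol:
                raise ProtocolError(
                    f"events overlap or are unsorted: {a.offset_s} > {b.onset_s}"
                )
        if self.total_s <= 0:
            raise ProtocolError("total_s must be > 0")

    @property
    def levels_db(self) -> tuple[float, ...]:
        return tuple(e.level_db for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


def build_protocol(
    levels_db: Sequence[float],
    stim_s: float = 5.0,
    rest_s: float = 60.0,
    pre_baseline_s: float = 60.0,
    labels: Sequence[str] | None = None,
) -> StimulusProtocol:
    """Build an evenly spaced graded-noise protocol.

    Events are placed at ``pre_baseline_s``, then every ``stim_s + rest_s``
    seconds; the timeline ends after the last event's rest, so

        total_s = pre_baseline_s + n * (stim_s + rest_s).

    With the default five levels (70..90 dB), 5 s stimuli, 60 s relaxation
    and a 60 s pre-stimulus baseline this yields a 385 s recording.

    Parameters
    ----------
    levels_db : sequence of float
        Sound pressure level of each stimulus, in presentation order.
    stim_s, rest_s, pre_baseline_s : float
        Stimulus duration, post-stimulus relaxation, and initial rest (s).
    labels : sequence of str, optional
        One label per level; defaults to conventional names where known.
    """
    if len(levels_db) == 0:
        raise ProtocolError("levels_db must be nonempty")
    if stim_s <= 0:
        raise ProtocolError(f"stim_s must be > 0, got {stim_s}")
    if rest_s < 0 or pre_baseline_s < 0:
        raise ProtocolError("rest_s and pre_baseline_s must be >= 0")
    if labels is not None and len(labels) != len(levels_db):
        raise ProtocolError("labels must match levels_db in length")

    events = []
    for i, level in enumerate(levels_db):
        onset = pre_baseline_s + i * (stim_s + rest_s)
        label = (
            labels[i] if labels is not None else DEFAULT_LABELS.get(float(level), "")
        )
        events.append(
            NoiseEvent(
                onset_s=onset, duration_s=stim_s, level_db=float(level), label=label
            )
        )
    total = pre_baseline_s + len(events) * (stim_s + rest_s)
    return StimulusProtocol(
        events=tuple(events),
        pre_baseline_s=pre_baseline_s,
        post_event_rest_s=rest_s,
        total_s=total,
    )
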