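"""Discrete-event kernel: event queue, simulation clock, seeded random streams.

The simulation advances by dispatching events in nondecreasing time order;
ties are broken by an integer priority rank, then by insertion order (FIFO).
Every source of randomness draws from a named substream so that a replication
is a pure function of ``(scenario, master seed, replication index)`` and the
substreams stay statistically independent by construction.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: Dispatch ranks for simultaneous events.  Death outranks pathway progress so
#: that a patient whose death coincides with a pathway event dies first.
PRIORITY_DEATH = 0
PRIORITY_DEFAULT = 5


class Event:
    """Handle for a scheduled event; permits cancellation before dispatch."""

    __slots__ = ("time", "priority", "seq", "action", "cancelled")

    def __init__(self, time: float, priority: int, seq: int, action: Callable[[], None]):
        self.time = time
        self.priority = priority
        self.seq = seq
        self.action = action
        self.cancelled = False

    def cancel(self) -> None:
        self.cancelled = True
        self.action = None

    def __lt__(self, other: "Event") -> bool:
        return (self.time, self.priority, self.seq) < (other.time, other.priority, other.seq)


class EventQueue:
    """Priority queue of timed events with a monotone clock."""

    def __init__(self) -> None:
        self._heap: list[Event] = []
        self._seq = 0
        self.now = 0.0

    def __len__(self) -> int:
        return sum(not e.cancelled for e in self._heap)

    def schedule(self, time: float, action: Callable[[], None],
                 priority: int = PRIORITY_DEFAULT) -> Event:
        """Register ``action`` to run at ``time``; returns a cancellable handle."""
        if time < self.now:
            raise ValueError(
                f"cannot schedule event at t={time} before current clock t={self.now}")
        event = Event(time, priority, self._seq, action)
        self._seq += 1
        heapq.heappush(self._heap, event)
        return event

    def run_until(self, horizon: float) -> int:
        """Dispatch events with time <= horizon; returns the dispatch count."""
        dispatched = 0
        heap = self._heap
        while heap and heap[0].time <= horizon:
            event = heapq.heappop(heap)
            if event.cancelled:
                continue
            self.now = event.time
            event.action()
            dispatched += 1
        return dispatched


def _stream_key(label: str) -> int:
    return zlib.crc32(label.encode("ascii"))


class RngRegistry:
    """Named, independent random substreams for one replication.

    Each substream is a :class:`numpy.random.Generator` seeded from the tuple
    ``(master seed, replication index, crc32(label))`` via ``SeedSequence``,
    so distinct labels and distinct replications never share a stream, and the
    same tuple always reproduces the same draws.

    The ``geography`` stream may be pinned to replication 0 so the hospital
    landscape stays fixed across replications while everything else varies.
    """

    STREAMS = ("arrivals", "profiles", "geography", "behavior",
               "biopsy", "delays", "mortality")

    def __init__(self, master_seed: int, replication: int,
                 fixed_geography: bool = False):
        if replication < 0:
            raise ValueError("replication index must be >= 0")
        self.master_seed = int(master_seed)
        self.replication = int(replication)
        self._generators: dict[str, np.random.Generator] = {}
        for label in self.STREAMS:
            rep = 0 if (label == "geography" and fixed_geography) else self.replication
            seq = np.random.SeedSequence(
                entropy=(self.master_seed, rep, _stream_key(label)))
            self._generators[label] = np.random.default_rng(seq)

    def __getattr__(self, label: str) -> np.random.Generator:
        try:
            return self.__dict__["_generators"][label]
        except KeyError:
            raise AttributeError(f"no stream named {label!r}; have {self.STREAMS}")


@dataclass(frozen=True)
class ReplicationSpec:
    """Controls one replication: index, horizon and warm-up window."""

    replication: int = 0
    horizon_days: float = 2000.0
    warmup_days: float = 0.0

    def __post_init__(self) -> None:
        if self.replication < 0:
            raise ValueError("replication index must be >= 0")
        if not (self.horizon_days >= self.warmup_days >= 0):
            raise ValueError("require horizon >= warmup >= 0")
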