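"""Simulated distributed runtime for block-level bitonic sorting.

Models ``p`` isolated workers, each owning one block of records.  Workers may
read only their own block; every cross-worker byte travels through an
explicit :class:`Mailbox` whose message counts and approximate payload sizes
are instrumented — the message-passing point-to-point contract, stepped
synchronously so a whole network stage completes before the next begins.

The parallel sort is the block analogue of the comparator network: each
worker first sorts its block locally, then every comparator of the p-input
bitonic network is replaced by a *compare-split* between the two workers it
connects.  In a compare-split both workers exchange their full sorted blocks
of size m, merge to 2m records, and each keeps one half — the "low" side
(by comparator direction) the lower m, the other the upper m.  For p = 2^q
workers the schedule runs q(q+1)/2 compare-split steps, after which the
rank-order concatenation of blocks is globally sorted.

Unequal block sizes are evened out beforehand by sentinel padding: sentinel
records compare greater than every real key, collect at the top of the
global order, and are stripped before any output is written.
"""

from __future__ import annotations

import json
from collections import deque
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, Iterator, List, Optional, Sequence, Tuple

from .sortnet import Direction, build_sorting_network

__all__ = [
    "SENTINEL",
    "Mailbox",
    "Runtime",
    "WorkerBlock",
    "IsolationError",
    "local_sort",
    "compare_split",
    "parallel_bitonic_sort",
    "pad_to_uniform",
    "strip_sentinels",
    "payload_size",
]


class _Sentinel:
    """Padding record comparing greater than any real key."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "<SENTINEL>"


#: The shared padding record used by :func:`pad_to_uniform`.
SENTINEL = _Sentinel()


def _effective_key(key: Optional[Callable[[Any], Any]]) -> Callable[[Any], Tuple[int, Any]]:
    # Sentinels sort strictly after every real record regardless of key type.
    def eff(item: Any) -> Tuple[int, Any]:
        if item is SENTINEL:
            return (1, ())
        return (0, key(item) if key is not None else item)

    return eff


def payload_size(payload: Any) -> int:
    """Approximate byte size of a message payload.

    Uses ``line_len`` where records carry one (SAM routing records), raw
    length for bytes, recursion for containers, and ``len(str(...))``
    otherwise.  Informational instrumentation only.
    """
    if payload is None or payload is SENTINEL:
        return 0
    if isinstance(payload, (bytes, bytearray)):
        return len(payload)
    line_len = getattr(payload, "line_len", None)
    if isinstance(line_len, int):
        return line_len
    if isinstance(payload, (list, tuple)):
        return sum(payload_size(x) for x in payload)
    return len(str(payload))


class IsolationError(RuntimeError):
    """A worker touched another worker's block without a message."""


class Mailbox:
    """FIFO point-to-point message queues with instrumentation.

    Delivery preserves per-(source, dest) ordering.  ``messages`` and
    ``bytes`` count all traffic ever sent.
    """

    def __init__(self) -> None:
        self._queues: Dict[Tuple[int, int], deque] = {}
        self.messages = 0
        self.bytes = 0

    def send(self, source: int, dest: int, payload: Any) -> None:
        self._queues.setdefault((source, dest), deque()).append(payload)
        self.messages += 1
        self.bytes += payload_size(payload)

    def receive(self, source: int, dest: int) -> Any:
        queue = self._queues.get((source, dest))
        if not queue:
            raise LookupError(f"no pending message from rank {source} to rank {dest}")
        return queue.popleft()

    def pending(self) -> int:
        return sum(len(q) for q in self._queues.values())


class Runtime:
    """Synchronous-stepped worker pool: mailbox, rank scoping, counters."""

    def __init__(self, p: int, audit: bool = True) -> None:
        if p < 1:
            raise ValueError(f"worker count must be >= 1, got {p}")
        self.p = p
        self.audit = audit
        self.mailbox = Mailbox()
        self.active_rank: Optional[int] = None
        self.compare_split_steps = 0  # parallel network stages executed
        self.compare_splits = 0  # individual block compare-splits
        self.bruck_rounds = 0

    @contextmanager
    def as_rank(self, rank: int) -> Iterator[None]:
        """Scope execution to one worker; block reads are audited inside."""
        if not 0 <= rank < self.p:
            raise ValueError(f"rank {rank} out of range for p={self.p}")
        previous, self.active_rank = self.active_rank, rank
        try:
            yield
        finally:
            self.active_rank = previous

    def report(self) -> Dict[str, int]:
        return {
            "p": self.p,
            "messages": self.mailbox.messages,
            "bytes": self.mailbox.bytes,
            "compare_split_steps": self.compare_split_steps,
            "compare_splits": self.compare_splits,
            "bruck_rounds": self.bruck_rounds,
        }

    def report_json(self) -> str:
        return json.dumps(self.report(), indent=2, sort_keys=True)


@dataclass
class WorkerBlock:
    """Rank-local list of records owned by one simulated processor.

    Reading ``items`` while another rank is active (and auditing is on)
    raises :class:`IsolationError`; all cross-worker movement must go
    through the runtime's mailbox.
    """

    rank: int
    _items: List[Any] = field(default_factory=list)
    runtime: Optional[Runtime] = None

    @property
    def items(self) -> List[Any]:
        rt = self.runtime
        if rt is not None and rt.audit and rt.active_rank not in (None, self.rank):
            raise IsolationError(
                f"rank {rt.active_rank} attempted a direct read of rank {self.rank}'s block"
            )
        return self._items

    @items.setter
    def items(self, value: List[Any]) -> None:
        rt = self.runtime
        if rt is not None and rt.audit and rt.active_rank not in (None, self.rank):
            raise IsolationError(
                f"rank {rt.active_rank} attempted a direct write of rank {self.rank}'s block"
            )
        self._items = list(value)

    @property
    def m(self) -> int:
        return len(self._items)


def local_sort(block: WorkerBlock, key: Optional[Callable[[Any], Any]] = None) -> WorkerBlock:
    """Stable in-place sort of one worker's block by the module-wide key."""
    eff = _effective_key(key)
    rt = block.runtime
    if rt is not None:
        with rt.as_rank(block.rank):
            block.items = sorted(block.items, key=eff)
    else:
        block.items = sorted(block.items, key=eff)
    return block


def _merge_sorted(a: Sequence[Any], b: Sequence[Any], eff: Callable[[Any], Any]) -> List[Any]:
    # Two-pointer merge; own items come first on ties so the operation is
    # deterministic given the (source, dest) roles.
    out: List[Any] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if eff(b[j]) < eff(a[i]):
            out.append(b[j])
            j += 1
        else:
            out.append(a[i])
            i += 1
    out.extend(a[i:])
    out.extend(b[j:])
    return out


def compare_split(
    low_worker: WorkerBlock,
    high_worker: WorkerBlock,
    direction: Direction,
    runtime: Runtime,
    key: Optional[Callable[[Any], Any]] = None,
) -> Tuple[WorkerBlock, WorkerBlock]:
    """Block-level compare-exchange between two workers.

    Each worker sends its full sorted block to the other through the
    mailbox (exactly two messages), merges the 2m records, and keeps one
    half: with an INCREASING comparator the lower-index worker keeps the
    lower m records, with DECREASING the upper m.  Both kept halves are
    sorted.
    """
    if low_worker.m != high_worker.m:
        raise ValueError(
            f"compare-split requires equal block sizes, got {low_worker.m} and {high_worker.m}"
        )
    eff = _effective_key(key)
    for blk in (low_worker, high_worker):
        with runtime.as_rank(blk.rank):
            if any(eff(blk.items[i + 1]) < eff(blk.items[i]) for i in range(blk.m - 1)):
                raise ValueError(f"rank {blk.rank} block is not sorted before compare-split")

    m = low_worker.m
    with runtime.as_rank(low_worker.rank):
        runtime.mailbox.send(low_worker.rank, high_worker.rank, list(low_worker.items))
    with runtime.as_rank(high_worker.rank):
        runtime.mailbox.send(high_worker.rank, low_worker.rank, list(high_worker.items))

    with runtime.as_rank(low_worker.rank):
        received = runtime.mailbox.receive(high_worker.rank, low_worker.rank)
        merged = _merge_sorted(low_worker.items, received, eff)
        low_worker.items = merged[:m] if direction is Direction.INCREASING else merged[m:]
    with runtime.as_rank(high_worker.rank):
        received = runtime.mailbox.receive(low_worker.rank, high_worker.rank)
        merged = _merge_sorted(high_worker.items, received, eff)
        high_worker.items = merged[m:] if direction is Direction.INCREASING else merged[:m]

    runtime.compare_splits += 1
    return low_worker, high_worker


def parallel_bitonic_sort(
    blocks: List[WorkerBlock],
    runtime: Optional[Runtime] = None,
    key: Optional[Callable[[Any], Any]] = None,
) -> List[WorkerBlock]:
    """Sort the union of all blocks so their rank-order concatenation is
    globally sorted.

    Requires p = 2^q workers with equal block sizes (pad first with
    :func:`pad_to_uniform`).  Runs the p-input bitonic network with every
    comparator replaced by a compare-split; ``runtime.compare_split_steps``
    counts the q(q+1)/2 parallel stages.  p = 1 degenerates to a local sort
    with zero compare-split steps.
    """
    p = len(blocks)
    if p < 1 or p & (p - 1):
        raise ValueError(f"worker count must be a power of two, got {p}")
    if runtime is None:
        runtime = Runtime(p)
    for blk in blocks:
        blk.runtime = runtime

    for blk in blocks:
        local_sort(blk, key=key)
    if p == 1:
        return blocks

    sizes = {blk.m for blk in blocks}
    if len(sizes) > 1:
        raise ValueError(f"parallel sort requires equal block sizes, got {sorted(sizes)}")

    network = build_sorting_network(p)
    for stage in network.stages:
        for comp in stage:
            compare_split(blocks[comp.index_a], blocks[comp.index_b], comp.direction, runtime, key=key)
        runtime.compare_split_steps += 1
    return blocks


def pad_to_uniform(blocks: List[WorkerBlock], sentinel: Any = SENTINEL) -> Tuple[List[WorkerBlock], int]:
    """Pad every block with sentinels up to the largest block size.

    Returns ``(blocks, pad_count)``; the caller strips exactly
    ``pad_count`` sentinels after sorting (they occupy the top of the
    global order).
    """
    if not blocks:
        return blocks, 0
    target = max(blk.m for blk in blocks)
    pad_count = 0
    for blk in blocks:
        missing = target - blk.m
        if missing:
            blk.items = blk.items + [sentinel] * missing
            pad_count += missing
    return blocks, pad_count


def strip_sentinels(blocks: List[WorkerBlock], sentinel: Any = SENTINEL) -> List[WorkerBlock]:
    """Remove padding records, leaving each block's real records in order."""
    for blk in blocks:
        blk.items = [item for item in blk.items if item is not sentinel]
    return blocks
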