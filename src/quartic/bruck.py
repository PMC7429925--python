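"""All-to-all personalized exchange over the mailbox contract.

Every worker holds an :class:`Outbox` of p payload slots, slot d being the
payload destined for rank d.  The naive exchange delivers each slot
directly — p(p-1) pairwise messages — and serves as the correctness
reference.  The Bruck scheme completes the same exchange in ceil(log2 p)
communication rounds:

1. *Rotation*: rank i relabels its slots so slot j holds the payload for
   rank (i + j) mod p; slot 0 is its own payload.
2. *Exchange*: in round r, rank i sends to (i + 2^r) mod p every slot whose
   index has bit r set, and replaces those slots with what it receives from
   (i - 2^r) mod p.  A slot of index j is forwarded once per set bit of j,
   for a total displacement of j ranks.
3. *Inverse rotation*: after the rounds, rank d holds in slot j the payload
   sent by rank (d - j) mod p; relabelling by source yields the inbox.

Messages carry (slot index, payload) frames so payloads forwarded through
intermediate ranks stay unambiguous.  Intra-slot payload order is preserved
end to end, so the exchange is deterministic.
"""

from __future__ import annotations

from typing import Any, Dict, List, Optional, Sequence

from .pengine import Runtime

__all__ = ["Outbox", "bruck_all_to_all", "naive_all_to_all"]

# An Outbox is one worker's list of p payload lists; payloads are opaque
# ordered lists of records/bytes.
Outbox = List[List[Any]]


def _check_outboxes(outboxes: Sequence[Outbox], p: int) -> None:
    if len(outboxes) != p:
        raise ValueError(f"expected {p} outboxes, got {len(outboxes)}")
    for rank, outbox in enumerate(outboxes):
        if len(outbox) != p:
            raise ValueError(
                f"rank {rank} outbox has {len(outbox)} destination slots, expected {p}"
            )


def naive_all_to_all(
    outboxes: Sequence[Outbox], p: int, runtime: Optional[Runtime] = None
) -> List[Outbox]:
    """Direct pairwise delivery; the correctness oracle for any p >= 1.

    Returns inboxes with ``inboxes[j][i] == outboxes[i][j]``.
    """
    _check_outboxes(outboxes, p)
    if runtime is None:
        runtime = Runtime(p)
    inboxes: List[Outbox] = [[[] for _ in range(p)] for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i == j:
                inboxes[j][i] = list(outboxes[i][j])
            else:
                runtime.mailbox.send(i, j, list(outboxes[i][j]))
    for j in range(p):
        for i in range(p):
            if i != j:
                inboxes[j][i] = runtime.mailbox.receive(i, j)
    return inboxes


def bruck_all_to_all(
    outboxes: Sequence[Outbox], p: int, runtime: Optional[Runtime] = None
) -> List[Outbox]:
    """Bruck all-to-all: identical result to :func:`naive_all_to_all` in
    exactly ceil(log2 p) mailbox rounds.

    Requires p = 2^q.  ``runtime.bruck_rounds`` accumulates the measured
    round count; all traffic goes through the runtime's mailbox.
    """
    _check_outboxes(outboxes, p)
    if p & (p - 1):
        raise ValueError(f"Bruck exchange requires a power-of-two worker count, got {p}")
    if runtime is None:
        runtime = Runtime(p)
    if p == 1:
        return [[list(outboxes[0][0])]]

    q = p.bit_length() - 1

    # Phase 1 — local rotation: slot j holds the payload for rank (i+j) mod p.
    slots: List[List[List[Any]]] = [
        [list(outboxes[i][(i + j) % p]) for j in range(p)] for i in range(p)
    ]

    # Phase 2 — q exchange rounds over the mailbox.
    for r in range(q):
        hop = 1 << r
        for i in range(p):
            frames = [(j, slots[i][j]) for j in range(p) if j & hop]
            runtime.mailbox.send(i, (i + hop) % p, frames)
        for i in range(p):
            frames = runtime.mailbox.receive((i - hop) % p, i)
            for j, payload in frames:
                slots[i][j] = payload
        runtime.bruck_rounds += 1

    # Phase 3 — inverse rotation: at rank d, slot j came from rank (d-j) mod p.
    inboxes: List[Outbox] = [
        [slots[d][(d - src) % p] for src in range(p)] for d in range(p)
    ]
    return inboxes
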