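"""Sequential bitonic-sort building blocks.

A *bitonic sequence* first increases then decreases (non-strictly), or is a
cyclic shift of such a sequence.  The *bitonic split* pairs element ``i`` of
the first half with element ``i + n/2`` of the second half, taking the
elementwise minimum into a low half and the maximum into a high half::

    s1 = <min(a_0, a_{n/2}), min(a_1, a_{n/2+1}), ..., min(a_{n/2-1}, a_{n-1})>
    s2 = <max(a_0, a_{n/2}), max(a_1, a_{n/2+1}), ..., max(a_{n/2-1}, a_{n-1})>

Both halves are again bitonic and every element of ``s1`` is <= every element
of ``s2``, so log2(n) recursive splits fully sort a bitonic input (the
*bitonic merge*, written BM_n+ for increasing and BM_n- for decreasing
order).  An arbitrary input of length n = 2^k is sorted by first building a
bitonic sequence with alternating increasing/decreasing merges of growing
width, then applying one final increasing merge of the full width.

The network is materialised explicitly as a staged schedule of two-input
comparators rather than executed recursively, so parallel depth and
comparator counts are inspectable: the full network has k(k+1)/2 parallel
steps of n/2 independent comparators each.

Comparators swap only on a *strict* order violation, so equal keys never
move: the network is well-behaved on the duplicate coordinates that are
common in genomic data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple, TypeVar

K = TypeVar("K")

__all__ = [
    "Direction",
    "ComparatorStep",
    "Network",
    "is_bitonic",
    "bitonic_split",
    "bitonic_merge",
    "build_sorting_network",
    "apply_network",
]


class Direction(enum.Enum):
    """Comparator orientation: INCREASING routes the smaller value to the
    lower index."""

    INCREASING = "increasing"
    DECREASING = "decreasing"

    def flipped(self) -> "Direction":
        return Direction.DECREASING if self is Direction.INCREASING else Direction.INCREASING


@dataclass(frozen=True)
class ComparatorStep:
    """One compare-exchange edge of a sorting network.

    ``index_a < index_b`` always; ``direction`` says which endpoint receives
    the smaller value (INCREASING: the lower index).
    """

    index_a: int
    index_b: int
    direction: Direction

    def __post_init__(self) -> None:
        if not 0 <= self.index_a < self.index_b:
            raise ValueError(
                f"comparator requires 0 <= index_a < index_b, got ({self.index_a}, {self.index_b})"
            )


@dataclass
class Network:
    """A data-independent comparator schedule.

    ``stages`` is an ordered list of parallel steps; comparators within one
    step touch disjoint indices and may run concurrently.
    """

    n: int
    stages: List[List[ComparatorStep]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, stage in enumerate(self.stages):
            seen: set[int] = set()
            for step in stage:
                if step.index_b >= self.n:
                    raise ValueError(f"stage {s}: comparator index {step.index_b} out of range for n={self.n}")
                for idx in (step.index_a, step.index_b):
                    if idx in seen:
                        raise ValueError(f"stage {s}: index {idx} appears twice")
                    seen.add(idx)

    @property
    def depth(self) -> int:
        """Number of parallel steps."""
        return len(self.stages)

    @property
    def comparator_count(self) -> int:
        return sum(len(stage) for stage in self.stages)

    def dump(self) -> str:
        """Plain-text schedule, one ``stage s: (a,b,dir) ...`` line per stage."""
        lines = []
        for s, stage in enumerate(self.stages):
            edges = " ".join(
                f"({c.index_a},{c.index_b},{'+' if c.direction is Direction.INCREASING else '-'})"
                for c in stage
            )
            lines.append(f"stage {s}: {edges}")
        return "\n".join(lines)


def _is_ascending_descending(values: Sequence[K]) -> bool:
    """True iff values are non-strictly increasing then non-strictly decreasing."""
    n = len(values)
    i = 0
    while i + 1 < n and values[i] <= values[i + 1]:
        i += 1
    while i + 1 < n and values[i] >= values[i + 1]:
        i += 1
    return i == n - 1


def is_bitonic(seq: Sequence[K]) -> bool:
    """True iff some cyclic shift of ``seq`` is increasing-then-decreasing.

    Empty and singleton sequences are bitonic.  Keys only need a total
    order; ties are allowed throughout.
    """
    values = list(seq)
    n = len(values)
    if n <= 2:
        return True
    return any(_is_ascending_descending(values[s:] + values[:s]) for s in range(n))


def _require_power_of_two(n: int, what: str = "length") -> int:
    if n < 1 or n & (n - 1):
        raise ValueError(f"{what} must be a power of two, got {n}")
    return n.bit_length() - 1


def bitonic_split(seq: Sequence[K]) -> Tuple[List[K], List[K]]:
    """Split a bitonic sequence into a low and a high bitonic half.

    Returns ``(s1, s2)`` with ``s1[i] = min(a_i, a_{i+n/2})`` and
    ``s2[i] = max(a_i, a_{i+n/2})``.  Both halves are bitonic and
    ``max(s1) <= min(s2)``.

    Raises :class:`ValueError` on odd length or non-bitonic input.
    """
    values = list(seq)
    n = len(values)
    if n % 2:
        raise ValueError(f"bitonic split requires an even length, got {n}")
    if not is_bitonic(values):
        raise ValueError("bitonic split requires a bitonic input sequence")
    half = n // 2
    s1 = [min(values[i], values[i + half]) for i in range(half)]
    s2 = [max(values[i], values[i + half]) for i in range(half)]
    return s1, s2


def bitonic_merge(seq: Sequence[K], direction: Direction = Direction.INCREASING) -> Tuple[List[K], int]:
    """Fully sort a bitonic sequence by recursive splitting.

    Returns ``(sorted_values, split_levels)`` where ``split_levels`` counts
    the recursion depth actually performed: exactly log2(n) for n = 2^k.

    Raises :class:`ValueError` for non-power-of-two lengths.
    """
    values = list(seq)
    _require_power_of_two(len(values))

    def merge(vals: List[K]) -> Tuple[List[K], int]:
        if len(vals) == 1:
            return vals, 0
        s1, s2 = bitonic_split(vals)
        lo, d1 = merge(s1)
        hi, d2 = merge(s2)
        return lo + hi, 1 + max(d1, d2)

    if direction is Direction.INCREASING:
        return merge(values)
    # A reversed bitonic sequence is bitonic; merge increasing then reverse.
    merged, depth = merge(values)
    return merged[::-1], depth


def build_sorting_network(n: int) -> Network:
    """Construct the full bitonic sorting network for ``n = 2^k`` inputs.

    The schedule first turns the input into a bitonic sequence with
    alternating increasing/decreasing merges of width 2, 4, ..., n/2, then
    applies the final increasing merge of width n.  Merge phase of width
    2^i contributes i parallel steps, so the network has k(k+1)/2 steps of
    n/2 comparators each.
    """
    k = _require_power_of_two(n, "network size")
    if k < 1:
        raise ValueError("network size must be at least 2")
    stages: List[List[ComparatorStep]] = []
    size = 2
    while size <= n:
        stride = size // 2
        while stride >= 1:
            stage: List[ComparatorStep] = []
            for i in range(n):
                j = i ^ stride
                if j > i:
                    direction = Direction.INCREASING if (i & size) == 0 else Direction.DECREASING
                    stage.append(ComparatorStep(i, j, direction))
            stages.append(stage)
            stride //= 2
        size *= 2
    return Network(n=n, stages=stages)


def apply_network(seq: Sequence[K], net: Network) -> List[K]:
    """Run every compare-exchange of ``net`` over ``seq`` in stage order.

    Swaps only on strict order violation, so positions of equal keys are
    never disturbed by a comparator.
    """
    values = list(seq)
    if len(values) != net.n:
        raise ValueError(f"sequence length {len(values)} does not match network size {net.n}")
    for stage in net.stages:
        for c in stage:
            a, b = values[c.index_a], values[c.index_b]
            if c.direction is Direction.INCREASING:
                if b < a:
                    values[c.index_a], values[c.index_b] = b, a
            else:
                if a < b:
                    values[c.index_a], values[c.index_b] = b, a
    return values
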