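import random

import pytest

from quartic.fixtures import FixtureSpec, generate_sam


def random_bitonic(rng: random.Random, n: int, lo: int = 0, hi: int = 100) -> list:
    """Random bitonic sequence: ascending subset + descending complement,
    under a random cyclic rotation.  Duplicates allowed."""
    values = [rng.randint(lo, hi) for _ in range(n)]
    split = rng.randint(0, n)
    rising = sorted(values[:split])
    falling = sorted(values[split:], reverse=True)
    seq = rising + falling
    shift = rng.randrange(n) if n else 0
    return seq[shift:] + seq[:shift]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260929)


@pytest.fixture
def sam_file(tmp_path):
    """Factory writing a seeded synthetic SAM to disk; returns (path, text)."""

    def make(name="input.sam", **spec_kwargs):
        spec = FixtureSpec(**spec_kwargs)
        text = generate_sam(spec)
        path = tmp_path / name
        path.write_text(text)
        return str(path), text

    return make
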