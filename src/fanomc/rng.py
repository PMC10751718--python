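"""Counter-based random streams for reproducible, batch-invariant histories.

Every particle history ``h`` of a run with base seed ``s`` owns an independent
xorshift128+ stream whose two state words are derived from ``(s, h)`` with
splitmix64.  The splitting rule is::

    k  = splitmix64(h + 0x632BE59BD9B4E019)
    m  = splitmix64(s) ^ k
    s0 = splitmix64(m)
    s1 = splitmix64(m + 0x9E3779B97F4A7C15)

so the stream consumed by a history depends only on ``(s, h)``, never on how
histories are grouped into batches.  The same jitted primitives back both the
vectorized engine and the pure-python reference transport, which makes the two
paths draw bit-identical random sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def splitmix64(x):
    """One splitmix64 output for a uint64 input (also advances-by-hash)."""
    z = x + _U(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


@njit(cache=True)
def substream_state(seed, history):
    """Derive the 2-word xorshift128+ state of history ``history``."""
    k = splitmix64(_U(history) + _U(0x632BE59BD9B4E019))
    m = splitmix64(_U(seed)) ^ k
    s0 = splitmix64(m)
    s1 = splitmix64(m + _U(0x9E3779B97F4A7C15))
    if s0 == _U(0) and s1 == _U(0):
        s1 = _U(1)
    state = np.empty(2, dtype=np.uint64)
    state[0] = s0
    state[1] = s1
    return state


@njit(cache=True)
def next_uint64(state):
    x = state[0]
    y = state[1]
    state[0] = y
    x ^= x << _U(23)
    state[1] = x ^ y ^ (x >> _U(17)) ^ (y >> _U(26))
    return state[1] + y


@njit(cache=True)
def uniform(state):
    """Uniform double in [0, 1) consuming one 64-bit draw."""
    return (next_uint64(state) >> _U(11)) * _INV_2_53


def derive_seed(base_seed: int, index: int) -> int:
    """A 31-bit child seed for independent sub-tasks (e.g. sweep cells)."""
    return int(splitmix64(_U(int(base_seed)) ^ splitmix64(_U(int(index))))) & 0x7FFFFFFF


class RandomStream:
    """Python-side view of one history's stream (shares the jitted core)."""

    def __init__(self, seed: int, history: int = 0):
        self.seed = int(seed)
        self.history = int(history)
        self.state = substream_state(self.seed, self.history)

    def uniform(self) -> float:
        return float(uniform(self.state))

    def spawn(self, history: int) -> "RandomStream":
        return RandomStream(self.seed, history)
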