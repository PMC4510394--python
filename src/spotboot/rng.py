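"""Minimal-standard multiplicative linear congruential generator.

The generator is the classic Lehmer/Park–Miller recurrence

    x_{i+1} = 16807 * x_i  mod  (2**31 - 1)

implemented with Schrage's factorization so every intermediate fits in a
signed 32-bit integer.  All resampling in this package flows through this
generator, which makes every bootstrap run reproducible bit-for-bit from a
single integer seed on any platform.

Uniform deviates are ``state / m`` and therefore lie strictly inside
``(0, 1)``: the state is never 0 (0 is absorbing) and never ``m``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MULTIPLIER", "MODULUS", "MinimalStandardRNG", "lcg_next", "InvalidStateError"]

MULTIPLIER = 16807
MODULUS = 2**31 - 1  # Mersenne prime 2147483647

# Schrage factorization m = a*q + r with r < q
_Q = MODULUS // MULTIPLIER  # 127773
_R = MODULUS % MULTIPLIER   # 2836

# leapfrog width for vectorized batch generation
_LEAP = 1024
_LEAP_MULT = pow(MULTIPLIER, _LEAP, MODULUS)


class InvalidStateError(ValueError):
    """Raised for a seed/state outside [1, m-1]."""


def _schrage_step(state: int) -> int:
    hi, lo = divmod(state, _Q)
    state = MULTIPLIER * lo - _R * hi
    if state <= 0:
        state += MODULUS
    return state


def lcg_next(state: int) -> tuple[int, float]:
    """Advance the recurrence one step.

    Returns ``(new_state, uniform)`` with ``uniform = new_state / m`` in
    the open interval (0, 1).
    """
    if not 1 <= state <= MODULUS - 1:
        raise InvalidStateError(f"LCG state must be in [1, {MODULUS - 1}], got {state}")
    new_state = _schrage_step(state)
    return new_state, new_state / MODULUS


class MinimalStandardRNG:
    """Stateful wrapper around the minimal-standard recurrence.

    Parameters
    ----------
    seed:
        Initial state, an integer in ``[1, 2**31 - 2]``.  Seed 0 is
        rejected (it is an absorbing state of a multiplicative
        congruential generator), as is any value >= m.
    """

    def __init__(self, seed: int = 1):
        seed = int(seed)
        if not 1 <= seed <= MODULUS - 1:
            raise InvalidStateError(
                f"seed must be an integer in [1, {MODULUS - 1}], got {seed}"
            )
        self._state = seed
        self._consumed = 0

    @property
    def state(self) -> int:
        return self._state

    @property
    def consumed(self) -> int:
        """Number of generator steps taken since construction."""
        return self._consumed

    def step(self) -> int:
        """Advance one step and return the new integer state."""
        self._state = _schrage_step(self._state)
        self._consumed += 1
        return self._state

    def uniform(self) -> float:
        """One uniform deviate in (0, 1); consumes exactly one step."""
        return self.step() / MODULUS

    def uniforms(self, k: int) -> np.ndarray:
        """``k`` consecutive uniform deviates as a float64 array.

        Bit-identical to calling :meth:`uniform` ``k`` times.  Internally
        uses a leapfrog decomposition: the first ``L`` states are produced
        by the scalar Schrage step, then each further block of ``L``
        states is the previous block times ``a**L mod m``, a single
        vectorized 64-bit multiply-mod (16807 * (2**31) < 2**63, so the
        products are exact).
        """
        k = int(k)
        if k < 0:
            raise ValueError("k must be >= 0")
        if k == 0:
            return np.empty(0, dtype=np.float64)
        if k <= _LEAP:
            out = np.empty(k, dtype=np.int64)
            s = self._state
            for i in range(k):
                s = _schrage_step(s)
                out[i] = s
        else:
            nrows = -(-k // _LEAP)
            out = np.empty((nrows, _LEAP), dtype=np.int64)
            s = self._state
            row = out[0]
            for i in range(_LEAP):
                s = _schrage_step(s)
                row[i] = s
            for j in range(1, nrows):
                np.mod(out[j - 1] * _LEAP_MULT, MODULUS, out=out[j])
            out = out.reshape(-1)[:k]
        self._state = int(out[-1])
        self._consumed += k
        return out / MODULUS

    def sample_indices(self, n: int, k: int) -> np.ndarray:
        """``k`` resampling indices uniform on ``{0, ..., n-1}``.

        Index ``j`` is ``floor(u_j * n)``, clamped to ``n - 1`` in the
        (floating-point) event that ``u_j * n`` rounds up to ``n``.
        Consumes exactly ``k`` generator steps.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if k < 1:
            raise ValueError("k must be >= 1")
        u = self.uniforms(k)
        idx = (u * n).astype(np.int64)
        np.minimum(idx, n - 1, out=idx)
        return idx
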