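"""Counter-style random streams keyed by (seed, year, purpose).

Scenario pairing uses common random numbers: the baseline and counterfactual
runs of one replicate share a :class:`RandomStreams` key, so the uniform
variate consumed by individual *i* for purpose *p* in year *y* is identical
in both runs. Streams are keyed rather than sequential so that a divergence
in one purpose (e.g. an extra birth) cannot shift every later draw.
"""
from __future__ import annotations

import numpy as np

PURPOSES: dict[str, int] = {
    "init": 0,
    "mortality": 1,
    "births": 2,
    "newborn": 3,
    "contract_t2dm": 4,
    "contract_chronic_liver_disease": 5,
    "contract_liver_cancer": 6,
    "death_chronic_liver_disease": 7,
    "death_liver_cancer": 8,
}


class RandomStreams:
    """Deterministic per-(year, purpose) uniform streams under one seed.

    Parameters
    ----------
    seed:
        Non-negative integer master key for this replicate.
    salt:
        Extra key component; a nonzero salt decouples two scenario runs
        (used when common random numbers are switched off).
    """

    def __init__(self, seed: int, salt: int = 0):
        if seed < 0 or salt < 0:
            raise ValueError("seed and salt must be non-negative integers")
        self.seed = int(seed)
        self.salt = int(salt)

    def generator(self, year: int, purpose: str) -> np.random.Generator:
        pid = PURPOSES[purpose]
        ss = np.random.SeedSequence([self.seed, self.salt, int(year), pid])
        return np.random.default_rng(ss)

    def uniforms(self, year: int, purpose: str, n: int) -> np.ndarray:
        """Uniform(0,1) array of length ``n``, index-aligned with individual ids."""
        return self.generator(year, purpose).random(n)


def spawn_replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit replicate seeds from a master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31 - 1)) for s in state]
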