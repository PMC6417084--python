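"""Deterministic fan-out of one global seed to per-stage seeds.

Stage seeds are derived with ``numpy.random.SeedSequence(seed, spawn_key=(k,))``
where ``k`` is a fixed per-stage counter; the derived integer is reduced below
2**31 so it can be handed to any library RNG.
"""

from __future__ import annotations

import numpy as np

# fixed stage counters; new stages append, existing ones never renumber
STAGES = {
    "counts": 0,
    "phenotypes": 1,
    "forest": 2,
    "folds": 3,
    "learner": 4,
    "permutation": 5,
}


def stage_seed(global_seed: int, stage: str, rep: int = 0) -> int:
    """Return a deterministic 31-bit seed for a named pipeline stage."""
    key = STAGES[stage] if stage in STAGES else abs(hash(stage)) % 1000
    ss = np.random.SeedSequence(int(global_seed), spawn_key=(key, int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(global_seed: int, stage: str, rep: int = 0) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage, rep))
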