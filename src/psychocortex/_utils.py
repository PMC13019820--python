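"""Small shared helpers: seed handling and input validation."""

from __future__ import annotations

import numpy as np

# Fixed per-stage offsets so one global seed yields reproducible,
# independent streams for every pipeline stage.
STAGE_OFFSETS = {
    "atlas": 101,
    "covariance": 211,
    "morphometry_ct": 307,
    "morphometry_sa": 311,
    "behavior": 401,
    "covariates": 409,
    "split": 503,
    "ridge_cv": 509,
    "permutation": 601,
    "spin": 701,
}

_MOD = 2**31 - 1


def child_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global one by a fixed offset."""
    if stage not in STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(seed) * 7919 + STAGE_OFFSETS[stage]) % _MOD


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def check_finite(name: str, arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr
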