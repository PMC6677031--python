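"""Deterministic random-stream fan-out.

A single integer seed drives the whole pipeline.  Each stage (and each
subject within a stage) gets its own independent stream derived through
``numpy.random.SeedSequence`` spawn keys, so toggling one stage on or off
never perturbs another stage's draws.
"""

from __future__ import annotations

import numpy as np

# Fixed stage offsets; order is part of the reproducibility contract.
STAGE_KEYS = {
    "demographics": 0,
    "tapping": 1,
    "spect": 2,
    "fmri": 3,
    "misc": 4,
}


def stage_rng(seed: int, stage: str, *subkeys: int) -> np.random.Generator:
    """Return the dedicated generator for ``stage`` (optionally per subject).

    Parameters
    ----------
    seed : int
        Global pipeline seed.
    stage : str
        One of ``STAGE_KEYS``.
    *subkeys : int
        Optional further indices (e.g. subject index) for per-entity streams.
    """
    if stage not in STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_KEYS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGE_KEYS[stage], *subkeys))
    return np.random.default_rng(ss)
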