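"""Stage-keyed random substreams.

Every stochastic stage of an analysis draws from its own substream derived
from one master seed and a fixed stage key.  Adding, removing or
reconfiguring one stage therefore never perturbs another stage's draws,
which is what makes full-study reports reproducible stage by stage.
"""

from __future__ import annotations

import numpy as np

# Fixed keys: appending new stages at the end never renumbers old ones.
STAGE_KEYS = {
    "simulate": 11,
    "network": 23,
    "bootstrap_edges": 31,
    "casedrop": 37,
    "nct_gender": 41,
    "nct_age": 43,
    "nct_schizotypy": 47,
    "dag": 53,
    "dag_subgroups": 59,
    "descriptives": 61,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated generator for *stage* under *master_seed*."""
    try:
        key = STAGE_KEYS[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def child_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit child seed (for APIs that take integer seeds)."""
    return int(rng.integers(0, 2**31 - 1))
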