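"""Named random substreams derived from a single master seed.

Every stochastic procedure in the package (tree simulation, trait
evolution, demographic bootstrap, rarefaction, permutation tests)
draws from its own substream so that adding replicates to one stage
never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _label_key(label: str) -> int:
    # stable across processes/platforms, unlike hash()
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    The same ``(seed, labels)`` pair always yields an identical stream.
    """
    keys = [_label_key(str(lab)) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def spawn_seed(seed: int, *labels: object) -> int:
    """A derived integer seed (< 2**31) for APIs that take plain seeds."""
    return int(substream(seed, *labels).integers(0, 2**31 - 1))
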