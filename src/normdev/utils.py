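"""Small shared helpers: seeded substreams and region naming."""

from __future__ import annotations

import zlib

import numpy as np

ROI_COLUMNS = ["subject_id", "site_id", "sex", "age", "group", "role", "region_id", "thickness"]


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named random substream: deterministic, independent per (seed, label)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def region_names(n_regions: int) -> list[str]:
    return [f"region_{i:03d}" for i in range(1, n_regions + 1)]
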