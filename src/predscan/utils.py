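"""Small shared helpers: seed fan-out and distribution diagnostics."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed.

    The derivation is a CRC32 of the stage name mixed with the base seed, so
    every pipeline stage is individually reproducible and stays below 2**31.
    """
    return (int(base_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)


def count_histogram_modes(
    values: np.ndarray, bins: int | None = None, min_rel_height: float = 0.05
) -> int:
    """Count local maxima of a histogram of ``values``.

    Used to verify that predicted-score distributions driven by one or two
    large-effect SNPs are multimodal (up to trimodal for a single SNP) while
    highly polygenic scores look unimodal.  A bin is a mode when it is a
    strict local maximum among nonzero-smoothed counts and reaches at least
    ``min_rel_height`` of the tallest bin.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10 or np.ptp(values) == 0:
        return 1 if values.size else 0
    if bins is None:
        bins = max(10, int(np.sqrt(values.size)))
    counts, _ = np.histogram(values, bins=bins)
    # pad so boundary bins can be modes
    c = np.concatenate([[0], counts, [0]]).astype(float)
    floor = min_rel_height * counts.max()
    n_modes = 0
    i = 1
    while i < len(c) - 1:
        if c[i] >= c[i - 1] and c[i] > floor:
            # walk over any plateau
            j = i
            while j + 1 < len(c) - 1 and c[j + 1] == c[i]:
                j += 1
            if c[j + 1] < c[i]:
                n_modes += 1
            i = j + 1
        else:
            i += 1
    return n_modes
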