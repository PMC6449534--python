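"""Small shared helpers (deterministic data splitting)."""

from __future__ import annotations

import numpy as np

__all__ = ["stratified_split"]


def stratified_split(labels: np.ndarray, fractions: tuple[float, ...],
                     seed: int) -> list[np.ndarray]:
    """Split indices into len(fractions) groups, stratified by label.

    Fractions must sum to 1 (within rounding). Within each class the split
    is a seeded permutation; remainders go to the first group. Returns one
    index array per group, each sorted.
    """
    labels = np.asarray(labels)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        sizes = [int(np.floor(f * n)) for f in fractions]
        sizes[0] += n - sum(sizes)
        lo = 0
        for g, size in enumerate(sizes):
            groups[g].extend(idx[lo:lo + size].tolist())
            lo += size
    return [np.array(sorted(g), dtype=int) for g in groups]
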