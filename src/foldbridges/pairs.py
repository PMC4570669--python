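"""All-against-all comparison schedules over domain identifiers."""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np


def all_vs_all_pairs(ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate every unordered pair of distinct identifiers.

    Returns two index arrays ``(i, j)`` with ``i < j`` positionally, i.e. the
    upper triangle of the pairwise comparison array.  For ``n`` domains this
    is the full ``n * (n - 1) / 2`` alignment schedule.
    """
    n = len(ids)
    if n != len(set(ids)):
        raise ValueError("domain identifiers must be unique")
    i, j = np.triu_indices(n, k=1)
    return i, j


def pair_count(ids: Sequence[str]) -> int:
    """Number of comparisons in the all-against-all schedule."""
    i, _ = all_vs_all_pairs(ids)
    return int(i.size)
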