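"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
they validate: AUC by exhaustive pairwise comparison, connected components by
breadth-first flood fill, the weighted cross-entropy by a plain scalar loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def mann_whitney_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as P(score+ > score-) + 0.5 P(score+ = score-), all pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def flood_fill_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """26-connected component labelling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < mask.shape[0]
                    and 0 <= n[1] < mask.shape[1]
                    and 0 <= n[2] < mask.shape[2]
                    and mask[n]
                    and not labels[n]
                ):
                    labels[n] = current
                    queue.append(n)
    return labels, current


def scalar_weighted_cce(
    pred: np.ndarray, label: np.ndarray, w: tuple[float, float, float],
    eps: float = 1e-7,
) -> float:
    """Plain-Python weighted categorical cross-entropy over (N, 3) arrays."""
    total = 0.0
    n = len(pred)
    for p_row, y_row in zip(pred, label):
        for wi, pi, yi in zip(w, p_row, y_row):
            pi = min(max(pi, eps), 1.0)
            total += wi * yi * np.log(pi)
    return -total / n
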