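"""Shared brute-force oracle helpers for the test suite."""

import itertools

import numpy as np


def flood_fill(binary, connectivity):
    """BFS connected-component labelling, independent of the package."""
    reach = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = [
        o for o in itertools.product([-1, 0, 1], repeat=3)
        if o != (0, 0, 0) and sum(abs(v) for v in o) <= reach
    ]
    labels = np.zeros(binary.shape, int)
    current = 0
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if labels[idx]:
            continue
        current += 1
        queue = [idx]
        labels[idx] = current
        while queue:
            x, y, z = queue.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(nb, binary.shape)):
                    if binary[nb] and not labels[nb]:
                        labels[nb] = current
                        queue.append(nb)
    return labels
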