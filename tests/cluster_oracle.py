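"""Brute-force connected-components oracle shared by cluster tests."""

import numpy as np


def flood_fill_components(mask, connectivity):
    """BFS flood fill with explicit neighbor offsets; returns a set of
    frozensets of voxel index tuples."""
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and {6: abs(i) + abs(j) + abs(k) == 1,
             18: abs(i) + abs(j) + abs(k) <= 2,
             26: True}[connectivity]
    ]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = []
        stack = [idx]
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for o in offs:
                nb = tuple(np.add(cur, o))
                if all(0 <= nb[d] < mask.shape[d] for d in range(3)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)
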