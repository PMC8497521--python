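"""Brute-force oracles for the image primitives.

Deliberately independent of the implementations they check: explicit
loops, explicit sorts, breadth-first flood fill.
"""

import numpy as np

def _median_oracle(arr):
    """Brute force: gather each 3x3x3 neighborhood (edge-replicated) and
    sort."""
    padded = np.pad(arr, 1, mode="edge")
    out = np.empty_like(arr)
    nz, ny, nx = arr.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                neigh = padded[z:z + 3, y:y + 3, x:x + 3].ravel()
                out[z, y, x] = np.sort(neigh)[13]
    return out



def _otsu_oracle_cut(counts, centers):
    """Exhaustive between-class-variance maximization, explicit loop."""
    p = counts / counts.sum()
    best, best_k = -1.0, None
    for k in range(len(centers) - 1):
        w0 = p[: k + 1].sum()
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = (p[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (p[k + 1:] * centers[k + 1:]).sum() / w1
        crit = w0 * w1 * (mu0 - mu1) ** 2
        if crit > best + 1e-12 * max(best, 1.0):
            best, best_k = crit, k
    return best_k



def _bfs_labels(mask, connectivity=26):
    """Flood-fill oracle: breadth-first search from each unvisited voxel."""
    from collections import deque

    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = sum(v != 0 for v in (dz, dy, dx))
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 1
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            q = deque([idx])
            labels[idx] = nxt
            while q:
                z, y, x = q.popleft()
                for dz, dy, dx in offsets:
                    n = (z + dz, y + dy, x + dx)
                    if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                            and mask[n] and labels[n] == 0:
                        labels[n] = nxt
                        q.append(n)
            nxt += 1
    return labels, nxt - 1


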