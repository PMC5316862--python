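"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: the threshold oracle is
a literal sliding-window mean, labeling is breadth-first search, filtering
is four explicit predicates, and z-linking is connected components on an
explicitly constructed overlap graph.
"""

from collections import deque

import numpy as np


def sliding_mean_threshold(response: np.ndarray, window: int, offset: float) -> np.ndarray:
    """Foreground iff response > mean of the centred window (reflected borders) + offset."""
    half = window // 2
    padded = np.pad(np.asarray(response, dtype=float), half, mode="symmetric")
    views = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    means = views.mean(axis=(2, 3))
    return response > means + offset


def bfs_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected components by BFS; labels 1..n in raster order of first pixel."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    nxt = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                labels[r0, c0] = nxt
                q = deque([(r0, c0)])
                while q:
                    r, c = q.popleft()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = nxt
                            q.append((rr, cc))
    return labels


def four_predicate_filter(mean_radius, radius_cv, eccentricity,
                          min_r=15.0, max_r=200.0, max_cv=0.2, max_ecc=0.75) -> bool:
    """True iff the object survives all four rejection rules."""
    if mean_radius <= min_r:
        return False
    if mean_radius > max_r:
        return False
    if radius_cv > max_cv:
        return False
    if eccentricity > max_ecc:
        return False
    return True


def overlap_graph_components(objects) -> list[frozenset]:
    """Connected components of the explicit adjacent-plane overlap graph.

    ``objects`` is a list of (plane_index, label, set_of_pixel_tuples).
    Returns a set partition of (plane_index, label) keys.
    """
    keys = [(p, l) for p, l, _ in objects]
    pix = {(p, l): s for p, l, s in objects}
    adj = {k: set() for k in keys}
    for i, (pi, li) in enumerate(keys):
        for pj, lj in keys[i + 1:]:
            if abs(pi - pj) == 1 and pix[(pi, li)] & pix[(pj, lj)]:
                adj[(pi, li)].add((pj, lj))
                adj[(pj, lj)].add((pi, li))
    seen, comps = set(), []
    for k in keys:
        if k in seen:
            continue
        comp, q = set(), deque([k])
        seen.add(k)
        while q:
            cur = q.popleft()
            comp.add(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    q.append(nb)
        comps.append(frozenset(comp))
    return comps
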