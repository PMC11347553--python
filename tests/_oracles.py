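"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain per-voxel Python loops, deliberately
sharing no code with the package, so that agreement between the two is
meaningful.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
DIRS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


def brute_glcm(levels: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair walk."""
    Ng = int(levels.max())
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for d in DIRS_13:
                    q = (x + d[0] * distance, y + d[1] * distance, z + d[2] * distance)
                    if not _inside(shape, q):
                        continue
                    b = levels[q]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def brute_glrlm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Run counts {(level, length): n} by scanning every line start."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    for d in DIRS_13:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    v = levels[x, y, z]
                    if v == 0:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and levels[prev] == v:
                        continue  # not a run start
                    length = 1
                    p = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, p) and levels[p] == v:
                        length += 1
                        p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                    runs[(int(v), length)] = runs.get((int(v), length), 0) + 1
    return runs


def brute_zones(levels: np.ndarray) -> list[tuple[int, list[tuple[int, int, int]]]]:
    """26-connected equal-level zones via stack flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0 or seen[x, y, z]:
                    continue
                v = levels[x, y, z]
                stack = [(x, y, z)]
                seen[x, y, z] = True
                members = []
                while stack:
                    p = stack.pop()
                    members.append(p)
                    for d in DIRS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, q) and not seen[q] and levels[q] == v:
                            seen[q] = True
                            stack.append(q)
                zones.append((int(v), members))
    return zones


def brute_glszm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): n}."""
    out: dict[tuple[int, int], int] = {}
    for v, members in brute_zones(levels):
        key = (v, len(members))
        out[key] = out.get(key, 0) + 1
    return out


def brute_border_distance(levels: np.ndarray) -> np.ndarray:
    """Exhaustive city-block distance of each in-mask voxel to the ROI
    border (nearest background voxel, with a virtual background ring
    outside the grid); border voxels get 1."""
    shape = levels.shape
    bg = []
    for x in range(-1, shape[0] + 1):
        for y in range(-1, shape[1] + 1):
            for z in range(-1, shape[2] + 1):
                if not _inside(shape, (x, y, z)) or levels[x, y, z] == 0:
                    bg.append((x, y, z))
    dist = np.zeros(shape, dtype=np.int64)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0:
                    continue
                dist[x, y, z] = min(abs(x - b[0]) + abs(y - b[1]) + abs(z - b[2]) for b in bg)
    return dist


def brute_gldzm(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(level, min border distance): n}."""
    dist = brute_border_distance(levels)
    out: dict[tuple[int, int], int] = {}
    for v, members in brute_zones(levels):
        d = min(int(dist[p]) for p in members)
        out[(v, d)] = out.get((v, d), 0) + 1
    return out


def brute_ngtdm(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(s_i, n_i) by explicit neighborhood averaging."""
    Ng = int(levels.max())
    s = np.zeros(Ng)
    n = np.zeros(Ng, dtype=np.int64)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                v = levels[x, y, z]
                if v == 0:
                    continue
                nbrs = [
                    levels[x + d[0], y + d[1], z + d[2]]
                    for d in DIRS_26
                    if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                    and levels[x + d[0], y + d[1], z + d[2]] != 0
                ]
                if not nbrs:
                    continue
                s[v - 1] += abs(v - sum(nbrs) / len(nbrs))
                n[v - 1] += 1
    return s, n


def brute_holm(pvalues) -> np.ndarray:
    """Step-down Holm by direct evaluation of the defining formula."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def brute_km(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate [(t, S(t))] at each distinct event time."""
    pairs = sorted(zip(times, events))
    s = 1.0
    out = []
    distinct = sorted({t for t, e in pairs if e})
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        deaths = sum(1 for ti, ei in pairs if ti == t and ei)
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out


def brute_logrank(times_a, events_a, times_b, events_b) -> tuple[float, float, float]:
    """Two-group log-rank by explicit per-event-time O/E/V tabulation
    (ties pooled at each distinct time).  Returns (O_A, E_A, V)."""
    all_t = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                      list(events_a) + list(events_b)) if e})
    oa = ea = var = 0.0
    for t in all_t:
        na = sum(1 for ti in times_a if ti >= t)
        nb = sum(1 for ti in times_b if ti >= t)
        da = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei)
        db = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei)
        n, d = na + nb, da + db
        if n == 0 or d == 0:
            continue
        oa += da
        ea += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return oa, ea, var
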