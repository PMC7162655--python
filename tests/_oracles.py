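"""Independent brute-force oracles used only by the tests.

Deliberately naive implementations, structurally unrelated to the
library code paths they check.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def euler_characteristic_cubes(mask: np.ndarray) -> int:
    """χ of the union of closed unit cubes, by counting distinct
    vertices, edges, faces and cubes one voxel at a time."""
    vertices, edges, faces = set(), set(), set()
    n_cubes = 0
    for z, y, x in np.argwhere(mask):
        n_cubes += 1
        corners = [
            (z + dz, y + dy, x + dx)
            for dz in (0, 1)
            for dy in (0, 1)
            for dx in (0, 1)
        ]
        vertices.update(corners)
        for a in corners:
            for b in corners:
                if a < b:
                    diff = sum(abs(a[i] - b[i]) for i in range(3))
                    if diff == 1:
                        edges.add((a, b))
        # 6 faces as frozensets of their 4 corners
        for axis in range(3):
            for side in (0, 1):
                face = frozenset(c for c in corners if c[axis] == (z, y, x)[axis] + side)
                faces.add(face)
    return len(vertices) - len(edges) + len(faces) - n_cubes


def _bfs_components(mask: np.ndarray, offsets) -> int:
    seen = np.zeros(mask.shape, dtype=bool)
    n = 0
    shape = mask.shape
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        n += 1
        dq = deque([start])
        seen[start] = True
        while dq:
            cur = dq.popleft()
            for off in offsets:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if all(0 <= nb[i] < shape[i] for i in range(3)):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        dq.append(nb)
    return n


_OFF26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
_OFF6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def b1_oracle(mask: np.ndarray) -> int:
    """First Betti number via b1 = b0 + b2 − χ with brute-force counts."""
    mask = np.asarray(mask, bool)
    b0 = _bfs_components(mask, _OFF26)
    bg = np.pad(~mask, 1, constant_values=True)
    b2 = _bfs_components(bg, _OFF6) - 1
    chi = euler_characteristic_cubes(mask)
    return b0 + b2 - chi


def r_squared_oracle(x, y) -> tuple[float, float, float]:
    """(slope, intercept, R²) from the normal equations, step by step."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    ss_res = sum((yi - (slope * xi + intercept)) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - my) ** 2 for yi in y)
    return slope, intercept, 1.0 - ss_res / ss_tot


def student_t_oracle(a, b) -> tuple[float, float, float]:
    """Equal-variance two-sample t (statistic, df, two-sided p)."""
    from scipy.stats import t as tdist

    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    tstat = (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    df = na + nb - 2
    p = 2 * tdist.sf(abs(tstat), df)
    return tstat, df, p


def welch_t_oracle(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t (statistic, df, two-sided p)."""
    from scipy.stats import t as tdist

    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    tstat = (ma - mb) / se2**0.5
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(tstat), df)
    return tstat, df, p
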