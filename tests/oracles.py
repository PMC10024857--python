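"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own code paths: flood fill is a
hand-rolled stack BFS, distances are dense boundary sampling, forward stain
mixing is written out in plain numpy.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon


def flood_fill_components(binary: np.ndarray) -> list[int]:
    """8-connected component pixel counts via an explicit stack BFS."""
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    h, w = binary.shape
    sizes = []
    for si in range(h):
        for sj in range(w):
            if not binary[si, sj] or visited[si, sj]:
                continue
            stack = [(si, sj)]
            visited[si, sj] = True
            size = 0
            while stack:
                i, j = stack.pop()
                size += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (0 <= ni < h and 0 <= nj < w
                                and binary[ni, nj] and not visited[ni, nj]):
                            visited[ni, nj] = True
                            stack.append((ni, nj))
            sizes.append(size)
    return sorted(sizes)


def boundary_sample_distance(point_xy: tuple[float, float], poly: Polygon,
                             step: float = 0.05) -> float:
    """Distance from a point to a polygon: 0 inside, else the minimum over
    densely sampled boundary points."""
    p = Point(point_xy)
    if poly.contains(p):
        return 0.0
    best = np.inf
    boundaries = [poly.exterior, *poly.interiors]
    for ring in boundaries:
        n = max(4, int(np.ceil(ring.length / step)))
        for k in range(n):
            q = ring.interpolate(k * ring.length / n)
            d = np.hypot(q.x - p.x, q.y - p.y)
            if d < best:
                best = d
    return float(best)


def forward_mix_od(densities: list[np.ndarray], vectors: list[np.ndarray]
                   ) -> np.ndarray:
    """Beer-Lambert forward model written out longhand."""
    h, w = densities[0].shape
    od = np.zeros((h, w, 3))
    for d, v in zip(densities, vectors):
        for ch in range(3):
            od[:, :, ch] += d * v[ch]
    return od
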