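import heapq
import math

import numpy as np
import pytest

from tubecount.synthgen import _downsample_majority, _segment_mask_ss


def dijkstra_cost(mask, dt, start, end, lam=1.0):
    """Independent geodesic oracle: heapq Dijkstra over foreground pixels
    with geometric step cost length * (cost(a) + cost(b)) / 2."""
    h, w = mask.shape
    node_cost = np.where(mask, 1.0 + lam / np.where(dt > 0, dt, 1.0), np.inf)
    dist = {start: 0.0}
    heap = [(0.0, start)]
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        if u == end:
            return d
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                v = (u[0] + dr, u[1] + dc)
                if not (0 <= v[0] < h and 0 <= v[1] < w) or not mask[v]:
                    continue
                step = math.hypot(dr, dc) * (node_cost[u] + node_cost[v]) / 2.0
                nd = d + step
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    return math.inf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def capsule_mask(shape, p0, p1, width):
    """Rasterise one thick segment exactly as the generator does."""
    ss = _segment_mask_ss((shape[0] * 4, shape[1] * 4), np.asarray(p0, float),
                          np.asarray(p1, float), width)
    return _downsample_majority(ss)


@pytest.fixture
def bar_mask():
    """Horizontal 100x5 bar inside a 9x104 canvas, midline at row 4."""
    mask = np.zeros((9, 104), dtype=bool)
    mask[2:7, 2:102] = True
    return mask
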