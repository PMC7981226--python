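"""Brute-force least-cost-path oracle shared by the geo and acceptance tests."""

import math

from lyresong import geo


def brute_force_min_cost(raster, start, goal):
    """Exhaustive DFS over simple paths with branch-and-bound pruning.

    Independent of the Dijkstra implementation: explores every simple path
    (pruned only when already costlier than the incumbent), so the
    returned optimum is exact.
    """
    nrows, ncols = raster.shape
    vals = raster.values
    best = [math.inf]

    def dist(a, b):
        dxs = raster.cell_sizes_m(a[0])
        step = dxs[1] if a[1] == b[1] else (dxs[0] if a[0] == b[0]
                                            else math.hypot(*dxs))
        return 0.5 * (vals[a] + vals[b]) * step

    def dfs(cell, cost, visited):
        if cost >= best[0]:
            return
        if cell == goal:
            best[0] = cost
            return
        r, c = cell
        for dr, dc in geo._NEIGHBOURS:
            nxt = (r + dr, c + dc)
            if 0 <= nxt[0] < nrows and 0 <= nxt[1] < ncols and nxt not in visited:
                dfs(nxt, cost + dist(cell, nxt), visited | {nxt})

    dfs(start, 0.0, {start})
    return best[0]
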