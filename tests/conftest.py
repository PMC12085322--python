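"""Shared fixtures and independent oracles for the test suite."""

import heapq
import math

import numpy as np
import pytest

from ahascape.landscape_io import DEFAULT_CLASS_CODES, GridSpec, LandcoverStack


def brute_force_cost_distance(cost: np.ndarray, focal: tuple[int, int]) -> np.ndarray:
    """Independent Dijkstra over the 8-connected grid, written against the
    stated edge rule only: orthogonal step (c_a + c_b) / 2, diagonal step
    sqrt(2) * (c_a + c_b) / 2, start cell accumulates 0."""
    n_rows, n_cols = cost.shape
    dist = np.full(cost.shape, np.inf)
    dist[focal] = 0.0
    heap = [(0.0, focal)]
    moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in moves:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            step = (cost[r, c] + cost[rr, cc]) / 2.0
            if dr != 0 and dc != 0:
                step *= math.sqrt(2.0)
            nd = d + step
            if nd < dist[rr, cc]:
                dist[rr, cc] = nd
                heapq.heappush(heap, (nd, (rr, cc)))
    return dist


def uniform_stack(n: int = 100, cell: float = 10.0, timesteps=(1899, 2012), fill: int = 0) -> LandcoverStack:
    """All-one-class land-cover stack on an n x n grid."""
    grid = GridSpec(origin_x=0.0, origin_y=n * cell, cell_size=cell, n_rows=n, n_cols=n)
    layers = {t: np.full((n, n), fill, dtype=np.int64) for t in timesteps}
    return LandcoverStack(grid=grid, timesteps=list(timesteps), layers=layers)


@pytest.fixture(scope="session")
def open_stack() -> LandcoverStack:
    return uniform_stack()


@pytest.fixture(scope="session")
def class_codes():
    return dict(DEFAULT_CLASS_CODES)
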