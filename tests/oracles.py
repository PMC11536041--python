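"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each rule from its written definition by
exhaustive enumeration, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def oracle_segment_states(d: list[float], params) -> list[str]:
    """Reference run/pause/passive labelling of displacement intervals.

    Enumerates every window explicitly against the rule definitions:
    a run window must start and end on a nonzero displacement, contain
    nonzero displacements of a single sign and at most
    ``params.absorb_zero_frames`` zeros, span >= run_min_frames intervals
    and >= run_min_px total displacement. Pauses are maximal zero
    stretches stalling >= pause_min_frames frames (k intervals = k+1
    frames); with a pause_max_frames cap, a longer stall terminates the
    trace. Passive: leftover intervals with |d| <= passive_max_px.
    """
    d = list(d)
    m = len(d)

    # catastrophe truncation (eb3): earliest over-long stall ends the comet
    if params.pause_max_frames is not None:
        i = 0
        while i < m:
            if d[i] == 0:
                j = i
                while j < m and d[j] == 0:
                    j += 1
                if (j - i) + 1 > params.pause_max_frames:
                    m = i
                    d = d[:m]
                    break
                i = j
            else:
                i += 1

    state = ["unclassified"] * m

    def sgn(x: float) -> int:
        return (x > params.position_tol_px) - (x < -params.position_tol_px)

    def window_is_run_shaped(a: int, b: int) -> bool:
        if sgn(d[a]) == 0 or sgn(d[b]) == 0:
            return False
        signs = {sgn(x) for x in d[a : b + 1] if sgn(x) != 0}
        if len(signs) != 1:
            return False
        zeros = sum(1 for x in d[a : b + 1] if sgn(x) == 0)
        return zeros <= params.absorb_zero_frames

    def window_qualifies(a: int, b: int) -> bool:
        return (b - a + 1) >= params.run_min_frames and abs(
            sum(d[a : b + 1])
        ) >= params.run_min_px

    i = 0
    while i < m:
        if sgn(d[i]) != 0 and state[i] == "unclassified":
            best = None
            for b in range(i, m):
                if window_is_run_shaped(i, b):
                    best = b
            if best is not None and window_qualifies(i, best):
                for k in range(i, best + 1):
                    state[k] = "run"
                i = best + 1
                continue
        i += 1

    i = 0
    while i < m:
        if sgn(d[i]) == 0 and state[i] == "unclassified":
            j = i
            while j < m and sgn(d[j]) == 0 and state[j] == "unclassified":
                j += 1
            if (j - i) + 1 >= params.pause_min_frames:
                for k in range(i, j):
                    state[k] = "pause"
            i = j
        else:
            i += 1

    if params.passive_enabled:
        for k in range(m):
            if state[k] == "unclassified" and abs(d[k]) <= params.passive_max_px:
                state[k] = "passive"
    return state


def states_from_segments(segments, n_intervals: int, frame_offset: int = 0) -> list[str]:
    """Expand a MotionSegment list back to per-interval labels."""
    state = ["unclassified"] * n_intervals
    for s in segments:
        for k in range(s.frame_start - frame_offset, s.frame_end - frame_offset):
            state[k] = s.kind
    return state


def oracle_nearest_on_polyline(point: np.ndarray, polyline: np.ndarray, n_dense: int = 20001):
    """Dense-sampling nearest point: arc position and distance to *point*."""
    seg = np.diff(polyline, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0, arc[-1], n_dense)
    x = np.interp(s, arc, polyline[:, 0])
    y = np.interp(s, arc, polyline[:, 1])
    d2 = (x - point[0]) ** 2 + (y - point[1]) ** 2
    k = int(np.argmin(d2))
    return s[k], float(np.sqrt(d2[k]))


def oracle_max_coloc_matching(ca: np.ndarray, cb: np.ndarray, box: float) -> int:
    """Maximum-cardinality one-to-one matching of box-compatible pairs."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((0, i) for i in range(len(ca)))
    g.add_nodes_from((1, j) for j in range(len(cb)))
    for i, p in enumerate(ca):
        for j, q in enumerate(cb):
            if abs(p[0] - q[0]) <= box and abs(p[1] - q[1]) <= box:
                g.add_edge((0, i), (1, j))
    match = nx.bipartite.maximum_matching(
        g, top_nodes=[(0, i) for i in range(len(ca))]
    )
    return sum(1 for k in match if k[0] == 0)
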