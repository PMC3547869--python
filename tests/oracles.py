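"""Independent reference computations used by several test modules."""

from __future__ import annotations

import numpy as np

from dictyosc.cluster_model import Arrangement, NetworkParams


def laplacian_pinv_resistance(arr: Arrangement, p: NetworkParams) -> float:
    """Effective resistance via the Laplacian pseudoinverse.

    R_ab = L+_aa + L+_bb - 2 L+_ab over the full (ungrounded) network — a
    different solution route than the implementation's grounded direct
    solve, sharing only the network definition.
    """
    occ = arr.occupancy
    m = occ.size
    n = m + 2  # 0 electrode, 1 bulk, 2+i cleft nodes

    # network definition (shared with the implementation): interface and
    # vertical elements per site, lateral R_lat when either site covered,
    # ideal short between two adjacent open sites
    edges = []
    for i in range(m):
        edges.append((0, 2 + i, p.R_iface))
        edges.append((2 + i, 1, p.R_block if occ[i] else p.R_open))
    for i in range(m - 1):
        edges.append((2 + i, 2 + i + 1, p.R_lat if occ[i] or occ[i + 1] else 0.0))

    # collapse ideal shorts by relabeling nodes (plain loop, no union-find)
    group = list(range(n))
    changed = True
    while changed:
        changed = False
        for a, b, r in edges:
            if r == 0 and group[a] != group[b]:
                old, new = max(group[a], group[b]), min(group[a], group[b])
                group = [new if g == old else g for g in group]
                changed = True
    labels = sorted(set(group))
    index = {g: i for i, g in enumerate(labels)}
    nn = len(labels)
    lap = np.zeros((nn, nn))
    for a, b, r in edges:
        if r == 0:
            continue
        ia, ib = index[group[a]], index[group[b]]
        if ia == ib:
            continue
        g = 1.0 / r
        lap[ia, ia] += g
        lap[ib, ib] += g
        lap[ia, ib] -= g
        lap[ib, ia] -= g
    src, snk = index[group[0]], index[group[1]]
    if src == snk:
        return 0.0
    plus = np.linalg.pinv(lap)
    return float(plus[src, src] + plus[snk, snk] - 2 * plus[src, snk])


def pearson_from_definition(z, y) -> float:
    """Plain-loop population Pearson coefficient (no vectorized shortcuts)."""
    n = len(z)
    mz = sum(z) / n
    my = sum(y) / n
    cov = sum((a - mz) * (b - my) for a, b in zip(z, y)) / n
    vz = sum((a - mz) ** 2 for a in z) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / (vz**0.5 * vy**0.5)


def run_partitions(total: int, max_part: int):
    """All integer partitions of ``total`` with parts <= max_part, descending."""
    if total == 0:
        yield ()
        return
    for first in range(min(total, max_part), 0, -1):
        for rest in run_partitions(total - first, first):
            yield (first,) + rest
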