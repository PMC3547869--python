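"""One-dimensional ohmic model of cell clustering on an electrode.

Adherent amebas act as highly resistive plaques over a conducting electrolyte
film; current leaving the electrode under a covered site must travel
laterally along the thin cleft before reaching an open (uncovered) site with
low-resistance access to the bulk. At fixed surface coverage, gathering the
covered sites into longer runs (larger clusters) lengthens those lateral
paths, so a more clustered arrangement shows a higher two-terminal
resistance than a homogeneous one — the sign of the impedance change the
clustering oscillation produces.

The electrode is a row of ``M`` sites, each covered or open. The resistor
ladder has one cleft node per site:

* electrode -> cleft_i through ``R_iface`` (electrode interface, every site);
* cleft_i <-> cleft_{i+1} through ``R_lat`` when either site is covered
  (the lateral cleft path); two adjacent open sites share the
  unobstructed bulk electrolyte and are joined by an ideal short, so the
  lateral cleft resistance is the only arrangement-sensitive element;
* cleft_i -> bulk through ``R_open`` when the site is open, through
  ``R_block`` (large: crossing a cell body) when covered.

Open, non-periodic boundaries model a finite electrode. All four resistances
are parameters; the defaults are a calibration chosen so that regrouping
dimers into trimers at coverage 1/2 moves the resistance by roughly 10%, the
order of the impedance oscillation amplitude seen on cell-covered
electrodes.

:func:`effective_resistance` solves the Kirchhoff nodal system exactly
(zero-resistance edges are contracted first, so ideal shorts are legal).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = [
    "Arrangement",
    "NetworkParams",
    "effective_resistance",
    "canonical_arrangement",
    "clustering_sweep",
]


@dataclass
class Arrangement:
    """Occupancy pattern of the 1-D electrode.

    occupancy[i] is True where site i is covered by a cell.
    """

    occupancy: np.ndarray
    site_length_um: float = 10.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 1 or self.occupancy.size < 2:
            raise ValueError("occupancy must be 1-D with at least 2 sites")
        if self.site_length_um <= 0:
            raise ValueError("site_length_um must be positive")

    @property
    def n_sites(self) -> int:
        return self.occupancy.size

    @property
    def coverage(self) -> float:
        return float(self.occupancy.mean())

    def mirrored(self) -> "Arrangement":
        return Arrangement(self.occupancy[::-1].copy(), self.site_length_um)

    def run_lengths(self) -> list[int]:
        """Lengths of maximal covered runs, left to right."""
        runs, n = [], 0
        for occ in self.occupancy:
            if occ:
                n += 1
            elif n:
                runs.append(n)
                n = 0
        if n:
            runs.append(n)
        return runs


@dataclass
class NetworkParams:
    """Resistances (ohm) of the four ladder elements, per site."""

    R_lat: float = 1.0
    R_open: float = 0.1
    R_iface: float = 1.0
    R_block: float = 1e6

    def __post_init__(self) -> None:
        vals = (self.R_lat, self.R_open, self.R_iface, self.R_block)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError("all resistances must be finite and >= 0")
        if self.R_block <= self.R_open:
            raise ValueError("R_block must exceed R_open (cells insulate)")


def _edges(arr: Arrangement, p: NetworkParams):
    """Yield (node_a, node_b, resistance). Nodes: 0=electrode, 1=bulk, 2+i=cleft_i."""
    occ = arr.occupancy
    m = occ.size
    for i in range(m):
        yield 0, 2 + i, p.R_iface
        yield 2 + i, 1, p.R_block if occ[i] else p.R_open
    for i in range(m - 1):
        if occ[i] or occ[i + 1]:
            yield 2 + i, 2 + i + 1, p.R_lat
        else:
            # two adjacent open sites share the unobstructed bulk: an
            # ideal lateral short, so only covered runs obstruct flow
            yield 2 + i, 2 + i + 1, 0.0


def effective_resistance(arr: Arrangement, p: NetworkParams | None = None) -> float:
    """Two-terminal resistance electrode <-> bulk of the site ladder (ohm).

    Builds the nodal (Laplacian) system from the edge list, contracts
    zero-resistance edges, grounds the bulk node, injects unit current at
    the electrode node and returns its potential. Returns ``inf`` when no
    conducting path exists.
    """
    if p is None:
        p = NetworkParams()
    edges = list(_edges(arr, p))
    n_nodes = 2 + arr.n_sites

    # contract ideal shorts via union-find
    parent = list(range(n_nodes))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b, r in edges:
        if r == 0:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups = {}
    for node in range(n_nodes):
        groups.setdefault(find(node), len(groups))
    idx = [groups[find(node)] for node in range(n_nodes)]
    src, snk = idx[0], idx[1]
    if src == snk:
        return 0.0

    n = len(groups)
    lap = np.zeros((n, n))
    for a, b, r in edges:
        if r == 0:
            continue
        ia, ib = idx[a], idx[b]
        if ia == ib:
            continue
        g = 1.0 / r
        lap[ia, ia] += g
        lap[ib, ib] += g
        lap[ia, ib] -= g
        lap[ib, ia] -= g

    keep = [i for i in range(n) if i != snk]
    sub = lap[np.ix_(keep, keep)]
    rhs = np.zeros(n - 1)
    rhs[keep.index(src)] = 1.0
    try:
        pot = np.linalg.solve(sub, rhs)
    except np.linalg.LinAlgError:
        return float("inf")
    r_eff = float(pot[keep.index(src)])
    if not np.isfinite(r_eff) or r_eff < 0:
        return float("inf")
    return r_eff


def canonical_arrangement(
    cluster_sizes, total_sites: int, site_length_um: float = 10.0
) -> Arrangement:
    """Deterministic 1-D embedding of a 2-D cluster-size distribution.

    Covered runs equal to the sorted cluster sizes (largest first) are laid
    down separated by single open sites; remaining open sites are appended.
    Only the run-length distribution — the feature the ladder model is
    sensitive to — survives the 2-D -> 1-D projection.
    """
    sizes = sorted(int(s) for s in cluster_sizes)
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    sizes = sizes[::-1]
    n_cov = sum(sizes)
    if n_cov + len(sizes) > total_sites:
        raise ValueError(
            f"{n_cov} covered sites + {len(sizes)} separating gaps do not fit "
            f"into {total_sites} sites"
        )
    occ: list[bool] = []
    for s in sizes:
        occ.extend([True] * s)
        occ.append(False)
    occ.extend([False] * (total_sites - len(occ)))
    return Arrangement(np.array(occ, dtype=bool), site_length_um)


def clustering_sweep(
    coverage: float,
    run_lengths,
    total_sites: int,
    p: NetworkParams | None = None,
    site_length_um: float = 10.0,
):
    """Resistance vs cluster run length at fixed coverage.

    For each requested run length L the covered-site budget
    ``round(coverage * total_sites)`` is split into runs of L and the ladder
    solved. Returns a list of ``(run_length, R_ohm)``; run lengths that do
    not divide the budget, or do not fit with their separating gaps, are
    skipped with a warning. For ``R_lat > 0`` the resistance is
    non-decreasing in run length.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if p is None:
        p = NetworkParams()
    n_cov = round(coverage * total_sites)
    if n_cov == 0:
        arr = Arrangement(np.zeros(total_sites, dtype=bool), site_length_um)
        r0 = effective_resistance(arr, p)
        return [(int(L), r0) for L in run_lengths]
    out = []
    for L in run_lengths:
        L = int(L)
        if L < 1 or n_cov % L != 0:
            warnings.warn(f"run length {L} does not divide {n_cov} covered sites; skipped")
            continue
        k = n_cov // L
        if n_cov + k > total_sites:
            warnings.warn(f"run length {L}: {k} runs do not fit; skipped")
            continue
        arr = canonical_arrangement([L] * k, total_sites, site_length_um)
        out.append((L, effective_resistance(arr, p)))
    return out
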