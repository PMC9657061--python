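"""Exact enumeration of interacting self-avoiding walks (ISAW) on the simple
cubic lattice.

An *N*-step ISAW is a self-avoiding walk of N unit steps whose energy is
``-m`` (in units of the contact energy), where *m* counts nonconsecutive
nearest-neighbour monomer pairs.  This module computes the exact two-variable
density of states ``c_{m,R2}`` — the number of walks with *m* contacts and
squared end-to-end distance *R2* — by exhaustive depth-first enumeration.

Counting convention: the first monomer sits at the origin and the second at
(1,0,0), so every reported count is 1/6 of the free-walk count.  Beyond the
fixed first step, walks are enumerated one representative per orientation
orbit: the first step that leaves the x-axis is required to be +y (orbit
weight x4) and the first step that leaves the xy-plane to be +z (orbit
weight x2), giving multiplicities 1 (walks on the axis), 4 (in the plane)
and 8 (fully three-dimensional).

Two independent code paths exist: :func:`enumerate_reduced` (symmetry-reduced,
numba-compiled) and :func:`enumerate_bruteforce` (naive pure-Python oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "LatticeWalk",
    "CoefficientTable",
    "PrefixJob",
    "enumerate_reduced",
    "enumerate_bruteforce",
    "list_prefixes",
    "merge_tables",
    "run_prefix_job",
]

# Fixed lexicographic direction order: +x, -x, +y, -y, +z, -z.
DIRECTIONS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))

# Orientation states of a partially built canonical walk.
_ON_AXIS = 0    # still confined to the x-axis
_IN_PLANE = 1   # left the axis, still in the xy-plane
_FULL_3D = 2    # left the plane

# int64 accumulators are exact for every chain length this code can finish
# at desk scale; the public table converts to Python ints regardless.
_MAX_STEPS = 27


@dataclass(frozen=True)
class LatticeWalk:
    """An ISAW configuration: ordered lattice sites, step length 1.

    ``sites[0] == (0,0,0)`` and ``sites[1] == (1,0,0)`` (fixed first step).
    """

    sites: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        s = self.sites
        if len(s) < 2 or s[0] != (0, 0, 0) or s[1] != (1, 0, 0):
            raise ValueError("walk must start (0,0,0) -> (1,0,0)")
        if len(set(s)) != len(s):
            raise ValueError("walk is not self-avoiding")
        for a, b in zip(s, s[1:]):
            if sum(abs(a[i] - b[i]) for i in range(3)) != 1:
                raise ValueError("consecutive sites must be lattice neighbours")

    @property
    def n_steps(self) -> int:
        return len(self.sites) - 1

    @property
    def occupancy(self) -> frozenset:
        return frozenset(self.sites)

    def contacts(self) -> int:
        """Number of nonconsecutive nearest-neighbour pairs, counted once each."""
        occ = set(self.sites)
        m = 0
        for j, s in enumerate(self.sites):
            for dx, dy, dz in DIRECTIONS:
                nb = (s[0] + dx, s[1] + dy, s[2] + dz)
                if nb in occ:
                    i = self.sites.index(nb)
                    if i < j - 1:  # each pair once, skip chain neighbours
                        m += 1
        return m

    def r2(self) -> int:
        x, y, z = self.sites[-1]
        return x * x + y * y + z * z


@dataclass
class CoefficientTable:
    """Exact density of states ``c_{m,R2}`` for one chain length.

    ``counts`` maps ``(m, r2)`` to an exact (arbitrary-precision) integer.
    Weighted sums over these counts exceed 64-bit range near N=27, so the
    public model keeps Python ints even though the enumerator accumulates
    in int64 internally.
    """

    n_steps: int
    counts: dict[tuple[int, int], int]
    metadata: dict = field(default_factory=dict)

    def total(self) -> int:
        """Number of N-step walks with the first step fixed (full SAW count / 6)."""
        return sum(self.counts.values())

    def max_contacts(self) -> int:
        return max(m for m, _ in self.counts)

    def validate(self) -> None:
        n = self.n_steps
        for (m, r2), c in self.counts.items():
            if c <= 0:
                raise ValueError(f"nonpositive count at {(m, r2)}")
            if not (0 <= m and 1 <= r2 <= n * n):
                raise ValueError(f"key out of range: {(m, r2)}")
            if (r2 - n) % 2:
                raise ValueError(f"parity violation at {(m, r2)} for N={n}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoefficientTable):
            return NotImplemented
        return self.n_steps == other.n_steps and self.counts == other.counts


@dataclass(frozen=True)
class PrefixJob:
    """A canonical walk prefix plus its orientation-orbit multiplicity.

    Jobs of one depth partition the configuration space: summing
    ``multiplicity x completions`` over all jobs reproduces the full table.
    """

    prefix: LatticeWalk
    multiplicity: int

    def __post_init__(self):
        if self.multiplicity not in (1, 4, 8):
            raise ValueError("multiplicity must be 1, 4 or 8")


def _allowed(state: int, d: int) -> bool:
    if state == _ON_AXIS:
        return d in (0, 1, 2)          # +-x, or break out via +y
    if state == _IN_PLANE:
        return d != 5                  # +-x, +-y, or break out via +z
    return True


def _step_state(state: int, d: int) -> tuple[int, int]:
    """New orientation state and weight factor after taking direction d."""
    if state == _ON_AXIS and d == 2:
        return _IN_PLANE, 4
    if state == _IN_PLANE and d == 4:
        return _FULL_3D, 2
    return state, 1


def _canonical_walks(depth: int):
    """Yield (sites, state, contacts, weight) for every canonical walk of `depth` steps."""
    start = [(0, 0, 0), (1, 0, 0)]

    def rec(sites, occ, state, m, w):
        if len(sites) - 1 == depth:
            yield tuple(sites), state, m, w
            return
        x, y, z = sites[-1]
        for d, (dx, dy, dz) in enumerate(DIRECTIONS):
            if not _allowed(state, d):
                continue
            nxt = (x + dx, y + dy, z + dz)
            if nxt in occ:
                continue
            gained = sum(
                1
                for ex, ey, ez in DIRECTIONS
                if (nxt[0] + ex, nxt[1] + ey, nxt[2] + ez) in occ
            ) - 1  # the predecessor is always an occupied neighbour
            nstate, fac = _step_state(state, d)
            occ.add(nxt)
            sites.append(nxt)
            yield from rec(sites, occ, nstate, m + gained, w * fac)
            sites.pop()
            occ.remove(nxt)

    yield from rec(start, set(start), _ON_AXIS, 0, 1)


def list_prefixes(depth: int) -> list[PrefixJob]:
    """Canonical prefixes of `depth` steps, the unit of parallel decomposition."""
    if depth < 2:
        raise ValueError("prefix depth must be >= 2")
    jobs = []
    for sites, _state, _m, w in _canonical_walks(depth):
        jobs.append(PrefixJob(prefix=LatticeWalk(sites=sites), multiplicity=w))
    return jobs


@njit(cache=True)
def _complete_kernel(prefix, state0, m0, n, counts):  # pragma: no cover - compiled
    # Iterative DFS completing a canonical prefix to n steps, accumulating
    # counts[m, r2] with the orbit weight *relative to the prefix*.
    off = n + 1
    side = 2 * n + 3
    occ = np.zeros((side, side, side), dtype=np.uint8)
    for i in range(prefix.shape[0]):
        occ[prefix[i, 0] + off, prefix[i, 1] + off, prefix[i, 2] + off] = 1

    p = prefix.shape[0] - 1  # steps already placed
    sx = np.zeros(n + 1, dtype=np.int64)
    sy = np.zeros(n + 1, dtype=np.int64)
    sz = np.zeros(n + 1, dtype=np.int64)
    sdir = np.zeros(n + 1, dtype=np.int64)
    sstate = np.zeros(n + 1, dtype=np.int64)
    sm = np.zeros(n + 1, dtype=np.int64)
    sw = np.zeros(n + 1, dtype=np.int64)

    depth = p
    sx[depth] = prefix[p, 0]
    sy[depth] = prefix[p, 1]
    sz[depth] = prefix[p, 2]
    sdir[depth] = 0
    sstate[depth] = state0
    sm[depth] = m0
    sw[depth] = 1

    while depth >= p:
        if depth == n:
            r2 = sx[depth] ** 2 + sy[depth] ** 2 + sz[depth] ** 2
            counts[sm[depth], r2] += sw[depth]
            occ[sx[depth] + off, sy[depth] + off, sz[depth] + off] = 0
            depth -= 1
            continue
        d = sdir[depth]
        if d >= 6:
            if depth > p:
                occ[sx[depth] + off, sy[depth] + off, sz[depth] + off] = 0
            depth -= 1
            continue
        sdir[depth] = d + 1
        st = sstate[depth]
        if st == 0 and d > 2:
            continue
        if st == 1 and d == 5:
            continue
        nx, ny, nz = sx[depth], sy[depth], sz[depth]
        if d == 0:
            nx += 1
        elif d == 1:
            nx -= 1
        elif d == 2:
            ny += 1
        elif d == 3:
            ny -= 1
        elif d == 4:
            nz += 1
        else:
            nz -= 1
        if occ[nx + off, ny + off, nz + off] == 1:
            continue
        gained = (
            occ[nx + 1 + off, ny + off, nz + off]
            + occ[nx - 1 + off, ny + off, nz + off]
            + occ[nx + off, ny + 1 + off, nz + off]
            + occ[nx + off, ny - 1 + off, nz + off]
            + occ[nx + off, ny + off, nz + 1 + off]
            + occ[nx + off, ny + off, nz - 1 + off]
            - 1
        )
        nstate = st
        w = sw[depth]
        if st == 0 and d == 2:
            nstate = 1
            w *= 4
        elif st == 1 and d == 4:
            nstate = 2
            w *= 2
        occ[nx + off, ny + off, nz + off] = 1
        depth += 1
        sx[depth] = nx
        sy[depth] = ny
        sz[depth] = nz
        sdir[depth] = 0
        sstate[depth] = nstate
        sm[depth] = sm[depth - 1] + gained
        sw[depth] = w


def run_prefix_job(job: PrefixJob, n_steps: int) -> CoefficientTable:
    """Complete one canonical prefix to ``n_steps``.

    The returned counts are *relative* to the prefix (its own multiplicity is
    not applied); :func:`merge_tables` applies it as the job weight.
    """
    if n_steps < job.prefix.n_steps:
        raise ValueError("n_steps shorter than the prefix")
    walk = job.prefix
    state = _ON_AXIS
    for a, b in zip(walk.sites, walk.sites[1:]):
        d = DIRECTIONS.index(tuple(b[i] - a[i] for i in range(3)))
        state, _ = _step_state(state, d)
    m0 = walk.contacts()
    prefix = np.array(walk.sites, dtype=np.int64)
    counts = np.zeros((4 * n_steps + 5, n_steps * n_steps + 1), dtype=np.int64)
    _complete_kernel(prefix, state, m0, n_steps, counts)
    return _table_from_array(n_steps, counts, generator="reduced-job")


def _table_from_array(n_steps, counts, generator):
    nz = np.nonzero(counts)
    table = {
        (int(m), int(r2)): int(counts[m, r2]) for m, r2 in zip(*nz)
    }
    return CoefficientTable(
        n_steps=n_steps, counts=table, metadata={"generator": generator}
    )


def enumerate_reduced(n_steps: int, prefix_depth: int | None = None) -> CoefficientTable:
    """Exact ``c_{m,R2}`` by symmetry-reduced exhaustive enumeration.

    ``prefix_depth`` only controls the parallel decomposition; the result is
    identical (and exact) for every valid depth.  Default: 2 (or 1 for N=1).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if prefix_depth is None:
        prefix_depth = min(2, n_steps)
    if n_steps > _MAX_STEPS:
        raise ValueError(
            f"n_steps={n_steps} exceeds the supported limit {_MAX_STEPS}; "
            "the enumeration would not finish at desk scale"
        )
    if not (1 <= prefix_depth <= n_steps):
        raise ValueError("prefix_depth must satisfy 1 <= depth <= n_steps")
    if n_steps == 1 or prefix_depth == 1:
        # single job: the fixed first step itself
        job = PrefixJob(
            prefix=LatticeWalk(sites=((0, 0, 0), (1, 0, 0))), multiplicity=1
        )
        table = run_prefix_job(job, n_steps)
    else:
        jobs = list_prefixes(min(prefix_depth, n_steps))
        parts = [(run_prefix_job(j, n_steps), j.multiplicity) for j in jobs]
        table = merge_tables(parts)
    table.metadata.update(
        {"generator": "reduced", "prefix_depth": prefix_depth}
    )
    table.validate()
    return table


def enumerate_bruteforce(n_steps: int) -> CoefficientTable:
    """Naive oracle: plain DFS with fixed first step, no symmetry reduction.

    Deliberately independent of the reduced path — contacts are recomputed
    from scratch for every completed walk.  Practical only for N <~ 10.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps > 10:
        raise ValueError("brute-force oracle is limited to n_steps <= 10")
    counts: dict[tuple[int, int], int] = {}

    def pair_contacts(sites):
        m = 0
        for i in range(len(sites)):
            for j in range(i + 2, len(sites)):
                a, b = sites[i], sites[j]
                if abs(a[0] - b[0]) + abs(a[1] - b[1]) + abs(a[2] - b[2]) == 1:
                    m += 1
        return m

    def rec(sites, occ):
        if len(sites) - 1 == n_steps:
            x, y, z = sites[-1]
            key = (pair_contacts(sites), x * x + y * y + z * z)
            counts[key] = counts.get(key, 0) + 1
            return
        x, y, z = sites[-1]
        for dx, dy, dz in DIRECTIONS:
            nxt = (x + dx, y + dy, z + dz)
            if nxt in occ:
                continue
            occ.add(nxt)
            sites.append(nxt)
            rec(sites, occ)
            sites.pop()
            occ.remove(nxt)

    start = [(0, 0, 0), (1, 0, 0)]
    rec(start, set(start))
    table = CoefficientTable(
        n_steps=n_steps, counts=counts, metadata={"generator": "bruteforce"}
    )
    table.validate()
    return table


def merge_tables(parts) -> CoefficientTable:
    """Entrywise weighted integer sum of per-job tables (exact).

    ``parts`` is a list of ``(CoefficientTable, weight)`` pairs or of bare
    tables (weight 1).  All parts must share ``n_steps``.
    """
    if not parts:
        raise ValueError("nothing to merge")
    norm = []
    for p in parts:
        if isinstance(p, CoefficientTable):
            norm.append((p, 1))
        else:
            norm.append((p[0], int(p[1])))
    n = norm[0][0].n_steps
    if any(t.n_steps != n for t, _ in norm):
        raise ValueError("mismatched n_steps in merge")
    acc: dict[tuple[int, int], int] = {}
    for t, w in norm:
        for key, c in t.counts.items():
            acc[key] = acc.get(key, 0) + w * c
    return CoefficientTable(
        n_steps=n, counts=acc, metadata={"generator": "merged", "parts": len(norm)}
    )
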