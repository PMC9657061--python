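"""Neville and Bulirsch-Stoer extrapolation of finite-size series to N -> oo.

Finite-size estimates T(N) are modelled as ``T(h) = T_inf + a1 h + a2 h^2 + ...``
in the scaling variable ``h = N^(-omega)``.  The Neville tableau extrapolates
with the interpolating polynomial evaluated at h = 0; Bulirsch-Stoer inserts
a correction term into the denominator so the extrapolant becomes a rational
function of h, which models scaling series far better than a polynomial.

With points ascending in N (h strictly decreasing) and the pre-column
``T_{i,-1} = 0``, the recursions at h = 0 read

    Neville:        T_{i,j} = T_{i+1,j-1} + (T_{i+1,j-1} - T_{i,j-1}) /
                              [ (N_{i+j}/N_i)^omega - 1 ]
    Bulirsch-Stoer: T_{i,j} = T_{i+1,j-1} + (T_{i+1,j-1} - T_{i,j-1}) /
                              [ (N_{i+j}/N_i)^omega
                                (1 - (T_{i+1,j-1}-T_{i,j-1})/(T_{i+1,j-1}-T_{i,j-2}))
                                - 1 ]

The quoted error of the k-point extrapolant ``T_{0,k-1}`` is
``|T_{0,k-2} - T_{1,k-2}|``, the spread of the two (k-1)-point extrapolants.

The free exponent omega is fixed by a parity-paired scan: odd- and even-step
chains form two independent series; both are extrapolated at each omega and
the combined error ``sqrt(eps_I^2 + eps_II^2)/2`` is minimized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .crossing import CrossingSeries
from .observables import dlog_r_dT, poly_from_table

__all__ = [
    "Tableau",
    "ScanRow",
    "PhiSeries",
    "neville",
    "bulirsch_stoer",
    "build_tableau",
    "scan_omega",
    "scan_refined",
    "phi_series",
]

_METHODS = ("neville", "bulirsch_stoer")

# Below this magnitude a Bulirsch-Stoer denominator is treated as degenerate
# and the cell falls back to the Neville update (the continuity limit of the
# correction factor -> 1).
_DEGENERATE = 1e-300


@dataclass(frozen=True)
class Tableau:
    """A triangular extrapolation tableau; column 0 holds the input series."""

    method: str
    omega: float
    n_values: tuple[int, ...]
    columns: tuple[tuple[float, ...], ...]

    @property
    def value(self) -> float:
        """The k-point extrapolant T_{0,k-1}."""
        return self.columns[-1][0]

    @property
    def error(self) -> float:
        """|T_{0,k-2} - T_{1,k-2}|, spread of the two (k-1)-point extrapolants."""
        if len(self.columns) < 2:
            return math.inf
        prev = self.columns[-2]
        return abs(prev[0] - prev[1])


@dataclass(frozen=True)
class ScanRow:
    """One omega of the parity-paired scan (mirrors the scan report columns)."""

    omega: float
    t_odd: float
    t_even: float
    err_odd: float
    err_even: float

    @property
    def mean(self) -> float:
        return 0.5 * (self.t_odd + self.t_even)

    @property
    def combined_error(self) -> float:
        return 0.5 * math.hypot(self.err_odd, self.err_even)


@dataclass
class PhiSeries:
    """Finite-size crossover-exponent estimates phi(N) at a fixed T_theta."""

    points: list[tuple[int, float]]
    t_theta: float

    def parity(self, which: str) -> list[tuple[int, float]]:
        want = 1 if which == "odd" else 0
        return [(n, p) for n, p in self.points if n % 2 == want]


def _check_points(values):
    ns = [n for n, _ in values]
    if len(ns) < 2:
        raise ValueError("need at least two points")
    if len(set(ns)) != len(ns):
        raise ValueError("duplicate N in series")
    if ns != sorted(ns):
        raise ValueError("points must be sorted by ascending N")
    return ns, [t for _, t in values]


def build_tableau(values, omega: float, method: str = "bulirsch_stoer") -> Tableau:
    """Run the full recursion; ``values`` is a sequence of (N, T(N))."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    if not omega > 0:
        raise ValueError("omega must be positive")
    ns, ts = _check_points(values)
    k = len(ns)
    columns = [list(ts)]
    prev2 = [0.0] * k  # T_{i,-1}
    for j in range(1, k):
        prev = columns[-1]
        col = []
        for i in range(k - j):
            a = prev[i + 1]  # T_{i+1,j-1}
            b = prev[i]      # T_{i,j-1}
            ratio = (ns[i + j] / ns[i]) ** omega
            if method == "neville":
                denom = ratio - 1.0
            else:
                inner = a - prev2[i]  # T_{i+1,j-1} - T_{i,j-2}
                if abs(inner) < _DEGENERATE:
                    denom = ratio - 1.0
                else:
                    denom = ratio * (1.0 - (a - b) / inner) - 1.0
                    if abs(denom) < _DEGENERATE:
                        denom = ratio - 1.0
            col.append(a + (a - b) / denom)
        prev2 = prev
        columns.append(col)
    return Tableau(
        method=method,
        omega=float(omega),
        n_values=tuple(ns),
        columns=tuple(tuple(c) for c in columns),
    )


def neville(values, omega: float) -> tuple[float, float]:
    """Polynomial (Neville) extrapolation to h = 0; returns (value, error)."""
    tab = build_tableau(values, omega, method="neville")
    return tab.value, tab.error


def bulirsch_stoer(values, omega: float) -> tuple[float, float]:
    """Rational (Bulirsch-Stoer) extrapolation to h = 0; returns (value, error)."""
    tab = build_tableau(values, omega, method="bulirsch_stoer")
    return tab.value, tab.error


def _series_points(series):
    if isinstance(series, CrossingSeries):
        return series.points
    return list(series)


def scan_omega(odd, even, grid, method: str = "bulirsch_stoer"):
    """One ScanRow per omega; best row minimizes the combined error.

    ``odd``/``even`` are CrossingSeries or plain sequences of (N, value).
    Ties break toward smaller omega; omegas where a recursion degenerates to
    a non-finite value are dropped from the ranking.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty omega grid")
    if grid != sorted(grid):
        raise ValueError("omega grid must be sorted")
    po, pe = _series_points(odd), _series_points(even)
    if not po or not pe:
        raise ValueError("both parity series must be nonempty")
    rows = []
    for om in grid:
        t1, e1 = (neville if method == "neville" else bulirsch_stoer)(po, om)
        t2, e2 = (neville if method == "neville" else bulirsch_stoer)(pe, om)
        rows.append(ScanRow(omega=om, t_odd=t1, t_even=t2, err_odd=e1, err_even=e2))
    finite = [
        r
        for r in rows
        if math.isfinite(r.mean) and math.isfinite(r.combined_error)
    ]
    if not finite:
        raise ValueError("no omega produced a finite extrapolant")
    best = min(finite, key=lambda r: (r.combined_error, r.omega))
    return rows, best


def scan_refined(
    odd,
    even,
    method: str = "bulirsch_stoer",
    omega_range: tuple[float, float] = (0.1, 3.0),
    coarse_step: float = 0.01,
    final_step: float = 1e-4,
) -> ScanRow:
    """Coarse scan then iterative x10 zoom around the minimum.

    Mirrors the two-stage protocol: a wide grid locates the small-error
    region, which is then refined until the grid step reaches ``final_step``.
    """
    lo, hi = omega_range
    step = coarse_step
    best = None
    while True:
        npts = int(round((hi - lo) / step)) + 1
        grid = [lo + i * step for i in range(npts)]
        grid = [om for om in grid if om > 0]
        _, best = scan_omega(odd, even, grid, method=method)
        if step <= final_step:
            return best
        lo, hi, step = best.omega - step, best.omega + step, step / 10.0


def phi_series(tables: dict, t_theta: float = 3.713) -> PhiSeries:
    """Finite-size crossover exponent by the ratio method.

    phi(N) = log[ (dlogR/dT)|_{N+1} / (dlogR/dT)|_{N-1} ] / log[(N+1)/(N-1)],
    with both derivatives evaluated analytically at the fixed ``t_theta``.
    The result is invariant to using log R or log R^2 (the 1/2 cancels).
    """
    if not t_theta > 0:
        raise ValueError("t_theta must be positive")
    from .observables import PolyPair

    def as_poly(n):
        obj = tables[n]
        return obj if isinstance(obj, PolyPair) else poly_from_table(obj)

    available = sorted(tables)
    points = []
    for n in available:
        if n - 1 in tables and n + 1 in tables:
            d_hi = dlog_r_dT(as_poly(n + 1), t_theta)
            d_lo = dlog_r_dT(as_poly(n - 1), t_theta)
            if d_hi <= 0 or d_lo <= 0:
                raise ValueError(f"nonpositive derivative ratio at N={n}")
            points.append(
                (n, math.log(d_hi / d_lo) / math.log((n + 1) / (n - 1)))
            )
    return PhiSeries(points=points, t_theta=t_theta)
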