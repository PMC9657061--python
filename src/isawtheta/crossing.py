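"""Finite-size theta-temperature estimates from the crossing equation.

At the theta point ``<R^2>_N ~ N``, so the per-step mean-square end-to-end
distance of two chains crosses there.  Restricting to chains of equal parity
(odd- and even-step walks terminate on disjoint sublattices of the cubic
lattice) and to the closest pair ``N' = N - 2``, the finite-size estimate
``T*(N)`` solves

    <R^2>_{N+1}(T*) / D(N+1) = <R^2>_{N-1}(T*) / D(N-1),

where ``D(n) = n`` plain, or ``D(n) = n (1 - 37/(363 ln n))`` with the
field-theoretic renormalization-group logarithmic correction switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .observables import PolyPair, mean_square_r, poly_from_table

__all__ = [
    "CrossingSeries",
    "NoCrossingError",
    "AmbiguousCrossingError",
    "log_correction_factor",
    "crossing_residual",
    "solve_t_star",
    "build_series",
]

_CORRECTIONS = ("none", "log")


class NoCrossingError(RuntimeError):
    """The residual does not change sign inside the bracket."""


class AmbiguousCrossingError(RuntimeError):
    """More than one sign change detected inside the bracket."""


@dataclass
class CrossingSeries:
    """Parity-labelled finite-size theta estimates (N, T*(N)), ascending N."""

    parity: str  # "odd" | "even"
    points: list[tuple[int, float]] = field(default_factory=list)
    correction: str = "none"

    def __post_init__(self):
        if self.parity not in ("odd", "even"):
            raise ValueError("parity must be 'odd' or 'even'")
        want = 1 if self.parity == "odd" else 0
        ns = [n for n, _ in self.points]
        if any(n % 2 != want for n in ns):
            raise ValueError(f"every N must be {self.parity}")
        if ns != sorted(ns) or any(b - a != 2 for a, b in zip(ns, ns[1:])):
            raise ValueError("points must ascend in steps of 2")

    @property
    def n_values(self) -> list[int]:
        return [n for n, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [t for _, t in self.points]


def log_correction_factor(n: int) -> float:
    """Multiplicative logarithmic correction 1 - 37/(363 ln n) to the step count."""
    return 1.0 - 37.0 / (363.0 * math.log(n))


def _norm(n: int, correction: str) -> float:
    if correction == "none":
        return float(n)
    if correction == "log":
        return n * log_correction_factor(n)
    raise ValueError(f"unknown correction {correction!r}")


def crossing_residual(
    poly_hi: PolyPair, poly_lo: PolyPair, T, correction: str = "none"
) -> float:
    """``<R^2>_{N+1}(T)/D(N+1) - <R^2>_{N-1}(T)/D(N-1)``."""
    if poly_hi.n_steps - poly_lo.n_steps != 2:
        raise ValueError("polynomials must be two steps apart")
    return mean_square_r(poly_hi, T) / _norm(poly_hi.n_steps, correction) - (
        mean_square_r(poly_lo, T) / _norm(poly_lo.n_steps, correction)
    )


def solve_t_star(
    poly_hi: PolyPair,
    poly_lo: PolyPair,
    correction: str = "none",
    bracket: tuple[float, float] = (1.0, 20.0),
    tol: float = 1e-10,
) -> float:
    """Unique root of the crossing residual inside ``bracket``.

    A 200-point scan guards against a missing or ambiguous crossing before
    the bracketed root find (Brent: bisection safeguarded by inverse
    interpolation) polishes to ``|dT| <= tol``.
    """
    lo, hi = bracket
    npts = 200
    ts = [lo + (hi - lo) * i / (npts - 1) for i in range(npts)]
    vals = [crossing_residual(poly_hi, poly_lo, t, correction) for t in ts]
    sign_changes = [
        i for i in range(npts - 1) if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0.0
    ]
    if not sign_changes:
        raise NoCrossingError(
            f"no crossing for N={poly_hi.n_steps}/{poly_lo.n_steps} in {bracket}"
        )
    if len(sign_changes) > 1:
        raise AmbiguousCrossingError(
            f"multiple crossings for N={poly_hi.n_steps}/{poly_lo.n_steps} in {bracket}"
        )
    i = sign_changes[0]
    return float(
        brentq(
            lambda t: crossing_residual(poly_hi, poly_lo, t, correction),
            ts[i],
            ts[i + 1],
            xtol=tol,
        )
    )


def build_series(
    tables: dict,
    n_min: int,
    n_max: int,
    correction: str = "none",
    bracket: tuple[float, float] = (1.0, 20.0),
    tol: float = 1e-10,
) -> tuple[CrossingSeries, CrossingSeries]:
    """T*(N) for every N in [n_min, n_max] with both N-1 and N+1 available.

    ``tables`` maps chain length to a CoefficientTable (or PolyPair).  Returns
    the odd- and even-parity series.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")

    def as_poly(n):
        if n not in tables:
            raise KeyError(f"missing coefficient table for N={n}")
        obj = tables[n]
        return obj if isinstance(obj, PolyPair) else poly_from_table(obj)

    odd = CrossingSeries(parity="odd", correction=correction)
    even = CrossingSeries(parity="even", correction=correction)
    for n in range(n_min, n_max + 1):
        for need in (n - 1, n + 1):
            if need not in tables:
                raise KeyError(f"missing coefficient table for N={need}")
        t_star = solve_t_star(
            as_poly(n + 1), as_poly(n - 1), correction, bracket, tol
        )
        (odd if n % 2 else even).points.append((n, t_star))
    return odd, even
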