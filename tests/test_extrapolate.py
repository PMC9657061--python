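"""Neville / Bulirsch-Stoer tableaus, the omega scan, and the phi ratio method."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isawtheta import (
    build_tableau,
    bulirsch_stoer,
    dlog_r_dT,
    neville,
    phi_series,
    poly_from_table,
    scan_omega,
    scan_refined,
)

ODD_N = (11, 13, 15, 17, 19, 21, 23, 25)


def series(fn, omega, ns=ODD_N):
    return [(n, fn(n ** -omega)) for n in ns]


class TestExactRecovery:
    @pytest.mark.parametrize("method", [neville, bulirsch_stoer])
    def test_constant_series(self, method):
        value, error = method([(n, 3.3) for n in ODD_N], omega=1.1)
        assert value == pytest.approx(3.3, abs=1e-12)
        assert error == pytest.approx(0.0, abs=1e-12)

    def test_h_linear_series(self):
        """T + a h with matching omega: Neville is exact; the zero-initialized
        Bulirsch-Stoer recursion converges to it with a tiny intrinsic residual."""
        data = series(lambda h: 3.7 + 2.0 * h, 0.8)
        nev_value, _ = neville(data, omega=0.8)
        assert nev_value == pytest.approx(3.7, abs=1e-10)
        bs_value, _ = bulirsch_stoer(data, omega=0.8)
        assert bs_value == pytest.approx(3.7, abs=1e-7)

    def test_polynomial_series_neville(self):
        value, _ = neville(
            series(lambda h: 3.7 + 2 * h - 1.3 * h**2 + 0.7 * h**3, 0.8), omega=0.8
        )
        assert value == pytest.approx(3.7, abs=1e-9)

    def test_rational_series_distinguishes_methods(self):
        """Bulirsch-Stoer nails (a+bh)/(1+ch); Neville demonstrably does not."""
        data = series(lambda h: (3.7 + 2.0 * h) / (1 + 5.0 * h), 0.8)
        bs_value, _ = bulirsch_stoer(data, omega=0.8)
        nev_value, _ = neville(data, omega=0.8)
        assert bs_value == pytest.approx(3.7, abs=1e-6)
        assert abs(nev_value - 3.7) > 1e-4  # polynomial form cannot model it

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        t_inf=st.floats(1.0, 5.0),
        slope=st.floats(-3.0, 3.0),
        omega=st.floats(0.5, 2.5),
    )
    def test_h_linear_recovery_property(self, t_inf, slope, omega):
        """Neville is an exact polynomial interpolant: h-linear data always
        extrapolates to the true limit."""
        data = series(lambda h: t_inf + slope * h, omega)
        value, _ = neville(data, omega=omega)
        assert value == pytest.approx(t_inf, abs=1e-7)


class TestTableauStructure:
    def test_neville_equals_interpolating_polynomial_at_zero(self):
        """The k-point Neville extrapolant is the Lagrange polynomial at h=0."""
        rng = np.random.default_rng(7)
        ns = ODD_N[:5]
        ts = 3.7 + rng.normal(0, 0.05, len(ns))
        omega = 0.9
        h = np.array([n ** -omega for n in ns])
        coeffs = np.polynomial.polynomial.polyfit(h, ts, len(ns) - 1)
        value, _ = neville(list(zip(ns, ts)), omega=omega)
        assert value == pytest.approx(coeffs[0], rel=1e-8)

    @pytest.mark.parametrize("method", ["neville", "bulirsch_stoer"])
    def test_error_is_subtableau_spread(self, method):
        """eps = |T_{0,k-2} - T_{1,k-2}|: the two (k-1)-point extrapolants."""
        rng = np.random.default_rng(3)
        data = [(n, 3.7 + 2.0 * n**-0.8 + rng.normal(0, 1e-3)) for n in ODD_N]
        full = build_tableau(data, 0.9, method=method)
        head = build_tableau(data[:-1], 0.9, method=method)
        tail = build_tableau(data[1:], 0.9, method=method)
        assert full.error == pytest.approx(abs(head.value - tail.value), rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            neville([(11, 2.4)], omega=1.0)
        with pytest.raises(ValueError):
            neville([(11, 2.4), (11, 2.5)], omega=1.0)
        with pytest.raises(ValueError):
            neville([(13, 2.5), (11, 2.4)], omega=1.0)
        with pytest.raises(ValueError):
            bulirsch_stoer([(11, 2.4), (13, 2.5)], omega=-1.0)
        with pytest.raises(ValueError):
            build_tableau([(11, 2.4), (13, 2.5)], 1.0, method="romberg")


class TestScan:
    def test_rows_and_tie_breaking(self):
        odd = [(n, 3.3) for n in ODD_N]
        even = [(n, 3.4) for n in (12, 14, 16, 18)]
        grid = [0.5, 1.0, 1.5]
        rows, best = scan_omega(odd, even, grid)
        assert [r.omega for r in rows] == grid
        assert all(r.combined_error == pytest.approx(0.0, abs=1e-12) for r in rows)
        assert best.omega == 0.5  # ties break toward smaller omega
        assert best.mean == pytest.approx(3.35, abs=1e-12)

    def test_scan_recovers_shared_limit(self):
        omega = 0.8
        odd = series(lambda h: 3.7 + 2.0 * h, omega)
        even = series(lambda h: 3.7 - 1.5 * h, omega, ns=(12, 14, 16, 18, 20, 22, 24, 26))
        best = scan_refined(odd, even)
        assert best.mean == pytest.approx(3.7, abs=1e-6)
        assert best.omega == pytest.approx(omega, abs=0.01)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            scan_omega([(11, 2.4), (13, 2.5)], [], [1.0])
        with pytest.raises(ValueError):
            scan_omega([(11, 2.4), (13, 2.5)], [(12, 2.4), (14, 2.5)], [])
        with pytest.raises(ValueError):
            scan_omega(
                [(11, 2.4), (13, 2.5)], [(12, 2.4), (14, 2.5)], [2.0, 1.0]
            )


class TestPhiRatio:
    def test_published_small_chain_values(self, reduced_tables):
        ph = phi_series({n: t for n, t in reduced_tables.items() if n >= 9}, 3.713)
        values = dict(ph.points)
        assert values[11] == pytest.approx(0.8944, abs=1e-4)
        assert values[12] == pytest.approx(0.8107, abs=1e-4)

    def test_invariant_to_rms_vs_mean_square(self, reduced_tables):
        """phi from d log R and from d log <R^2> coincide (the 1/2 cancels)."""
        polys = {n: poly_from_table(t) for n, t in reduced_tables.items()}
        t_theta = 3.713
        n = 11
        num = 2.0 * dlog_r_dT(polys[n + 1], t_theta)  # d log <R^2> / dT
        den = 2.0 * dlog_r_dT(polys[n - 1], t_theta)
        phi_sq = math.log(num / den) / math.log((n + 1) / (n - 1))
        ph = phi_series({m: t for m, t in reduced_tables.items() if m >= 9}, t_theta)
        assert dict(ph.points)[n] == pytest.approx(phi_sq, rel=1e-13)

    def test_parity_accessor(self, reduced_tables):
        ph = phi_series({n: t for n, t in reduced_tables.items() if n >= 9}, 3.713)
        assert all(n % 2 == 1 for n, _ in ph.parity("odd"))
        assert all(n % 2 == 0 for n, _ in ph.parity("even"))

    def test_invalid_t_theta(self, reduced_tables):
        with pytest.raises(ValueError):
            phi_series(reduced_tables, -1.0)

    def test_degenerate_derivative_is_explicit(self, reduced_tables):
        # a 1-step chain has constant R, so the ratio at N=2 is undefined
        with pytest.raises(ValueError, match="N=2"):
            phi_series({n: reduced_tables[n] for n in (1, 2, 3)}, 3.713)
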