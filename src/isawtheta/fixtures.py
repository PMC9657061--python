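"""Published finite-size series, embedded as immutable fixtures.

These are the printed 4-decimal values of the finite-size theta temperatures
(plain and log-corrected crossing equations) and of the finite-size crossover
exponent at T_theta = 3.713, for chain midpoints N = 11..26.  They let the
whole extrapolation stack run and be tested without any enumeration cost.

Note the precision caveat: the values carry +-5e-5 rounding, which the
extrapolation tableaus amplify substantially (see docs/methods.md).
"""

from __future__ import annotations

from .crossing import CrossingSeries
from .extrapolate import PhiSeries

__all__ = [
    "theta_series_plain",
    "theta_series_corrected",
    "phi_series_fixture",
    "PHI_T_THETA",
]

# Plain crossing equation, T*(N), N odd then even.
_T1_ODD = (
    (11, 2.3826), (13, 2.4961), (15, 2.5904), (17, 2.6697),
    (19, 2.7375), (21, 2.7962), (23, 2.8474), (25, 2.8926),
)
_T1_EVEN = (
    (12, 2.3710), (14, 2.4889), (16, 2.5860), (18, 2.6670),
    (20, 2.7358), (22, 2.7951), (24, 2.8468), (26, 2.8923),
)

# Log-corrected crossing equation.
_T3_ODD = (
    (11, 2.5421), (13, 2.6345), (15, 2.7135), (17, 2.7811),
    (19, 2.8396), (21, 2.8907), (23, 2.9356), (25, 2.9754),
)
_T3_EVEN = (
    (12, 2.5112), (14, 2.6137), (16, 2.6989), (18, 2.7705),
    (20, 2.8316), (22, 2.8845), (24, 2.9307), (26, 2.9715),
)

# Crossover exponent ratio estimates at fixed T_theta = 3.713.
PHI_T_THETA = 3.713
_T4 = (
    (11, 0.8944), (12, 0.8107), (13, 0.8350), (14, 0.7753),
    (15, 0.7936), (16, 0.7485), (17, 0.7628), (18, 0.7271),
    (19, 0.7387), (20, 0.7097), (21, 0.7192), (22, 0.6951),
    (23, 0.7032), (24, 0.6826), (25, 0.6896), (26, 0.6719),
)


def theta_series_plain() -> tuple[CrossingSeries, CrossingSeries]:
    """(odd, even) finite-size theta series from the plain crossing equation."""
    return (
        CrossingSeries(parity="odd", points=list(_T1_ODD), correction="none"),
        CrossingSeries(parity="even", points=list(_T1_EVEN), correction="none"),
    )


def theta_series_corrected() -> tuple[CrossingSeries, CrossingSeries]:
    """(odd, even) series from the log-corrected crossing equation."""
    return (
        CrossingSeries(parity="odd", points=list(_T3_ODD), correction="log"),
        CrossingSeries(parity="even", points=list(_T3_EVEN), correction="log"),
    )


def phi_series_fixture() -> PhiSeries:
    """Finite-size crossover-exponent series at T_theta = 3.713."""
    return PhiSeries(points=list(_T4), t_theta=PHI_T_THETA)
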