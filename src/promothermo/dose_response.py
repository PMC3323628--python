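"""Dose-response analysis for a promoter with two identical binding sites.

A single activator species binding two identical promoter sites is the
two-activator model with x_A = x_B = x and w_A = w_B = w.  The double-site
occupancy is compared against twice the occupancy of a one-site reference
promoter with the same x_P and w,

    p_single = x_P (1 + x w) / (x_P (1 + x w) + 1 + x),

through the dose-resolved synergy D(x) = p_double(x) - 2 p_single(x) and the
Chi-Carey ratio p_double / (2 p_single).  Depending on x_P, w and the omega
factors the sign of D(x) follows one of three patterns as the dose grows:
always negative (less-than-additive), one crossover to positive, or the
re-entrant sequence negative / positive / negative.

With neutral omega factors the critical doses have a closed form: the
single-stimulation odds u(x) = x_P (1 + w x)/(1 + x) must enter the window
(u-, u+) with u+- = (1 -+ sqrt(1 - 8 x_P))/2, and each attained window edge
u_c maps to the dose x_c = (u_c - x_P)/(x_P w - u_c).  With a pure
three-body interaction (w = 1, omega_tf = 1) a single crossover exists
exactly when omega3 (1 - x_P) > 2, at

    x* = (m + sqrt(m (m + omega3 - c))) / (omega3 - c),
    c = 2/(1 - x_P),  m = c - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .two_activator import TwoActivatorSystem, occupancy_two

__all__ = [
    "DoubleSiteSystem",
    "DoseResponseCurve",
    "double_site_occupancy",
    "single_site_occupancy",
    "dose_synergy",
    "critical_dose_three_body",
    "critical_xp_line_three_body",
    "critical_doses_nonlinearity",
    "find_critical_doses",
    "classify_dose_pattern",
    "synergy_ratio",
    "dose_response_curve",
]

#: Default log-dose bracketing grid for numeric root finding.
DOSE_GRID = (1e-6, 1e6, 400)

_PATTERNS = {0: "less_than_additive", 1: "single_crossover", 2: "re_entrant"}


@dataclass(frozen=True)
class DoubleSiteSystem:
    """Promoter with two identical sites for one activator species.

    ``x`` is the shared relative activator dose, ``w`` the per-site TF-RNAP
    factor, ``omega_tf`` the site-site TF-TF factor and ``omega3`` the
    three-body factor active when both sites and RNAP are occupied.
    """

    x_P: float
    x: float
    w: float = 1.0
    omega_tf: float = 1.0
    omega3: float = 1.0

    def __post_init__(self):
        for name in ("x_P", "x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("w", "omega_tf", "omega3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def as_two_activator(self, x: float | None = None) -> TwoActivatorSystem:
        dose = self.x if x is None else x
        return TwoActivatorSystem(
            x_P=self.x_P, x_A=dose, x_B=dose,
            w_A=self.w, w_B=self.w,
            omega_AB=self.omega_tf, omega3=self.omega3,
        )


@dataclass
class DoseResponseCurve:
    """Tabulated dose response with critical-dose annotations."""

    rows: pd.DataFrame
    critical_doses: tuple[float, ...]
    pattern: str

    def __post_init__(self):
        doses = self.critical_doses
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("critical doses must be strictly increasing")
        if _PATTERNS.get(len(doses)) != self.pattern:
            raise ValueError(
                f"pattern {self.pattern!r} inconsistent with {len(doses)} critical doses"
            )


def double_site_occupancy(sys: DoubleSiteSystem, x: float | None = None) -> float:
    """RNAP occupancy of the double-site promoter (two-activator special case)."""
    return occupancy_two(sys.as_two_activator(x))


def single_site_occupancy(x_P: float, x: float, w: float) -> float:
    """RNAP occupancy of the one-site reference promoter.

    p = x_P (1 + x w) / (x_P (1 + x w) + 1 + x); monotone non-decreasing in
    x for w >= 1, saturating at x_P w / (1 + x_P w).
    """
    if x_P < 0 or x < 0 or w <= 0:
        raise ValueError("require x_P >= 0, x >= 0, w > 0")
    if math.isinf(x):
        r = x_P * w
        return r / (1.0 + r)
    on = x_P * (1.0 + x * w)
    return on / (on + 1.0 + x)


def dose_synergy(sys: DoubleSiteSystem, x: float | None = None) -> float:
    """D(x) = p_double(x) - 2 p_single(x); its sign classifies the dose."""
    dose = sys.x if x is None else x
    return double_site_occupancy(sys, dose) - 2.0 * single_site_occupancy(sys.x_P, dose, sys.w)


def synergy_ratio(sys: DoubleSiteSystem, x: float | None = None) -> float:
    """Chi-Carey synergy measure p_double / (2 p_single); > 1 iff D > 0."""
    dose = sys.x if x is None else x
    p_single = single_site_occupancy(sys.x_P, dose, sys.w)
    if p_single == 0.0:
        raise ValueError("synergy ratio undefined at zero single-site occupancy (x_P = 0)")
    return double_site_occupancy(sys, dose) / (2.0 * p_single)


# ---------------------------------------------------------------------------
# Closed-form critical doses


def critical_dose_three_body(x_P: float, omega3: float) -> float | None:
    """Crossover dose for a pure three-body interaction (w = 1, omega_tf = 1).

    The unique positive root of D(x) exists exactly when
    omega3 (1 - x_P) > 2; for x_P >= 1 the response is less than additive at
    every dose.  Closed quadratic-root form (validated against bisection).
    """
    if x_P <= 0:
        raise ValueError(f"x_P must be > 0, got {x_P}")
    if omega3 <= 0:
        raise ValueError(f"omega3 must be > 0, got {omega3}")
    if x_P >= 1.0:
        return None
    c = 2.0 / (1.0 - x_P)
    if omega3 <= c:  # existence threshold omega3 (1 - x_P) > 2
        return None
    m = c - 1.0
    a = omega3 - c
    return (m + math.sqrt(m * (m + a))) / a


def critical_xp_line_three_body(omega3: float) -> float | None:
    """Largest x_P admitting a three-body crossover: x_P* = 1 - 2/omega3.

    None for omega3 <= 2 (no crossover at any RNAP concentration); tends to
    the asymptote 1 as omega3 -> infinity.
    """
    if omega3 <= 0:
        raise ValueError(f"omega3 must be > 0, got {omega3}")
    if omega3 <= 2.0:
        return None
    return 1.0 - 2.0 / omega3


def critical_doses_nonlinearity(x_P: float, w: float) -> list[float]:
    """All positive roots of D(x) with neutral omega factors, ascending.

    The single-stimulation odds u(x) = x_P (1 + w x)/(1 + x) runs from x_P
    to x_P w; D > 0 exactly while u lies in the window (u-, u+) with
    u+- = (1 -+ sqrt(1 - 8 x_P))/2, which exists only for x_P < 1/8.  Each
    attained window edge maps back to the dose (u - x_P)/(x_P w - u).
    Zero roots for x_P >= 1/8 (hence for x_P >= 1/2); one root when the
    saturated odds stop inside the window (x_P < (w-2)/w^2); two roots when
    they pass beyond it (re-entrant).
    """
    if x_P <= 0 or w <= 0:
        raise ValueError("require x_P > 0 and w > 0")
    if x_P >= 0.125:
        return []
    disc = math.sqrt(1.0 - 8.0 * x_P)
    u_sat = x_P * w
    roots = []
    for u_edge in ((1.0 - disc) / 2.0, (1.0 + disc) / 2.0):
        if x_P < u_edge < u_sat:
            roots.append((u_edge - x_P) / (u_sat - u_edge))
    return sorted(roots)


def find_critical_doses(
    sys: DoubleSiteSystem,
    grid: tuple[float, float, int] = DOSE_GRID,
    xtol: float = 1e-12,
) -> list[float]:
    """Numeric roots of D(x): sign-change bracketing on a log-dose grid.

    400 log-spaced doses by default, each sign change refined by bisection
    (Brent) to ``xtol`` absolute in log-dose.  D is smooth with at most two
    roots in every regime examined, so bracketing is exhaustive.
    """
    lo, hi, n = grid
    xs = np.logspace(math.log10(lo), math.log10(hi), int(n))
    ds = np.array([dose_synergy(sys, x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if ds[i] == 0.0:
            roots.append(xs[i])
        elif ds[i] * ds[i + 1] < 0.0:
            lg = brentq(
                lambda t: dose_synergy(sys, 10.0**t),
                math.log10(xs[i]), math.log10(xs[i + 1]), xtol=xtol,
            )
            roots.append(10.0**lg)
    return roots


def classify_dose_pattern(
    x_P: float,
    w: float,
    omega_tf: float = 1.0,
    omega3: float = 1.0,
) -> str:
    """Dose-response pattern from the number of crossover doses.

    0 roots -> ``less_than_additive``; 1 -> ``single_crossover``;
    2 -> ``re_entrant``.  Defined on the activator domain (w >= 1, omega
    factors >= 1).  Neutral omega factors use the closed form; otherwise
    the numeric root finder.
    """
    if w < 1.0 or omega_tf < 1.0 or omega3 < 1.0:
        raise ValueError("pattern classification is defined for activators only")
    if x_P <= 0:
        raise ValueError("x_P must be > 0")
    if omega_tf == 1.0 and omega3 == 1.0:
        roots = critical_doses_nonlinearity(x_P, w)
    else:
        roots = find_critical_doses(DoubleSiteSystem(x_P, 0.0, w, omega_tf, omega3))
    return _PATTERNS[len(roots)]


def dose_response_curve(
    sys: DoubleSiteSystem,
    doses: np.ndarray,
) -> DoseResponseCurve:
    """Tabulate occupancies, D, and the Chi-Carey ratio over a dose range."""
    doses = np.asarray(doses, dtype=float)
    rows = pd.DataFrame(
        {
            "x": doses,
            "p_double": [double_site_occupancy(sys, x) for x in doses],
            "p_single": [single_site_occupancy(sys.x_P, x, sys.w) for x in doses],
        }
    )
    rows["D"] = rows["p_double"] - 2.0 * rows["p_single"]
    rows["ratio"] = rows["p_double"] / (2.0 * rows["p_single"])
    if sys.omega_tf == 1.0 and sys.omega3 == 1.0:
        critical = critical_doses_nonlinearity(sys.x_P, sys.w)
    elif sys.w == 1.0 and sys.omega_tf == 1.0:
        root = critical_dose_three_body(sys.x_P, sys.omega3)
        critical = [] if root is None else [root]
    else:
        critical = find_critical_doses(sys)
    return DoseResponseCurve(rows, tuple(critical), _PATTERNS[len(critical)])
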