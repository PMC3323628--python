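"""Critical surfaces separating greater-than- from less-than-additive regimes.

The sign of the synergy difference D admits an exact reformulation.  Writing
``u``, ``v`` for the on/off odds of the two single stimulations and ``S`` for
the odds of the dual stimulation (odds = v_on/v_off), a short calculation
gives

    sign(D) = sign( S (1 - u v) - u - v - 2 u v ).

All closed-form boundaries below are limits of this statistic:

* saturated, equal activators (neutral omega factors): the critical RNAP
  concentration is x_P*(w) = (w - 2) / w^2, zero at w = 2, peaked at
  (w, x_P) = (4, 1/8), decaying to zero as w grows;
* strong activation and low RNAP concentration: the statistic reduces to
  h = omega3 w_A w_B - w_A - w_B, whose zero set is the hyperbola
  w_B = w_A / (omega3 w_A - 1);
* the universal three-body threshold: h > 0 on the whole activator domain
  w_A, w_B > 1 exactly when omega3 >= 2.

Regime classification follows the tabulated case analysis (low TF
concentration, weak activators, high RNAP, weak activation, nonlinearity
cases, and three-body cases) with documented numeric thresholds standing in
for the much-greater/much-less conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .two_activator import TwoActivatorSystem, occupancy_two, synergy_difference

__all__ = [
    "RegimeLabel",
    "BoundaryCurve",
    "synergy_sign_statistic",
    "saturated_sign_statistic",
    "limiting_sign_statistic",
    "critical_xp_equal_activators",
    "critical_xp_vs_energy",
    "two_body_hyperbola",
    "three_body_hyperbola",
    "minimal_universal_three_body_factor",
    "classify_regime",
    "sign_scan_oracle",
    "boundary_curve",
]

# Numeric thresholds standing in for the >> / << regime conditions.
# Adjustable via keyword arguments of classify_regime.
STRONG_ACTIVATION_MIN = 100.0   # x_i * w_i >= 100 counts as strong activation
LOW_POLYMERASE_MAX = 0.01       # x_P <= 0.01 counts as low RNAP concentration
LOW_TF_MAX = 0.01               # x_A, x_B <= 0.01 counts as low TF concentration
WEAK_COMBINED_FACTOR_MAX = 2.0  # w_A * w_B * omega3 <= 2 -> weak activators
WEAK_ACTIVATION_MAX = 1.0       # x_i * w_i <= 1 counts as weak activation
EQUAL_SHIFT_RTOL = 1e-9         # w_A ~ w_B for the equal-activator boundary


@dataclass(frozen=True)
class RegimeLabel:
    """Matched case of the regime table with the predicted sign of D."""

    case_id: str
    predicted_sign: str
    conditions_met: tuple[str, ...] = ()

    def __post_init__(self):
        if self.case_id not in {"1", "2", "3", "4", "5a", "5b", "6", "7a", "7b", "unclassified"}:
            raise ValueError(f"unknown case id {self.case_id!r}")
        if self.predicted_sign not in {"negative", "positive", "either"}:
            raise ValueError(f"unknown sign {self.predicted_sign!r}")


@dataclass
class BoundaryCurve:
    """Sampled critical curve: (free coordinate, critical value) pairs."""

    parameterization: str
    samples: pd.DataFrame
    validity_domain: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.validity_domain
        coord = self.samples["coordinate"].to_numpy()
        crit = self.samples["critical_value"].to_numpy()
        if len(coord) and not ((coord >= lo) & (coord <= hi)).all():
            raise ValueError("samples outside validity domain")
        if len(crit) and not (np.isfinite(crit) & (crit >= 0)).all():
            raise ValueError("critical values must be finite and >= 0")


# ---------------------------------------------------------------------------
# Sign statistics


def _odds(system: TwoActivatorSystem, x_A: float, x_B: float) -> float:
    """On/off odds v_on/v_off at the given doses (x_P factored in)."""
    s = system
    num = 1.0 + x_A * s.w_A + x_B * s.w_B \
        + x_A * x_B * s.w_A * s.w_B * s.omega_AB * s.omega3
    den = 1.0 + x_A + x_B + x_A * x_B * s.omega_AB
    return s.x_P * num / den


def synergy_sign_statistic(system: TwoActivatorSystem) -> float:
    """Quadratic-form statistic with the same sign as D (neutral omegas).

    G = S (1 - u v) - u - v - 2 u v with u, v, S the single- and
    dual-stimulation on/off odds.  Valid (and only accepted) under the
    nonlinearity-case conditions omega_AB = omega3 = 1, where
    S = u v / x_P and G is quadratic in the two single-stimulation odds.
    """
    s = system
    if not (s.omega_AB == 1.0 and s.omega3 == 1.0):
        raise ValueError(
            "synergy_sign_statistic requires omega_AB = omega3 = 1 "
            f"(got omega_AB={s.omega_AB}, omega3={s.omega3})"
        )
    if not (math.isfinite(s.x_A) and math.isfinite(s.x_B)):
        raise ValueError("doses must be finite")
    u = _odds(s, s.x_A, 0.0)
    v = _odds(s, 0.0, s.x_B)
    big_s = _odds(s, s.x_A, s.x_B)
    return big_s * (1.0 - u * v) - u - v - 2.0 * u * v


def saturated_sign_statistic(w_A, w_B, x_P, omega3=1.0):
    """Sign statistic in the joint-saturation limit, divided by x_P.

    g = omega3 w_A w_B (1 - x_P^2 w_A w_B) - w_A - w_B - 2 x_P w_A w_B.
    The TF-TF factor omega_AB cancels at joint saturation.  Array-friendly.
    """
    wab = np.asarray(w_A) * np.asarray(w_B)
    return omega3 * wab * (1.0 - x_P**2 * wab) - np.asarray(w_A) - np.asarray(w_B) \
        - 2.0 * x_P * wab


def limiting_sign_statistic(w_A, w_B, omega3=1.0):
    """Strong-activation, low-RNAP limit: h = omega3 w_A w_B - w_A - w_B."""
    return omega3 * np.asarray(w_A) * np.asarray(w_B) - np.asarray(w_A) - np.asarray(w_B)


# ---------------------------------------------------------------------------
# Closed-form critical boundaries


def critical_xp_equal_activators(w: float) -> float | None:
    """Critical RNAP concentration for equal activators at saturation.

    x_P*(w) = (w - 2)/w^2 for w >= 2; below the curve the saturated dual
    response is greater than additive, above it less than additive.  For
    w < 2 no positive boundary exists (None).  The curve rises from zero at
    w = 2 to its maximum 1/8 at w = 4 and decays to zero as w -> infinity;
    it stays below the universal 1/2 ceiling everywhere.
    """
    if w <= 0:
        raise ValueError(f"w must be > 0, got {w}")
    if w < 2.0:
        return None
    return (w - 2.0) / w**2


def critical_xp_vs_energy(g: float) -> float | None:
    """Equal-activator boundary parameterised by the energy shift g = dE/RT.

    Equals critical_xp_equal_activators(e^g).
    """
    return critical_xp_equal_activators(math.exp(g))


def two_body_hyperbola(w_A: float) -> float:
    """Critical w_B over which strong, low-RNAP activation turns synergistic.

    Zero set of h = w_A w_B - w_A - w_B (neutral omegas):
    w_B*(w_A) = w_A / (w_A - 1), defined for w_A > 1; the diagonal crosses
    at w_A = w_B = 2 and the curve decays to the asymptote w_B = 1.
    """
    if w_A <= 1.0:
        raise ValueError(
            f"two_body_hyperbola requires w_A > 1 (critical w_B unbounded at w_A = {w_A})"
        )
    return w_A / (w_A - 1.0)


def three_body_hyperbola(w_A: float, omega3: float) -> float:
    """Critical w_B with a three-body factor: w_B* = w_A / (omega3 w_A - 1).

    Defined for w_A above the asymptote 1/omega3; as omega3 grows the
    asymptotes 1/omega3 move toward the axes, and for omega3 >= 2 the whole
    activator domain w_A, w_B > 1 lies above the curve.
    """
    if w_A <= 0 or omega3 <= 0:
        raise ValueError("w_A and omega3 must be > 0")
    if omega3 * w_A <= 1.0:
        raise ValueError(
            f"w_A = {w_A} at or below the asymptote 1/omega3 = {1.0 / omega3}; "
            "critical w_B unbounded"
        )
    return w_A / (omega3 * w_A - 1.0)


def minimal_universal_three_body_factor(
    n_grid: int = 200,
    w_max: float = 100.0,
    w_min_offset: float = 1e-4,
    tol: float = 1e-4,
) -> float:
    """Infimum omega3 making the limiting statistic positive for all activators.

    Bisects on omega3 against an ``n_grid``-point log grid of two-body
    factors in (1, w_max], checking positivity of
    h = omega3 w_A w_B - w_A - w_B over all grid pairs.  The worst case
    sits at w_A = w_B -> 1+, so the infimum is 2.
    """
    grid = np.logspace(math.log10(1.0 + w_min_offset), math.log10(w_max), n_grid)
    wa = grid[:, None]
    wb = grid[None, :]

    def positive_everywhere(omega3: float) -> bool:
        return bool(np.min(limiting_sign_statistic(wa, wb, omega3)) > 0.0)

    lo, hi = 1.0, 4.0
    if positive_everywhere(lo):  # pragma: no cover - grid would have to degenerate
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if positive_everywhere(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Regime classification


def _sign_label(value: float) -> str:
    if value > 0:
        return "positive"
    if value < 0:
        return "negative"
    return "either"


def classify_regime(
    system: TwoActivatorSystem,
    strong_activation_min: float = STRONG_ACTIVATION_MIN,
    low_polymerase_max: float = LOW_POLYMERASE_MAX,
    low_tf_max: float = LOW_TF_MAX,
) -> RegimeLabel:
    """Match the promoter against the tabulated synergy cases.

    Cases are tried in the fixed priority order 1, 2, 3, 4, 7b, 7a, 6, 5b,
    5a so overlapping preconditions resolve deterministically; the first
    case whose conditions hold is reported, with the sign taken from the
    relevant boundary statistic where one applies.  Defined for activators
    only (w_A, w_B >= 1).
    """
    s = system
    if s.w_A < 1.0 or s.w_B < 1.0:
        raise ValueError(
            "regime classification is defined for activators only (w_A, w_B >= 1); "
            f"got w_A={s.w_A}, w_B={s.w_B}"
        )
    act_a = s.x_A * s.w_A
    act_b = s.x_B * s.w_B
    neutral_omegas = s.omega_AB == 1.0 and s.omega3 == 1.0
    strong = act_a >= strong_activation_min and act_b >= strong_activation_min
    low_xp = s.x_P <= low_polymerase_max

    # case 1: low TF concentrations
    if s.x_A <= low_tf_max and s.x_B <= low_tf_max:
        return RegimeLabel("1", "negative", (f"x_A, x_B <= {low_tf_max}",))
    # case 2: weak activators (sufficient bound w_A w_B omega3 <= 2 makes the
    # sign statistic negative for every dose and every omega_AB)
    if s.w_A * s.w_B * s.omega3 <= WEAK_COMBINED_FACTOR_MAX:
        return RegimeLabel("2", "negative", (f"w_A*w_B*omega3 <= {WEAK_COMBINED_FACTOR_MAX}",))
    # case 3: high RNAP concentration, neutral omegas
    if neutral_omegas and s.x_P >= 0.5:
        return RegimeLabel("3", "negative", ("omega_AB = omega3 = 1", "x_P >= 1/2"))
    # case 4: weak activation products, neutral omegas
    if neutral_omegas and act_a <= WEAK_ACTIVATION_MAX and act_b <= WEAK_ACTIVATION_MAX:
        return RegimeLabel(
            "4", "negative",
            ("omega_AB = omega3 = 1", f"x_A*w_A, x_B*w_B <= {WEAK_ACTIVATION_MAX}"),
        )
    # cases 7b/7a: three-body interactions under strong activation, low RNAP
    if strong and low_xp and s.omega_AB == 1.0 and s.omega3 != 1.0:
        conds = (
            f"x_i*w_i >= {strong_activation_min}",
            f"x_P <= {low_polymerase_max}",
            "omega_AB = 1",
        )
        if s.omega3 >= 2.0:
            return RegimeLabel("7b", "positive", conds + ("omega3 >= 2",))
        h = float(limiting_sign_statistic(s.w_A, s.w_B, s.omega3))
        return RegimeLabel("7a", _sign_label(h), conds)
    # case 6: nonlinearity under strong activation, low RNAP (omega3 = 1,
    # omega_AB arbitrary -- it cancels at joint saturation)
    if strong and low_xp and s.omega3 == 1.0:
        h = float(limiting_sign_statistic(s.w_A, s.w_B, 1.0))
        return RegimeLabel(
            "6", _sign_label(h),
            (f"x_i*w_i >= {strong_activation_min}", f"x_P <= {low_polymerase_max}", "omega3 = 1"),
        )
    # cases 5b/5a: nonlinearity at high TF concentrations, neutral omegas
    if neutral_omegas and strong:
        conds = ("omega_AB = omega3 = 1", f"x_i*w_i >= {strong_activation_min}")
        if math.isclose(s.w_A, s.w_B, rel_tol=EQUAL_SHIFT_RTOL):
            crit = critical_xp_equal_activators(s.w_A)
            if crit is None or s.x_P > crit:
                sign = "negative"
            elif s.x_P < crit:
                sign = "positive"
            else:
                sign = "either"
            return RegimeLabel("5b", sign, conds + ("w_A = w_B",))
        g = float(saturated_sign_statistic(s.w_A, s.w_B, s.x_P, 1.0))
        return RegimeLabel("5a", _sign_label(g), conds)
    return RegimeLabel("unclassified", "either", ())


# ---------------------------------------------------------------------------
# Brute-force oracle and curve sampling


def sign_scan_oracle(
    template: TwoActivatorSystem,
    coordinates: dict[str, np.ndarray],
    max_points: int = 1_000_000,
) -> pd.DataFrame:
    """Grid evaluation of D over free coordinates of the template system.

    ``coordinates`` maps field names of :class:`TwoActivatorSystem` to value
    arrays; the cartesian product is evaluated and the table of coordinates,
    D, and sign(D) returned.  Deterministic; used to validate every
    closed-form boundary.
    """
    from dataclasses import replace

    names = list(coordinates)
    valid = {"x_P", "x_A", "x_B", "w_A", "w_B", "omega_AB", "omega3"}
    unknown = set(names) - valid
    if unknown:
        raise ValueError(f"unknown coordinates {sorted(unknown)}")
    grids = [np.asarray(coordinates[n], dtype=float) for n in names]
    if any(not np.isfinite(g).all() for g in grids):
        raise ValueError("coordinate ranges must be finite")
    n_points = int(np.prod([len(g) for g in grids])) if grids else 0
    if n_points > max_points:
        raise ValueError(f"grid of {n_points} points exceeds the {max_points} cap")
    rows = []
    for values in product(*grids):
        system = replace(template, **dict(zip(names, values)))
        D = synergy_difference(system).D
        rows.append((*values, D, int(np.sign(D))))
    return pd.DataFrame(rows, columns=[*names, "D", "sign"])


_CURVES = {"eq21", "eq22", "eq23", "eq24"}


def boundary_curve(
    which: str,
    lo: float,
    hi: float,
    n: int,
    omega3: float = 1.0,
) -> BoundaryCurve:
    """Sample one of the closed-form critical curves on [lo, hi].

    eq21: x_P*(w) for equal activators at saturation (coordinate w);
    eq22: the same vs the energy shift g = ln w;
    eq23: w_B*(w_A), strong activation, low RNAP, neutral omegas;
    eq24: w_B*(w_A) with the three-body factor omega3.
    Coordinates without a finite positive critical value are dropped.
    """
    if which not in _CURVES:
        raise ValueError(f"unknown curve {which!r}; expected one of {sorted(_CURVES)}")
    if not (lo < hi and n >= 2):
        raise ValueError("range must satisfy lo < hi with n >= 2 samples")
    coords = np.linspace(lo, hi, n)
    rows = []
    for c in coords:
        try:
            if which == "eq21":
                value = critical_xp_equal_activators(c)
            elif which == "eq22":
                value = critical_xp_vs_energy(c)
            elif which == "eq23":
                value = two_body_hyperbola(c)
            else:
                value = three_body_hyperbola(c, omega3)
        except ValueError:
            value = None
        if value is not None:
            rows.append((c, value))
    samples = pd.DataFrame(rows, columns=["coordinate", "critical_value"])
    return BoundaryCurve(which, samples, (lo, hi))
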