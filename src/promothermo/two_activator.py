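"""Closed-form occupancy and synergy measure for two activators.

For two transcription factors A and B the RNAP occupancy probability has the
closed form

    p = v_on / (v_on + v_off)
    v_on  = x_P (1 + x_A w_A + x_B w_B + x_A x_B w_A w_B omega_AB omega3)
    v_off = 1 + x_A + x_B + x_A x_B omega_AB

The synergy of a dual stimulation is quantified by the difference measure

    D = p(x_A, x_B) - p(x_A, 0) - p(0, x_B)

whose sign separates greater-than-additive (D > 0) from less-than-additive
(D < 0) responses.  D is computed from raw occupancies without basal
subtraction; pass ``include_basal=True`` to add the basal occupancy back
(the alternative convention D + p(0,0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .statespace import ActivatorDose, PolymeraseDose

__all__ = [
    "TwoActivatorSystem",
    "SynergyAssessment",
    "occupancy_two",
    "occupancy_array",
    "synergy_difference",
    "synergy_difference_array",
    "saturation_occupancies",
    "fold_change",
    "fold_change_saturation",
]

#: Absolute half-width (in probability units) of the band around D = 0
#: classified as ``additive``.
ADDITIVE_TOLERANCE = 1e-9


def _dose_value(x) -> float:
    if isinstance(x, (ActivatorDose, PolymeraseDose)):
        return x.relative_concentration
    return float(x)


@dataclass(frozen=True)
class TwoActivatorSystem:
    """Promoter regulated by two activators: the seven model coordinates.

    Doses ``x_P, x_A, x_B`` are dimensionless relative concentrations
    (may be 0); ``w_A, w_B`` are the two-body TF-RNAP factors, ``omega_AB``
    the TF-TF factor, ``omega3`` the three-body TF-TF-RNAP factor (all > 0).
    Dose objects from :mod:`promothermo.statespace` are accepted and coerced
    to their relative concentrations.
    """

    x_P: float
    x_A: float
    x_B: float
    w_A: float = 1.0
    w_B: float = 1.0
    omega_AB: float = 1.0
    omega3: float = 1.0

    def __post_init__(self):
        for name in ("x_P", "x_A", "x_B"):
            value = _dose_value(getattr(self, name))
            object.__setattr__(self, name, value)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in ("w_A", "w_B", "omega_AB", "omega3"):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")

    def swapped(self) -> "TwoActivatorSystem":
        """The same promoter with the roles of A and B exchanged."""
        return replace(self, x_A=self.x_B, x_B=self.x_A, w_A=self.w_B, w_B=self.w_A)

    def with_doses(self, x_A: float, x_B: float) -> "TwoActivatorSystem":
        return replace(self, x_A=x_A, x_B=x_B)


@dataclass(frozen=True)
class SynergyAssessment:
    """The difference measure D with its sign classification.

    D lies in (-2, 1); it is classified greater-than-additive when
    D > tolerance, less-than-additive when D < -tolerance, else additive.
    """

    D: float
    classification: str
    tolerance: float = ADDITIVE_TOLERANCE

    def __post_init__(self):
        if not -2.0 < self.D < 1.0:
            raise ValueError(f"D = {self.D} outside its admissible range (-2, 1)")

    @staticmethod
    def classify(D: float, tolerance: float = ADDITIVE_TOLERANCE) -> "SynergyAssessment":
        if tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if D > tolerance:
            label = "greater_than_additive"
        elif D < -tolerance:
            label = "less_than_additive"
        else:
            label = "additive"
        return SynergyAssessment(D, label, tolerance)


def occupancy_two(system: TwoActivatorSystem) -> float:
    """RNAP occupancy probability of the two-activator promoter.

    Evaluated via the on/off odds ratio so saturating doses cannot
    overflow: p = r/(1+r) with r = v_on/v_off.
    """
    s = system
    num = 1.0 + s.x_A * s.w_A + s.x_B * s.w_B \
        + s.x_A * s.x_B * s.w_A * s.w_B * s.omega_AB * s.omega3
    den = 1.0 + s.x_A + s.x_B + s.x_A * s.x_B * s.omega_AB
    if math.isinf(num) or math.isinf(den):
        # fall back to the log-space route for astronomically large doses
        return _occupancy_log(s)
    r = s.x_P * num / den
    return r / (1.0 + r)


def _occupancy_log(s: TwoActivatorSystem) -> float:
    from scipy.special import logsumexp

    def lg(x):
        return math.log(x) if x > 0 else -math.inf

    la, lb = lg(s.x_A), lg(s.x_B)
    on = logsumexp([
        0.0,
        la + lg(s.w_A),
        lb + lg(s.w_B),
        la + lb + lg(s.w_A) + lg(s.w_B) + lg(s.omega_AB) + lg(s.omega3),
    ])
    off = logsumexp([0.0, la, lb, la + lb + lg(s.omega_AB)])
    lr = lg(s.x_P) + on - off
    return float(1.0 / (1.0 + math.exp(-lr))) if lr < 700 else 1.0


def occupancy_array(x_P, x_A, x_B, w_A=1.0, w_B=1.0, omega_AB=1.0, omega3=1.0):
    """Broadcasting evaluation of the two-activator occupancy.

    Same closed form as :func:`occupancy_two`, over numpy arrays; used for
    dense parameter-grid searches.
    """
    import numpy as np

    x_A, x_B = np.asarray(x_A, float), np.asarray(x_B, float)
    w_A, w_B = np.asarray(w_A, float), np.asarray(w_B, float)
    num = 1.0 + x_A * w_A + x_B * w_B + x_A * x_B * w_A * w_B * omega_AB * omega3
    den = 1.0 + x_A + x_B + x_A * x_B * omega_AB
    r = np.asarray(x_P, float) * num / den
    return r / (1.0 + r)


def synergy_difference_array(x_P, x_A, x_B, w_A=1.0, w_B=1.0, omega_AB=1.0, omega3=1.0):
    """Broadcasting D = p(x_A, x_B) - p(x_A, 0) - p(0, x_B)."""
    p_dual = occupancy_array(x_P, x_A, x_B, w_A, w_B, omega_AB, omega3)
    p_a = occupancy_array(x_P, x_A, 0.0, w_A, w_B, omega_AB, omega3)
    p_b = occupancy_array(x_P, 0.0, x_B, w_A, w_B, omega_AB, omega3)
    return p_dual - p_a - p_b


def synergy_difference(
    system: TwoActivatorSystem,
    tolerance: float = ADDITIVE_TOLERANCE,
    include_basal: bool = False,
) -> SynergyAssessment:
    """Difference measure D = p(x_A,x_B) - p(x_A,0) - p(0,x_B).

    Symmetric under exchanging the (dose, w) pairs of the two activators.
    With ``include_basal`` the basal occupancy p(0,0) is added back
    (alternative convention; not the default).
    """
    p_dual = occupancy_two(system)
    p_a = occupancy_two(system.with_doses(system.x_A, 0.0))
    p_b = occupancy_two(system.with_doses(0.0, system.x_B))
    D = p_dual - p_a - p_b
    if include_basal:
        D += occupancy_two(system.with_doses(0.0, 0.0))
    return SynergyAssessment.classify(D, tolerance)


def saturation_occupancies(system: TwoActivatorSystem) -> tuple[float, float, float]:
    """Analytic occupancy limits as each dose, then both, tend to infinity.

    Returns (p_sat_A, p_sat_B, p_sat_AB) with
    p_sat_A = x_P w_A / (1 + x_P w_A) and
    p_sat_AB = x_P w_A w_B omega3 / (1 + x_P w_A w_B omega3);
    the TF-TF factor omega_AB cancels in the joint limit.
    """
    s = system
    ra = s.x_P * s.w_A
    rb = s.x_P * s.w_B
    rab = s.x_P * s.w_A * s.w_B * s.omega3
    return ra / (1.0 + ra), rb / (1.0 + rb), rab / (1.0 + rab)


def fold_change(system: TwoActivatorSystem) -> tuple[float, float, float]:
    """Fold changes at the system's doses, F = p_stim / p_basal.

    Requires x_P > 0 (the basal occupancy x_P/(1+x_P) is the denominator).
    """
    s = system
    if s.x_P <= 0:
        raise ValueError("fold changes require x_P > 0 (basal occupancy undefined)")
    p0 = s.x_P / (1.0 + s.x_P)
    p_a = occupancy_two(s.with_doses(s.x_A, 0.0))
    p_b = occupancy_two(s.with_doses(0.0, s.x_B))
    p_ab = occupancy_two(s)
    return p_a / p0, p_b / p0, p_ab / p0


def fold_change_saturation(system: TwoActivatorSystem) -> tuple[float, float, float]:
    """Fold changes of the saturation responses relative to basal occupancy.

    As x_P -> 0 these tend to (w_A, w_B, w_A w_B omega3), the limits used
    for fold-change-based parameter estimation.
    """
    s = system
    if s.x_P <= 0:
        raise ValueError("fold changes require x_P > 0 (basal occupancy undefined)")
    p0 = s.x_P / (1.0 + s.x_P)
    p_a, p_b, p_ab = saturation_occupancies(s)
    return p_a / p0, p_b / p0, p_ab / p0
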