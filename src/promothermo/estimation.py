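"""Parameter estimation from saturation fold changes and synergy contours.

Reporter assays typically report fold changes F = stimulated/basal activity
for three conditions: activator A alone, B alone, and both (saturating
stimulation).  In the low-RNAP limit (x_P -> 0) the saturation fold changes
equal the cooperativity factors directly,

    F_A -> w_A,   F_B -> w_B,   F_AB -> w_A w_B omega3,

so w_A = F_A, w_B = F_B and omega3 = F_AB/(F_A F_B); the TF-TF factor
omega_AB cancels at joint saturation and is not identifiable from the three
numbers.  When x_P is known the exact relations
F = w (1 + x_P)/(1 + x_P w) are inverted instead.

From estimated parameters the locus D(x_A, x_B) = 0 in the dose plane (the
boundary between less-than-additive and greater-than-additive stimulation)
is traced by 1-D root finding along rays from the origin, with dose axes
optionally rescaled to the dose inducing a given fraction of the
single-stimulation saturation activity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .boundaries import BoundaryCurve
from .dose_response import single_site_occupancy
from .two_activator import TwoActivatorSystem, synergy_difference

__all__ = [
    "FoldChangeRecord",
    "EstimatedParameters",
    "estimate_from_fold_changes",
    "dose_for_saturation_fraction",
    "synergy_domain_contour",
]

CONDITIONS = ("A_only", "B_only", "dual")


@dataclass(frozen=True)
class FoldChangeRecord:
    """One saturation fold change: condition label -> measured ratio."""

    condition: str
    fold_change: float
    noise_sd: float | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not math.isfinite(self.fold_change) or self.fold_change < 0:
            raise ValueError(f"fold change must be finite and >= 0, got {self.fold_change}")
        if self.fold_change < 1.0:
            warnings.warn(
                f"fold change {self.fold_change} < 1 for {self.condition}: "
                "not expected for an activator",
                stacklevel=2,
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class EstimatedParameters:
    """Estimated cooperativity factors with the assumptions used.

    ``omega3`` is the joint saturation factor F_AB/(F_A F_B); omega3 and the
    TF-TF factor omega_AB are not separately identifiable from three
    saturation fold changes, which ``assumptions`` records.
    """

    w_A: float
    w_B: float
    omega3: float
    assumptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("w_A", "w_B", "omega3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"estimate {name} must be > 0")

    def to_system(self, x_P: float, x_A: float = 0.0, x_B: float = 0.0) -> TwoActivatorSystem:
        return TwoActivatorSystem(
            x_P=x_P, x_A=x_A, x_B=x_B,
            w_A=self.w_A, w_B=self.w_B, omega_AB=1.0, omega3=self.omega3,
        )


def _invert_fold_change(F: float, x_P: float, label: str) -> float:
    """Solve F = w (1 + x_P)/(1 + x_P w) for w."""
    den = 1.0 + x_P * (1.0 - F)
    if den <= 0:
        raise ValueError(
            f"fold change {F} for {label} is not invertible at x_P = {x_P} "
            f"(must be < (1 + x_P)/x_P = {(1.0 + x_P) / x_P:.6g})"
        )
    return F / den


def estimate_from_fold_changes(
    records,
    x_P: float | None = None,
) -> EstimatedParameters:
    """Estimate (w_A, w_B, omega3) from three saturation fold changes.

    Low-x_P mode (default, ``x_P`` absent): w_A = F_A, w_B = F_B,
    omega3 = F_AB/(F_A F_B).  Exact mode (``x_P`` given): invert
    F = w (1 + x_P)/(1 + x_P w) per single condition and the analogous
    joint-saturation relation for w_A w_B omega3.
    """
    by_condition: dict[str, FoldChangeRecord] = {}
    for rec in records:
        if not isinstance(rec, FoldChangeRecord):
            rec = FoldChangeRecord(*rec)
        if rec.condition in by_condition:
            raise ValueError(f"duplicate record for condition {rec.condition!r}")
        by_condition[rec.condition] = rec
    missing = [c for c in CONDITIONS if c not in by_condition]
    if missing:
        raise ValueError(f"missing fold-change condition(s): {missing}")
    F_A = by_condition["A_only"].fold_change
    F_B = by_condition["B_only"].fold_change
    F_AB = by_condition["dual"].fold_change

    if x_P is None:
        w_a, w_b = F_A, F_B
        joint = F_AB
        assumptions = {"low_polymerase": True, "saturation": True, "x_P_used": None}
    else:
        if x_P <= 0:
            raise ValueError(f"x_P must be > 0, got {x_P}")
        w_a = _invert_fold_change(F_A, x_P, "A_only")
        w_b = _invert_fold_change(F_B, x_P, "B_only")
        joint = _invert_fold_change(F_AB, x_P, "dual")
        assumptions = {"low_polymerase": False, "saturation": True, "x_P_used": x_P}
    # omega_AB cancels at joint saturation: only the product w_A w_B omega3 is
    # observable, so omega3 and omega_AB are not separately identifiable here.
    assumptions["omega_AB_not_identifiable"] = True
    return EstimatedParameters(
        w_A=w_a, w_B=w_b, omega3=joint / (w_a * w_b), assumptions=assumptions
    )


def dose_for_saturation_fraction(fraction: float, x_P: float, w: float) -> float:
    """Dose inducing the stated fraction of the single-site saturation activity.

    Solves p(x*) = fraction * p(infinity) for the one-site promoter, where
    p(infinity) = x_P w/(1 + x_P w).  The equation is linear in the dose and
    solved exactly; the solution is monotone increasing in ``fraction`` and
    diverges as fraction -> 1.  Requires w > 1 (otherwise no dose
    dependence) and a fraction above the basal activity fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if w <= 1.0:
        raise ValueError(f"w must be > 1 for a dose-dependent response, got {w}")
    if x_P <= 0:
        raise ValueError(f"x_P must be > 0, got {x_P}")
    p_sat = x_P * w / (1.0 + x_P * w)
    target = fraction * p_sat
    p_basal = x_P / (1.0 + x_P)
    if target <= p_basal:
        raise ValueError(
            f"fraction {fraction} does not exceed the basal activity fraction "
            f"{p_basal / p_sat:.6g}; no positive dose reaches it"
        )
    # p(x) = x_P (1 + x w)/(x_P (1 + x w) + 1 + x) = target, linear in x
    x = (target - x_P * (1.0 - target)) / (x_P * w * (1.0 - target) - target)
    return x


def synergy_domain_contour(
    params: EstimatedParameters,
    x_P: float,
    n_rays: int = 64,
    max_dose: float = 1e6,
    rescale_fraction: float | None = None,
    tol: float = 1e-9,
) -> BoundaryCurve:
    """Trace the D = 0 contour of an estimated promoter in the dose plane.

    Along ``n_rays`` rays from the origin the radial root of
    D(x_A, x_B) = 0 is bracketed on a log grid and refined until
    |D| < ``tol``.  With ``rescale_fraction`` the axes are divided by the
    dose inducing that fraction of each single-stimulation saturation
    activity (occupancy-based).  An empty sample table means D < 0
    everywhere searched (reported, not an error).
    """
    if x_P <= 0:
        raise ValueError("x_P must be > 0")
    if params.w_A < 1.0 or params.w_B < 1.0:
        raise ValueError("contour tracing is defined on the activator domain (w >= 1)")

    def D(x_a: float, x_b: float) -> float:
        return synergy_difference(params.to_system(x_P, x_a, x_b)).D

    scale_a = scale_b = 1.0
    if rescale_fraction is not None:
        scale_a = dose_for_saturation_fraction(rescale_fraction, x_P, params.w_A)
        scale_b = dose_for_saturation_fraction(rescale_fraction, x_P, params.w_B)

    angles = np.linspace(0.0, math.pi / 2.0, n_rays + 2)[1:-1]
    radii = np.logspace(-6, math.log10(max_dose), 200)
    points = []
    for theta in angles:
        ca, sa = math.cos(theta), math.sin(theta)
        values = np.array([D(r * ca, r * sa) for r in radii])
        idx = np.nonzero(values[:-1] * values[1:] < 0.0)[0]
        if len(idx) == 0:
            continue
        i = idx[0]  # innermost crossing separates the origin's LTA pocket
        root = brentq(
            lambda lr: D(10.0**lr * ca, 10.0**lr * sa),
            math.log10(radii[i]), math.log10(radii[i + 1]),
            xtol=1e-14, rtol=8.9e-16,
        )
        r0 = 10.0**root
        if abs(D(r0 * ca, r0 * sa)) < tol:
            points.append((r0 * ca / scale_a, r0 * sa / scale_b))
    samples = pd.DataFrame(points, columns=["coordinate", "critical_value"])
    curve = BoundaryCurve("x_A", samples, (0.0, max_dose))
    return curve
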