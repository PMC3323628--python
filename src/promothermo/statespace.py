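"""General promoter state space for N transcription factors plus RNA polymerase.

The promoter of a gene regulated by N transcription factors (TFs) and RNA
polymerase (RNAP) is modelled as a set of 2^(N+1) mutually exclusive occupancy
states: every subset of TFs may be bound, with or without RNAP.  Each state
carries a Boltzmann statistical weight

    W(S, sigma) = x_P^sigma * prod_{i in S} x_i
                  * prod_{i<j in S} omega_ij
                  * [ prod_{i in S} w_i * prod_{i<j in S} omega3_ij ]^sigma

where ``S`` is the bound-TF subset, ``sigma`` the RNAP flag, ``x_i = c_i/K_i``
dimensionless relative concentrations, and the factors ``w_i`` (TF-RNAP),
``omega_ij`` (TF-TF) and ``omega3_ij`` (TF-TF-RNAP three-body) encode free
energy shifts via ``factor = exp(-dE/(R T))``.  State probabilities are the
weights divided by the partition sum, and the RNAP occupancy probability is
the cumulative probability of all RNAP-bound states.

Weights are accumulated in log space and exponentiated once, so saturating
doses and strong factors (up to ~1e12) give finite probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "ActivatorDose",
    "PolymeraseDose",
    "EnergyParameters",
    "CooperativityParameters",
    "PromoterState",
    "PromoterStateSpace",
    "factors_from_energies",
    "energies_from_factors",
    "enumerate_states",
    "state_weight",
    "state_probabilities",
    "on_off_sums",
    "occupancy_probability",
    "transcription_rate",
    "TABLE_DISPLAY_ORDER_2TF",
]

#: Gas constant by energy-unit tag (per mole per kelvin).
GAS_CONSTANT = {
    "kcal/mol": 1.98720425864083e-3,
    "J/mol": 8.31446261815324,
}

#: Default temperature in kelvin (room temperature).
DEFAULT_TEMPERATURE = 298.15

#: Display permutation mapping the internal two-TF state order
#: (off block then on block, TF subsets in binary order) onto the
#: conventional tabulation (empty; P; A; B; PA; PB; AB; PAB).
TABLE_DISPLAY_ORDER_2TF = (1, 5, 2, 3, 6, 7, 4, 8)


def _as_pair(key) -> tuple[str, str]:
    i, j = tuple(key)
    if i == j:
        raise ValueError(f"pair key with duplicate TF {i!r}")
    return (i, j) if i < j else (j, i)


def _validate_pairs(mapping: Mapping, what: str) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for key, value in mapping.items():
        pair = _as_pair(key)
        if pair in out:
            raise ValueError(f"duplicate {what} entry for pair {pair}")
        out[pair] = float(value)
    return out


@dataclass(frozen=True)
class ActivatorDose:
    """Relative (dimensionless) concentration of one transcription factor.

    ``relative_concentration`` is x = c/K.  If both the absolute
    concentration and the dissociation constant are supplied, their ratio
    must agree with ``relative_concentration`` to 1e-12 relative tolerance.
    """

    name: str
    relative_concentration: float
    absolute_concentration: float | None = None
    dissociation_constant: float | None = None

    def __post_init__(self):
        if self.relative_concentration < 0:
            raise ValueError(
                f"dose of {self.name!r} must be >= 0, got {self.relative_concentration}"
            )
        if self.absolute_concentration is not None and self.dissociation_constant is not None:
            ratio = self.absolute_concentration / self.dissociation_constant
            if not math.isclose(ratio, self.relative_concentration, rel_tol=1e-12):
                raise ValueError(
                    f"relative concentration {self.relative_concentration} of {self.name!r} "
                    f"inconsistent with concentration/Kd = {ratio}"
                )

    @classmethod
    def from_absolute(cls, name: str, concentration: float, kd: float) -> "ActivatorDose":
        if kd <= 0:
            raise ValueError(f"dissociation constant of {name!r} must be > 0")
        return cls(name, concentration / kd, concentration, kd)


@dataclass(frozen=True)
class PolymeraseDose:
    """Relative RNA polymerase concentration x_P = [RNAP]/K_P."""

    relative_concentration: float
    absolute_concentration: float | None = None
    dissociation_constant: float | None = None

    def __post_init__(self):
        if self.relative_concentration < 0:
            raise ValueError(
                f"polymerase dose must be >= 0, got {self.relative_concentration}"
            )
        if self.absolute_concentration is not None and self.dissociation_constant is not None:
            ratio = self.absolute_concentration / self.dissociation_constant
            if not math.isclose(ratio, self.relative_concentration, rel_tol=1e-12):
                raise ValueError("relative polymerase concentration inconsistent with c/Kd")

    @classmethod
    def from_absolute(cls, concentration: float, kd: float) -> "PolymeraseDose":
        if kd <= 0:
            raise ValueError("polymerase dissociation constant must be > 0")
        return cls(concentration / kd, concentration, kd)


@dataclass(frozen=True)
class EnergyParameters:
    """Free-energy shifts of the binding interactions, with unit tag.

    ``delta_e[i]`` is the shift of the RNAP binding energy induced by TF i
    alone (two-body); ``delta_e_pair[(i,j)]`` the TF-TF interaction energy;
    ``delta_e3[(i,j)]`` the three-body TF-TF-RNAP shift.  Activating shifts
    are negative (they lower the RNAP binding energy) and map to
    cooperativity factors > 1 under ``factor = exp(-dE/(R T))``.
    """

    delta_e: Mapping[str, float] = field(default_factory=dict)
    delta_e_pair: Mapping = field(default_factory=dict)
    delta_e3: Mapping = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    units: str = "kcal/mol"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if self.units not in GAS_CONSTANT:
            raise ValueError(
                f"unknown energy unit tag {self.units!r}; expected one of {sorted(GAS_CONSTANT)}"
            )
        object.__setattr__(self, "delta_e", dict(self.delta_e))
        object.__setattr__(self, "delta_e_pair", _validate_pairs(self.delta_e_pair, "TF-TF energy"))
        object.__setattr__(self, "delta_e3", _validate_pairs(self.delta_e3, "three-body energy"))

    @property
    def gas_constant(self) -> float:
        return GAS_CONSTANT[self.units]

    @property
    def rt(self) -> float:
        """Thermal energy R*T in the tagged units."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class CooperativityParameters:
    """Multiplicative interaction factors of a promoter.

    ``w[i]`` couples TF i to bound RNAP (two-body, > 1 for an activator);
    ``omega_tf[(i,j)]`` couples two bound TFs regardless of RNAP;
    ``omega3[(i,j)]`` is active only when both TFs and RNAP are bound.
    Missing entries default to 1 (no interaction).  The core accepts any
    positive factor; regime-classification operations additionally require
    activator factors w >= 1.
    """

    w: Mapping[str, float] = field(default_factory=dict)
    omega_tf: Mapping = field(default_factory=dict)
    omega3: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "w", {k: float(v) for k, v in self.w.items()})
        object.__setattr__(self, "omega_tf", _validate_pairs(self.omega_tf, "TF-TF factor"))
        object.__setattr__(self, "omega3", _validate_pairs(self.omega3, "three-body factor"))
        for name, value in self.w.items():
            if value <= 0:
                raise ValueError(f"two-body factor w[{name!r}] must be > 0, got {value}")
        for label, mapping in (("omega_tf", self.omega_tf), ("omega3", self.omega3)):
            for pair, value in mapping.items():
                if value <= 0:
                    raise ValueError(f"{label}[{pair}] must be > 0, got {value}")

    def w_of(self, name: str) -> float:
        return self.w.get(name, 1.0)

    def omega_tf_of(self, i: str, j: str) -> float:
        return self.omega_tf.get(_as_pair((i, j)), 1.0)

    def omega3_of(self, i: str, j: str) -> float:
        return self.omega3.get(_as_pair((i, j)), 1.0)


@dataclass
class PromoterState:
    """One occupancy state of the transcriptional machinery.

    ``free_energy_shift`` is the state's interaction free energy relative to
    the empty promoter, i.e. -RT * log(factor part of the weight); the
    concentration (degeneracy) part of the weight is excluded.  Units follow
    the ``EnergyParameters`` used to build the state space (kcal/mol at
    298.15 K by default).
    """

    index: int
    polymerase_bound: bool
    bound_tfs: frozenset[str]
    weight: float = 1.0
    free_energy_shift: float = 0.0
    log_weight: float = 0.0

    def __post_init__(self):
        if self.index < 1:
            raise ValueError("state index must be >= 1")
        if self.weight < 0:
            raise ValueError("state weight must be >= 0")
        if not self.polymerase_bound and not self.bound_tfs:
            if self.weight != 1.0 or self.free_energy_shift != 0.0:
                raise ValueError("empty state must have weight 1 and zero energy shift")


@dataclass
class PromoterStateSpace:
    """All 2^(n_tf+1) states with weights, probabilities and on/off sums.

    ``v_on`` / ``v_off`` are the summed weights of RNAP-bound / RNAP-free
    states (relative equilibrium concentrations normalised to the empty
    state); the occupancy probability is ``v_on / (v_on + v_off)``.
    """

    n_tf: int
    tf_names: tuple[str, ...]
    states: list[PromoterState]
    v_on: float
    v_off: float
    probabilities: dict[int, float]

    @property
    def occupancy(self) -> float:
        return self.v_on / (self.v_on + self.v_off)

    def to_frame(self) -> pd.DataFrame:
        """State table with the documented export columns."""
        return pd.DataFrame(
            {
                "state_index": [s.index for s in self.states],
                "rnap_bound": [int(s.polymerase_bound) for s in self.states],
                "bound_tfs": ["+".join(sorted(s.bound_tfs)) for s in self.states],
                "weight": [s.weight for s in self.states],
                "probability": [self.probabilities[s.index] for s in self.states],
            }
        )


# ---------------------------------------------------------------------------
# Energy <-> factor transformation


def factors_from_energies(energies: EnergyParameters) -> CooperativityParameters:
    """Map free-energy shifts to cooperativity factors, exp(-dE/(R T)).

    Activating shifts are negative and map to factors > 1.  The inverse map
    is :func:`energies_from_factors`.
    """
    rt = energies.rt
    return CooperativityParameters(
        w={k: math.exp(-v / rt) for k, v in energies.delta_e.items()},
        omega_tf={k: math.exp(-v / rt) for k, v in energies.delta_e_pair.items()},
        omega3={k: math.exp(-v / rt) for k, v in energies.delta_e3.items()},
    )


def energies_from_factors(
    params: CooperativityParameters,
    temperature: float = DEFAULT_TEMPERATURE,
    units: str = "kcal/mol",
) -> EnergyParameters:
    """Inverse of :func:`factors_from_energies` at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    rt = GAS_CONSTANT[units] * temperature
    return EnergyParameters(
        delta_e={k: -rt * math.log(v) for k, v in params.w.items()},
        delta_e_pair={k: -rt * math.log(v) for k, v in params.omega_tf.items()},
        delta_e3={k: -rt * math.log(v) for k, v in params.omega3.items()},
        temperature=temperature,
        units=units,
    )


# ---------------------------------------------------------------------------
# State enumeration and weights


def enumerate_states(n_tf: int, tf_names: Sequence[str] | None = None) -> PromoterStateSpace:
    """Enumerate all 2^(n_tf+1) occupancy states (skeleton, unit weights).

    Ordering is deterministic: the RNAP-free block first, then the
    RNAP-bound block, each with TF subsets in binary counting order (TF 1
    is the least significant bit).  For two TFs the permutation
    :data:`TABLE_DISPLAY_ORDER_2TF` maps this onto the conventional
    (empty; P; A; B; PA; PB; AB; PAB) tabulation.
    """
    if n_tf < 0:
        raise ValueError(f"n_tf must be >= 0, got {n_tf}")
    if tf_names is None:
        tf_names = _default_names(n_tf)
    tf_names = tuple(tf_names)
    if len(tf_names) != n_tf or len(set(tf_names)) != n_tf:
        raise ValueError("tf_names must be n_tf unique identifiers")
    states = []
    index = 1
    for sigma in (False, True):
        for mask in range(2**n_tf):
            bound = frozenset(tf_names[i] for i in range(n_tf) if mask >> i & 1)
            states.append(PromoterState(index, sigma, bound))
            index += 1
    probabilities = {s.index: math.nan for s in states}
    return PromoterStateSpace(n_tf, tf_names, states, math.nan, math.nan, probabilities)


def _default_names(n_tf: int) -> tuple[str, ...]:
    if n_tf <= 26:
        return tuple(chr(ord("A") + i) for i in range(n_tf))
    return tuple(f"TF{i + 1}" for i in range(n_tf))


def _log_state_weight(
    polymerase_bound: bool,
    bound_tfs: Iterable[str],
    dose_of: Mapping[str, float],
    x_p: float,
    params: CooperativityParameters,
) -> tuple[float, float]:
    """(log weight, log of the interaction-factor part) of one state."""
    bound = sorted(bound_tfs)
    for name in bound:
        if name not in dose_of:
            raise KeyError(f"unknown TF identifier {name!r} in state")
    log_conc = 0.0
    log_factor = 0.0
    if polymerase_bound:
        log_conc += math.log(x_p) if x_p > 0 else -math.inf
    for name in bound:
        x = dose_of[name]
        log_conc += math.log(x) if x > 0 else -math.inf
        if polymerase_bound:
            log_factor += math.log(params.w_of(name))
    for i, j in combinations(bound, 2):
        log_factor += math.log(params.omega_tf_of(i, j))
        if polymerase_bound:
            log_factor += math.log(params.omega3_of(i, j))
    return log_conc + log_factor, log_factor


def state_weight(
    state: PromoterState,
    doses: Sequence[ActivatorDose],
    pol: PolymeraseDose,
    params: CooperativityParameters,
) -> float:
    """Boltzmann statistical weight of one state (empty state -> 1)."""
    dose_of = {d.name: d.relative_concentration for d in doses}
    log_w, _ = _log_state_weight(
        state.polymerase_bound, state.bound_tfs, dose_of, pol.relative_concentration, params
    )
    return math.exp(log_w)


def state_probabilities(
    doses: Sequence[ActivatorDose],
    pol: PolymeraseDose,
    params: CooperativityParameters,
    energies: EnergyParameters | None = None,
) -> PromoterStateSpace:
    """Full state space with weights, probabilities, and on/off sums.

    Probabilities are weights over the partition sum, computed from log
    weights with a single log-sum-exp normalisation.  ``energies`` only sets
    the units/temperature used to report per-state free-energy shifts.
    """
    names = [d.name for d in doses]
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names in doses")
    dose_of = {d.name: d.relative_concentration for d in doses}
    rt = (energies or EnergyParameters()).rt

    space = enumerate_states(len(doses), names)
    log_weights = np.empty(len(space.states))
    for k, state in enumerate(space.states):
        log_w, log_f = _log_state_weight(
            state.polymerase_bound, state.bound_tfs, dose_of, pol.relative_concentration, params
        )
        log_weights[k] = log_w
        state.log_weight = log_w
        state.weight = math.exp(log_w)
        state.free_energy_shift = -rt * log_f

    log_z = logsumexp(log_weights)
    probs = np.exp(log_weights - log_z)
    space.probabilities = {s.index: float(p) for s, p in zip(space.states, probs)}
    on = np.array([s.polymerase_bound for s in space.states])
    # v_on/v_off from log space as well, so huge doses stay finite relative
    # to each other even if individual weights overflow.
    space.v_on = float(np.sum(np.exp(log_weights[on]))) if on.any() else 0.0
    space.v_off = float(np.sum(np.exp(log_weights[~on])))
    return space


def on_off_sums(
    doses: Sequence[ActivatorDose],
    pol: PolymeraseDose,
    params: CooperativityParameters,
) -> tuple[float, float]:
    """Summed weights of RNAP-bound (v_on) and RNAP-free (v_off) states."""
    space = state_probabilities(doses, pol, params)
    return space.v_on, space.v_off


def occupancy_probability(
    doses: Sequence[ActivatorDose],
    pol: PolymeraseDose,
    params: CooperativityParameters,
) -> float:
    """Probability that RNAP occupies the promoter, v_on/(v_on + v_off).

    Computed as the cumulative probability of all RNAP-bound states, which
    is finite for doses/factors up to ~1e12.
    """
    space = state_probabilities(doses, pol, params)
    return sum(
        space.probabilities[s.index] for s in space.states if s.polymerase_bound
    )


def transcription_rate(p: float, rate_scale: float) -> float:
    """Transcription rate proportional to RNAP occupancy, rate = k * p.

    The proportionality constant carries the arbitrary units of the readout
    and is not estimated by this package.
    """
    if rate_scale <= 0:
        raise ValueError(f"rate_scale must be > 0, got {rate_scale}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"occupancy probability must be in [0, 1], got {p}")
    return rate_scale * p
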