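"""Configuration parsing, tabular output, and the synthetic fixture generator.

Configs are YAML or JSON documents with a ``polymerase`` block, a ``tfs``
list, and either a ``factors`` block or an ``energies`` block (never both).
Tables are written as TSV with one header line, ``%.12g`` floats, ``\\n``
line endings and UTF-8; identical inputs produce byte-identical files.

The fixture generator emulates reporter-assay readouts: it draws promoter
truth parameters log-uniformly, computes noiseless saturation fold changes
through the forward model at low RNAP concentration, and applies
multiplicative lognormal noise.  It is the only source of randomness in the
package, seeded explicitly, and retains the truth columns for recovery
tests.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .statespace import (
    ActivatorDose,
    CooperativityParameters,
    EnergyParameters,
    PolymeraseDose,
    factors_from_energies,
)
from .two_activator import TwoActivatorSystem, fold_change_saturation

__all__ = [
    "ConfigError",
    "RunConfig",
    "FixtureSet",
    "load_config",
    "write_table",
    "generate_fixtures",
    "GENERATOR_VERSION",
]

logger = logging.getLogger("promothermo")

GENERATOR_VERSION = "1"


class ConfigError(ValueError):
    """Raised when a configuration document violates the schema."""


def _require_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_dose(block: dict, where: str, name: str | None = None):
    allowed = {"relative_concentration", "concentration", "kd"}
    if name is not None:
        allowed |= {"name"}
    _require_keys(block, allowed, where)
    has_rel = "relative_concentration" in block
    has_abs = "concentration" in block or "kd" in block
    if has_abs and not ("concentration" in block and "kd" in block):
        raise ConfigError(f"{where}: concentration and kd must be given together")
    if not has_rel and not has_abs:
        raise ConfigError(
            f"{where}: needs relative_concentration or concentration+kd"
        )
    if name is None:
        if has_abs and has_rel:
            return PolymeraseDose(
                float(block["relative_concentration"]),
                float(block["concentration"]), float(block["kd"]),
            )
        if has_abs:
            return PolymeraseDose.from_absolute(float(block["concentration"]), float(block["kd"]))
        return PolymeraseDose(float(block["relative_concentration"]))
    if has_abs and has_rel:
        return ActivatorDose(
            name, float(block["relative_concentration"]),
            float(block["concentration"]), float(block["kd"]),
        )
    if has_abs:
        return ActivatorDose.from_absolute(name, float(block["concentration"]), float(block["kd"]))
    return ActivatorDose(name, float(block["relative_concentration"]))


def _parse_pairs(block: dict) -> dict:
    out = {}
    for key, value in block.items():
        parts = tuple(p.strip() for p in str(key).split(","))
        if len(parts) != 2:
            raise ConfigError(f"pair key {key!r} must be of the form 'A,B'")
        out[parts] = float(value)
    return out


@dataclass
class RunConfig:
    """Validated model configuration: doses plus cooperativity factors."""

    polymerase: PolymeraseDose
    tfs: list[ActivatorDose]
    factors: CooperativityParameters
    energies: EnergyParameters | None = None
    seed: int | None = None
    log_level: str = "WARNING"

    def to_two_activator_system(self) -> TwoActivatorSystem:
        """Closed-form two-activator view (requires exactly two TFs)."""
        if len(self.tfs) != 2:
            raise ConfigError(
                f"two-activator analysis needs exactly 2 TFs, config has {len(self.tfs)}"
            )
        a, b = self.tfs
        return TwoActivatorSystem(
            x_P=self.polymerase.relative_concentration,
            x_A=a.relative_concentration,
            x_B=b.relative_concentration,
            w_A=self.factors.w_of(a.name),
            w_B=self.factors.w_of(b.name),
            omega_AB=self.factors.omega_tf_of(a.name, b.name),
            omega3=self.factors.omega3_of(a.name, b.name),
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON model configuration.

    Defaults: all factors 1 (neutral), temperature 298.15 K.  Unknown keys
    are rejected with a message naming the key; ``factors`` and ``energies``
    are mutually exclusive.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a mapping")
    _require_keys(
        doc, {"polymerase", "tfs", "factors", "energies", "seed", "log_level"}, "config"
    )
    if "polymerase" not in doc:
        raise ConfigError("config needs a 'polymerase' block")
    if "factors" in doc and "energies" in doc:
        raise ConfigError("'factors' and 'energies' are mutually exclusive")

    pol = _parse_dose(doc["polymerase"], "polymerase")
    tfs = []
    for i, block in enumerate(doc.get("tfs", []) or []):
        if "name" not in block:
            raise ConfigError(f"tfs[{i}]: needs a 'name'")
        tfs.append(_parse_dose(block, f"tfs[{i}]", name=str(block["name"])))
    names = [t.name for t in tfs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate TF names in config: {names}")

    energies = None
    if "energies" in doc:
        block = doc["energies"]
        _require_keys(
            block,
            {"units", "temperature", "delta_e", "delta_e_pair", "delta_e3"},
            "energies",
        )
        energies = EnergyParameters(
            delta_e={str(k): float(v) for k, v in (block.get("delta_e") or {}).items()},
            delta_e_pair=_parse_pairs(block.get("delta_e_pair") or {}),
            delta_e3=_parse_pairs(block.get("delta_e3") or {}),
            temperature=float(block.get("temperature", 298.15)),
            units=str(block.get("units", "kcal/mol")),
        )
        factors = factors_from_energies(energies)
    elif "factors" in doc:
        block = doc["factors"]
        _require_keys(block, {"w", "omega_tf", "omega_3"}, "factors")
        factors = CooperativityParameters(
            w={str(k): float(v) for k, v in (block.get("w") or {}).items()},
            omega_tf=_parse_pairs(block.get("omega_tf") or {}),
            omega3=_parse_pairs(block.get("omega_3") or {}),
        )
    else:
        factors = CooperativityParameters()

    unknown_w = set(factors.w) - set(names)
    if unknown_w:
        raise ConfigError(f"factors reference unknown TF(s) {sorted(unknown_w)}")

    return RunConfig(
        polymerase=pol,
        tfs=tfs,
        factors=factors,
        energies=energies,
        seed=doc.get("seed"),
        log_level=str(doc.get("log_level", "WARNING")),
    )


def write_table(rows: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Write a TSV table: one header line, %.12g floats, \\n endings, UTF-8."""
    buf = _io.StringIO()
    rows.to_csv(buf, sep="\t", index=False, float_format=float_format, lineterminator="\n")
    Path(path).write_bytes(buf.getvalue().encode("utf-8"))


@dataclass
class FixtureSet:
    """Synthetic reporter-assay fixtures with retained ground truth."""

    parameter_grid: pd.DataFrame
    fold_changes: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_table(self.parameter_grid, directory / "parameter_grid.tsv")
        write_table(self.fold_changes, directory / "fold_changes.tsv")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


DEFAULT_FIXTURE_SPEC = {
    "n": 200,
    "w_range": (1.0, 50.0),
    "omega3_range": (0.5, 20.0),
    "x_P": 1e-6,
    "noise_sd": 0.1,
}


def generate_fixtures(seed: int, spec: dict | None = None) -> FixtureSet:
    """Draw synthetic saturation fold-change tables with known truth.

    Truth parameters are drawn log-uniformly from the spec ranges;
    noiseless fold changes come from the forward model at low RNAP
    concentration (x_P = 1e-6 by default) and saturating doses; lognormal
    multiplicative noise of the given sd is applied.  Same seed, same
    tables, byte for byte.
    """
    merged = dict(DEFAULT_FIXTURE_SPEC)
    merged.update(spec or {})
    n = int(merged["n"])
    w_lo, w_hi = merged["w_range"]
    o_lo, o_hi = merged["omega3_range"]
    if n <= 0 or w_lo <= 0 or w_lo > w_hi or o_lo <= 0 or o_lo > o_hi:
        raise ValueError(f"invalid fixture spec: {merged}")
    sd = float(merged["noise_sd"])
    if sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x_p = float(merged["x_P"])

    rng = np.random.default_rng(seed)
    w_a = np.exp(rng.uniform(np.log(w_lo), np.log(w_hi), n))
    w_b = np.exp(rng.uniform(np.log(w_lo), np.log(w_hi), n))
    omega3 = np.exp(rng.uniform(np.log(o_lo), np.log(o_hi), n))

    grid = pd.DataFrame(
        {"promoter": np.arange(n), "x_P": x_p, "w_A": w_a, "w_B": w_b, "omega3": omega3}
    )
    records = []
    for k in range(n):
        system = TwoActivatorSystem(
            x_P=x_p, x_A=0.0, x_B=0.0, w_A=w_a[k], w_B=w_b[k], omega3=omega3[k]
        )
        f_a, f_b, f_ab = fold_change_saturation(system)
        for condition, clean in (("A_only", f_a), ("B_only", f_b), ("dual", f_ab)):
            noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
            records.append(
                {
                    "promoter": k,
                    "condition": condition,
                    "fold_change": clean * noise,
                    "fold_change_true": clean,
                }
            )
    fold_changes = pd.DataFrame(records)
    manifest = {
        "seed": int(seed),
        "generator_version": GENERATOR_VERSION,
        "spec": {
            "n": n,
            "w_range": [w_lo, w_hi],
            "omega3_range": [o_lo, o_hi],
            "x_P": x_p,
            "noise_sd": sd,
        },
    }
    return FixtureSet(grid, fold_changes, manifest)
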