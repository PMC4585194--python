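"""Model parameters: the rate and shape constants of the transplant-immune ODE model.

All constants are strictly positive rates or scales with the units noted on
each field; ``alpha`` (the apparent antigenic mismatch factor) is the single
dimensionless control parameter on [0, 1].  The defaults are the published
calibration of the model and are the values every simulation and analysis
routine uses unless explicitly overridden.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ModelParameters", "ParameterError"]


class ParameterError(ValueError):
    """Raised for out-of-domain or unknown model parameters."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate/shape constants of the six-variable immune model.

    Symbols follow the convention ``k_<target><source>`` for interaction
    rates, ``mu_*`` for decay rates, ``s_*`` for source terms and ``x_*`` for
    half-max scales of the sixth-order Hill saturations.
    """

    # Innate compartment (resting pool I_R and activated I)
    s_ir: float = 0.08     # source of resting innate components (I_R-units/h)
    mu_ir: float = 0.12    # decay of resting innate components (1/h)
    mu_i: float = 0.05     # decay of activated innate components (1/h)
    k_id: float = 0.02     # activation of I_R by DAMPs from damaged tissue (1/D-units/h)
    k_ii: float = 0.01     # self-activation of innate components (1/I-units/h)
    k_itp: float = 0.008   # activation of I_R by pro-inflammatory T cells (1/T_P-units/h)

    # Host damage D
    k_di: float = 0.35     # maximum host-tissue damage rate by I (D-units/h)
    x_di: float = 0.06     # I level giving half-max damage production (I-units)
    mu_d: float = 0.02     # tissue repair/regeneration rate (1/h, host and graft)

    # Graft damage D_G and graft-function curve G(D_G)
    k_dgig: float = 0.35   # maximum graft damage rate by innate components (D_G-units/h)
    k_dgtp: float = 0.7    # maximum graft damage rate by T_P, scaled by alpha (D_G-units/h)
    x_dgtp: float = 1.0    # T_P level giving half-max graft damage (T_P-units)
    k_gdg: float = 10.0    # shape constant of the graft-function curve (dimensionless)
    x_gdg: float = 0.5     # damage scale of the graft-function curve (D_G-units)

    # Anti-inflammatory mediators A
    s_a: float = 0.0125    # background source of A (A-units/h)
    k_ai: float = 0.04     # maximum induction of A by inflammation (A-units/h)
    k_aid: float = 48.0    # weight of host damage relative to I in A induction (I-units/D-units)
    mu_a: float = 0.1      # decay of A (1/h)
    k_ata: float = 0.001   # induction of A by anti-inflammatory T cells (1/T_A-units/h)

    # T-cell compartment (precursor pool T_0, effector T_P, regulatory T_A)
    s_t0: float = 1.0      # source of inactive memory T cells (T_0-units/h)
    mu_t0: float = 0.05    # decay of T_0 (1/h)
    k_tpi: float = 0.008   # T_P activation by innate components (1/I-units/h)
    k_tpig: float = 0.02   # T_P activation by innate components via allo-recognition (1/I-units/h)
    k_tpt0g: float = 0.02  # T_P self-expansion via allo-recognition (1/h)
    mu_tp: float = 0.03    # decay of activated T_P (1/h)
    k_taia: float = 0.04   # T_A induction by I in the presence of A (1/I-units/A-units/h)
    k_tat0g: float = 0.001 # alloreactive T_A self-expansion (1/h)
    mu_ta: float = 0.03    # decay of activated T_A (1/h)

    # Inhibition scales
    a_inf: float = 0.28    # strength scale of inhibition by A (A-units)
    b_inf: float = 0.5     # strength scale of inhibition by T_A (T_A-units)

    # Mismatch factor
    alpha: float = 0.0     # apparent antigenic mismatch, 0 = syngeneic, 1 = full mismatch

    # Merged-damage analysis only: graft-damage coefficient of the combined
    # host+graft damage variable.  Set equal to k_dgig, its graft analogue in
    # the full model; the merged-damage equilibria are insensitive to this
    # choice because the graft-function factor is ~0 at the elevated state.
    k_dig: float = 0.35

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or not (value == value):
                raise ParameterError(f"parameter {f.name!r} must be a finite number")
            if f.name == "alpha":
                if not 0.0 <= value <= 1.0:
                    raise ParameterError(f"alpha must lie in [0, 1], got {value}")
            elif value <= 0.0:
                raise ParameterError(f"parameter {f.name!r} must be strictly positive, got {value}")

    # -- derived quantities -------------------------------------------------

    @property
    def baseline_a(self) -> float:
        """Homeostatic anti-inflammatory level s_a/mu_a (0.125 at defaults)."""
        return self.s_a / self.mu_a

    @property
    def cap_i(self) -> float:
        """Upper bound on I at any equilibrium, s_ir/mu_i."""
        return self.s_ir / self.mu_i

    @property
    def cap_d(self) -> float:
        """Upper bound on D (or merged damage) at any equilibrium, k_di/mu_d."""
        return self.k_di / self.mu_d

    # -- construction / serialization ---------------------------------------

    def replace(self, **overrides: float) -> "ModelParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParameters":
        return cls().replace(**dict(mapping))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load a flat key/value parameter file (JSON or YAML by suffix)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ParameterError(f"{path}: expected a flat key/value mapping")
        return cls.from_mapping(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
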