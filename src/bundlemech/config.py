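"""Configuration files, state I/O and non-dimensionalization of physical inputs.

All model quantities are non-dimensional: lengths are scaled by the bundle
width ``W`` and stiffnesses by a reference bending stiffness ``B_s = 0.01``,
so ``L' = L/W``, ``N' = N/(B_s W^2)`` and ``K' = K/(B_s W^2)``.  Physical
rods of Young's modulus ``E`` and circular cross-section radius ``R`` carry
a bending stiffness ``pi E R^4 / 2``; the outer/inner ratio of those gives
``B_r``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

from .model import BundleState, ModelParams

__all__ = [
    "PhysicalInput",
    "nondimensionalize",
    "load_config",
    "save_config",
    "save_state",
    "load_state",
    "PRESETS",
]

B_S_DEFAULT = 0.01


@dataclass
class PhysicalInput:
    """Dimensional description of a bundle (mm / MPa units)."""

    width_mm: float
    length_mm: float
    E_outer_MPa: float
    E_inner_MPa: float
    R_outer_mm: float
    R_inner_mm: float
    B_s: float = B_S_DEFAULT

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name}: must be > 0")


def bending_coefficient(E: float, R: float) -> float:
    """Bending stiffness pi E R^4 / 2 of a circular-section rod."""
    return math.pi * E * R ** 4 / 2.0


def nondimensionalize(phys: PhysicalInput) -> dict:
    """Reduce a physical bundle to model parameters.

    Returns a dict with the scaled length ``L``, the bending coefficients
    ``B_outer``/``B_inner``, their ratio ``B_r`` and the load scale
    ``1/(B_s W^2)`` by which physical loads are multiplied.
    """
    L = phys.length_mm / phys.width_mm
    B_outer = bending_coefficient(phys.E_outer_MPa, phys.R_outer_mm)
    B_inner = bending_coefficient(phys.E_inner_MPa, phys.R_inner_mm)
    load_scale = 1.0 / (phys.B_s * phys.width_mm ** 2)
    return {
        "L": L,
        "B_outer": B_outer,
        "B_inner": B_inner,
        "B_r": B_outer / B_inner,
        "load_scale": load_scale,
    }


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_RUN_FIELDS = {"seed", "grid", "tol", "max_iter", "preset"}

#: Named parameter presets for the published phase-diagram variants.
PRESETS: dict[str, dict] = {
    # clamped baseline survey (m=10, L=5, K=2, B=1)
    "fig3e": {"m": 10, "L": 5.0, "K": 2.0, "B_in": 1.0, "boundary": "clamped"},
    # pinned-only boundary variant
    "fig5a": {"m": 10, "L": 5.0, "K": 2.0, "B_in": 1.0, "boundary": "pinned"},
    # twenty rods
    "fig5b": {"m": 20, "L": 5.0, "K": 2.0, "B_in": 1.0, "boundary": "clamped"},
    # doubled / halved matrix stiffness
    "fig5c": {"m": 10, "L": 5.0, "K": 4.0, "B_in": 1.0, "boundary": "clamped"},
    "fig5d": {"m": 10, "L": 5.0, "K": 1.0, "B_in": 1.0, "boundary": "clamped"},
    # strain-hardening matrix (lower overlap decay C2)
    "fig7": {"m": 10, "L": 5.0, "K": 2.0, "B_in": 1.0, "C2": 40.0,
             "boundary": "clamped"},
}


def load_config(path_or_dict, preset: str | None = None):
    """Read a JSON config into (ModelParams, run-options dict).

    Unknown keys are rejected, naming the offending field; parameter
    validation errors propagate from :class:`ModelParams` with the field
    name.  An empty config yields the full default parameter set.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = json.load(fh)
    preset = preset or raw.pop("preset", None)
    base: dict = {}
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        base.update(PRESETS[preset])
    run = {k: raw.pop(k) for k in list(raw) if k in _RUN_FIELDS}
    unknown = set(raw) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    base.update(raw)
    if "lateral_loads" in base and base["lateral_loads"] is not None:
        arr = np.asarray(base["lateral_loads"], dtype=float)
        base["lateral_loads"] = (
            tuple(arr) if arr.ndim == 1 else tuple(map(tuple, arr))
        )
    return ModelParams(**base), run


def save_config(params: ModelParams, path, run: dict | None = None) -> None:
    obj = params.to_dict()
    if run:
        obj.update(run)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def save_state(state: BundleState, params: ModelParams, path) -> None:
    """JSON container: {meta: parameter fields, theta: m x n angle matrix}."""
    with open(path, "w") as fh:
        json.dump(state.to_json(params), fh)


def load_state(path):
    with open(path) as fh:
        return BundleState.from_json(json.load(fh))
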