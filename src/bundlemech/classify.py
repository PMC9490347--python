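"""Classification of bundle configurations into the four deformation modes.

Three scalar diagnostics decide the label of a minimized state:

(i)  the mean absolute moment ``B_r <|kappa|>``: the per-joint curvature
     measure ``tan^2((theta_ij - theta_i(j-1))/2)`` averaged along each
     filament and over the filaments, multiplied by ``B_r`` (outer filaments
     deform less for the same load);
(ii) the same moment restricted to the outer and to the inner filaments;
(iii) the pinching parameter ``P`` in [0, 1]: the normalized angle
     antisymmetry between mirror filament pairs (i, m+1-i).

Decision rule, in order: moment below 1e-5 -> undeformed; inner/outer moment
ratio above 5 -> internal; P above 0.75 -> pinched; otherwise global.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BundleState, ModelParams

__all__ = [
    "Classification",
    "mean_absolute_moment",
    "pinching_parameter",
    "classify_state",
    "MOMENT_THRESHOLD",
    "INTERNAL_RATIO",
    "PINCH_THRESHOLD",
]

MOMENT_THRESHOLD = 1e-5   # below: undeformed
INTERNAL_RATIO = 5.0      # inner/outer moment ratio above: internal
PINCH_THRESHOLD = 0.75    # P above: pinched


@dataclass
class Classification:
    moment_all: float
    moment_outer: float
    moment_inner: float | None
    pinch: float
    label: str

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def mean_absolute_moment(params: ModelParams, state: BundleState,
                         subset: str = "all") -> float:
    """B_r x mean over filaments of the mean joint curvature measure.

    The curvature measure is |tan^2(dtheta/2)| per interior joint (no 1/2l
    weighting: this is the diagnostic, not the bending energy).  ``subset``
    selects all, outer (rows 1 and m) or inner filaments; the inner subset
    requires m >= 3.
    """
    theta = state.theta
    if subset == "all":
        rows = theta
    elif subset == "outer":
        rows = theta[[0, -1]]
    elif subset == "inner":
        if params.m < 3:
            raise ValueError("inner subset requires m >= 3 filaments")
        rows = theta[1:-1]
    else:
        raise ValueError(f"unknown subset {subset!r}")
    curv = np.tan(0.5 * np.diff(rows, axis=1)) ** 2
    return float(params.B_r * curv.mean(axis=1).mean())


def pinching_parameter(params: ModelParams, state: BundleState) -> float:
    """Normalized mirror antisymmetry of the angles, in [0, 1].

    P averages |theta_ij - theta_(m+1-i)j| / (|theta_ij| + |theta_(m+1-i)j|)
    over the n segments and the m_h mirror pairs (straight pairs, zero
    denominator, contribute nothing: they are evidence for neither symmetry
    nor antisymmetry).  P = 1 for exactly antisymmetric (pinched) states,
    P = 0 for symmetric (global/internal) ones.
    """
    theta = state.theta
    m = params.m
    m_h = m // 2
    upper = theta[m - 1:m - 1 - m_h:-1]   # rows m, m-1, ... (mirror order)
    lower = theta[:m_h]
    num = np.abs(lower - upper)
    den = np.abs(lower) + np.abs(upper)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / den, 0.0)
    return float(terms.sum() / (params.n * m_h))


def classify_state(params: ModelParams, state: BundleState) -> Classification:
    """Assign one of {undeformed, global, pinched, internal} to a state."""
    moment_all = mean_absolute_moment(params, state, "all")
    moment_outer = mean_absolute_moment(params, state, "outer")
    moment_inner = (
        mean_absolute_moment(params, state, "inner") if params.m >= 3 else None
    )
    pinch = pinching_parameter(params, state)

    if moment_all <= MOMENT_THRESHOLD:
        label = "undeformed"
    else:
        internal = False
        if moment_inner is not None:
            if moment_outer == 0.0:
                # formally infinite ratio: internal provided the inner
                # filaments are deformed at all
                internal = moment_inner > MOMENT_THRESHOLD
            else:
                internal = moment_inner / moment_outer > INTERNAL_RATIO
        if internal:
            label = "internal"
        elif pinch > PINCH_THRESHOLD:
            label = "pinched"
        else:
            label = "global"
    return Classification(moment_all, moment_outer, moment_inner, pinch, label)
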