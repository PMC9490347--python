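"""Geometry of a planar bundle of inextensible elastic filaments.

A bundle is ``m`` parallel rods of equal arc length ``L``, each discretized
into ``n`` straight segments of length ``l = L/n``.  The only degrees of
freedom are the segment angles ``theta[i, j]`` (filament ``i``, segment
``j``); node positions follow by cumulative summation, so inextensibility is
exact by construction.  The rods are stacked across a bundle width ``W``
(fixed to 1 after non-dimensionalization), giving a rest separation
``d0 = W/(m-1)`` between vertical neighbours.

This module holds the parameter container, the angle -> coordinate map, the
inter-filament spring distances (vertical and diagonal) and the triangle
areas used by the overlap penalty.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "BundleState",
    "BundleGeometry",
    "rest_state",
    "coordinates_from_angles",
    "pair_distances",
    "triangle_areas",
    "build_geometry",
]

_BOUNDARIES = ("pinned", "clamped")


@dataclass(frozen=True)
class ModelParams:
    """All material, penalty, load and discretization constants of a bundle.

    Parameters are non-dimensional throughout (see :mod:`bundlemech.config`
    for converting physical inputs).  ``boundary='clamped'`` implies the
    pinned constraint as well; both are imposed as stiff quadratic penalty
    potentials with stiffness ``C3``.
    """

    m: int = 10            # number of filaments (>= 2)
    n: int = 200           # segments per filament
    L: float = 5.0         # filament length / bundle width
    K: float = 2.0         # matrix (spring) stiffness
    B_in: float = 1.0      # inner-filament bending stiffness
    B_r: float = 1.0       # outer/inner bending-stiffness ratio (>= 1)
    Nc: float = 0.0        # axial compressive load per filament
    Np: float = 0.0        # pinching load on the outer filaments
    C1: float = 1e6        # overlap-penalty amplitude
    C2: float = 100.0      # overlap-penalty decay rate
    C3: float = 1e5        # boundary-constraint stiffness
    boundary: str = "clamped"
    W: float = 1.0         # bundle width; reference length, fixed at 1
    # Optional lateral-load override: per-filament (m,) or per-node (m, n)
    # values replacing the default (+Np on row m, -Np on row 1, 0 inside).
    lateral_loads: tuple | None = field(default=None)

    def __post_init__(self):
        if not isinstance(self.m, (int, np.integer)) or self.m < 2:
            raise ValueError("m: filament count must be an integer >= 2")
        if not isinstance(self.n, (int, np.integer)) or self.n < 2:
            raise ValueError("n: segment count must be an integer >= 2")
        for name in ("L", "B_in", "C1", "C2", "C3", "W"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be > 0")
        for name in ("K", "Nc", "Np"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")
        if self.B_r < 1:
            raise ValueError("B_r: outer/inner stiffness ratio must be >= 1")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary: must be one of {_BOUNDARIES}")
        if self.lateral_loads is not None:
            arr = np.asarray(self.lateral_loads, dtype=float)
            if arr.shape not in ((self.m,), (self.m, self.n)):
                raise ValueError("lateral_loads: shape must be (m,) or (m, n)")

    # ---- derived constants -------------------------------------------------

    @property
    def l(self) -> float:
        """Segment length L/n."""
        return self.L / self.n

    @property
    def d0(self) -> float:
        """Rest separation of vertically neighbouring nodes, W/(m-1)."""
        return self.W / (self.m - 1)

    @property
    def d0_diag(self) -> float:
        """Rest length of the diagonal springs, sqrt(d0^2 + l^2)."""
        return float(np.hypot(self.d0, self.l))

    @property
    def A0(self) -> float:
        """Rest area of each overlap triangle, l/(2(m-1))."""
        return self.l / (2.0 * (self.m - 1))

    def bending_stiffness(self) -> np.ndarray:
        """Per-filament bending stiffness: B_r*B_in on rows 1 and m."""
        B = np.full(self.m, self.B_in)
        B[0] = B[-1] = self.B_r * self.B_in
        return B

    def lateral_load_table(self) -> np.ndarray:
        """(m, n) table of lateral loads N_p(ij) acting on nodes j=1..n."""
        if self.lateral_loads is not None:
            arr = np.asarray(self.lateral_loads, dtype=float)
            if arr.ndim == 1:
                return np.repeat(arr[:, None], self.n, axis=1)
            return arr.copy()
        table = np.zeros((self.m, self.n))
        table[-1, :] = self.Np
        table[0, :] = -self.Np
        return table

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["lateral_loads"] is not None:
            d["lateral_loads"] = np.asarray(d["lateral_loads"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        ll = d.get("lateral_loads")
        if ll is not None:
            arr = np.asarray(ll, dtype=float)
            d["lateral_loads"] = tuple(arr.ravel()) if arr.ndim == 1 else tuple(
                map(tuple, arr)
            )
        return cls(**d)

    def content_hash(self) -> str:
        """Stable hash of the parameter values (used for sweep caching)."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:16]

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)


@dataclass
class BundleState:
    """An m x n matrix of segment angles (radians); theta=0 is the rest state."""

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2-D (m, n) array")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta entries must be finite")

    @property
    def m(self) -> int:
        return self.theta.shape[0]

    @property
    def n(self) -> int:
        return self.theta.shape[1]

    def copy(self) -> "BundleState":
        return BundleState(self.theta.copy())

    def to_json(self, params: ModelParams) -> dict:
        return {"meta": params.to_dict(), "theta": self.theta.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> tuple["BundleState", ModelParams]:
        params = ModelParams.from_dict(obj["meta"])
        state = cls(np.asarray(obj["theta"], dtype=float))
        if state.theta.shape != (params.m, params.n):
            raise ValueError("theta shape does not match meta (m, n)")
        return state, params


@dataclass
class BundleGeometry:
    """Derived node coordinates, spring distances and overlap-triangle areas.

    coords   : (m, n+1, 2) node positions, node j=0 fixed at x=0.
    d        : (m-1, n+1)  vertical neighbour distances d_ij, j=0..n.
    d_plus   : (m-1, n)    forward diagonals, stored index jj <-> j=jj
                           (pairs node (i, j) with (i+1, j+1); no j=n term).
    d_minus  : (m-1, n)    backward diagonals, stored index jj <-> j=jj+1
                           (pairs node (i, j) with (i+1, j-1); no j=0 term).
    areas    : (m-1, n, 2) the two triangles of each quad (i, j), j=0..n-1.
    """

    coords: np.ndarray
    d: np.ndarray
    d_plus: np.ndarray
    d_minus: np.ndarray
    areas: np.ndarray


def rest_state(params: ModelParams) -> BundleState:
    """The straight configuration: all angles zero."""
    return BundleState(np.zeros((params.m, params.n)))


def coordinates_from_angles(params: ModelParams, state: BundleState) -> np.ndarray:
    """Map angles to node coordinates by cumulative summation.

    Node j of filament i sits at the running sum of segment vectors
    (l cos theta, l sin theta), offset vertically by (i-1)*d0; node 0 is
    clamped to x=0 for every filament, so each segment has length exactly l.
    """
    if state.theta.shape != (params.m, params.n):
        raise ValueError(
            f"state shape {state.theta.shape} does not match params "
            f"(m, n)=({params.m}, {params.n})"
        )
    l = params.l
    coords = np.empty((params.m, params.n + 1, 2))
    coords[:, 0, 0] = 0.0
    coords[:, 0, 1] = np.arange(params.m) * params.d0
    np.cumsum(l * np.cos(state.theta), axis=1, out=coords[:, 1:, 0])
    coords[:, 1:, 1] = coords[:, 0, 1][:, None] + np.cumsum(
        l * np.sin(state.theta), axis=1
    )
    return coords


def pair_distances(coords: np.ndarray):
    """Vertical and diagonal spring distances between neighbouring filaments."""
    vert = coords[1:] - coords[:-1]                   # (m-1, n+1, 2)
    dp = coords[1:, 1:] - coords[:-1, :-1]            # node (i,j)->(i+1,j+1)
    dm = coords[1:, :-1] - coords[:-1, 1:]            # node (i,j)->(i+1,j-1)
    d = np.linalg.norm(vert, axis=-1)
    d_plus = np.linalg.norm(dp, axis=-1)
    d_minus = np.linalg.norm(dm, axis=-1)
    return d, d_plus, d_minus


def triangle_areas(coords: np.ndarray) -> np.ndarray:
    """Areas of the two triangles spanned by each quad of neighbouring nodes.

    Quad (i, j) is the four nodes (i,j), (i+1,j), (i,j+1), (i+1,j+1).  Its
    forward diagonal splits it into triangle 1 (vectors d_ij and d+_ij from
    base node (i,j)) and triangle 2 (vectors d_i(j+1) and d+_ij into node
    (i+1,j+1)); each area is half the absolute 2-D cross product.
    """
    u1 = coords[1:, :-1] - coords[:-1, :-1]   # d_ij
    w = coords[1:, 1:] - coords[:-1, :-1]     # d+_ij
    u2 = coords[1:, 1:] - coords[:-1, 1:]     # d_i(j+1)
    cross1 = u1[..., 0] * w[..., 1] - u1[..., 1] * w[..., 0]
    cross2 = u2[..., 0] * w[..., 1] - u2[..., 1] * w[..., 0]
    return 0.5 * np.stack([np.abs(cross1), np.abs(cross2)], axis=-1)


def build_geometry(params: ModelParams, state: BundleState) -> BundleGeometry:
    """Assemble coordinates, spring distances and areas in one pass."""
    coords = coordinates_from_angles(params, state)
    d, d_plus, d_minus = pair_distances(coords)
    areas = triangle_areas(coords)
    return BundleGeometry(coords, d, d_plus, d_minus, areas)


def coordinates_to_csv(coords: np.ndarray, path) -> None:
    """Export node coordinates with columns filament,index,x,y (1-based ids)."""
    import pandas as pd

    m, npts, _ = coords.shape
    fil, idx = np.meshgrid(np.arange(1, m + 1), np.arange(npts), indexing="ij")
    pd.DataFrame(
        {
            "filament": fil.ravel(),
            "index": idx.ravel(),
            "x": coords[..., 0].ravel(),
            "y": coords[..., 1].ravel(),
        }
    ).to_csv(path, index=False)
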