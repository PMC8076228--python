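"""Core domain types and geometric primitives for the suture interface model.

The model describes an osteogenic front separating differentiated bone
(``u ~ 1``) from undifferentiated mesenchyme (``u ~ 0``).  The front moves
in its normal direction with speed

    V = f(v) - sigma * kappa

where ``f(v) = alpha * (v - v_c)`` converts the local concentration of a
diffusible osteogenesis-promoting factor ``v`` into a differentiation speed,
and ``sigma * kappa`` is a surface-tension penalty on curvature of the bone
front (``kappa > 0`` where bone protrudes into mesenchyme).

Axis conventions used throughout the package: arrays are indexed
``[row, col] == [y, x]``; the suture runs along ``y`` (axis 0, periodic) and
bone growth happens along ``x`` (axis 1, no-flux).  ``nx`` counts columns,
``ny`` rows, so field arrays have shape ``(ny, nx)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "SimulationParams",
    "FieldState",
    "InterfaceCurve",
    "forcing",
    "curvature",
    "extract_interface",
]

#: floor on the gradient magnitude (in units of 1/dx) used when normalising
#: grad(u); kappa is only consumed on the interface band where |grad u| = O(1/eps).
GRADIENT_FLOOR = 1.0e-8


@dataclass(frozen=True)
class SimulationParams:
    """All model and numerical constants for one simulation.

    Parameters
    ----------
    alpha:
        Efficacy of the factor on osteogenesis: front speed per unit
        concentration excess over ``v_c``.
    sigma:
        Surface-tension coefficient: front speed per unit curvature.
    v_c:
        Critical factor concentration at which osteogenesis and bone
        resorption balance (the front is stationary).
    D_v:
        Diffusion coefficient of the factor (length^2 / time).
    c:
        Passive soft-tissue expansion speed (length / time, >= 0).
    k_p, k_d:
        Production rate of the factor in mesenchyme and its first-order
        decay rate.  The saturation concentration is ``k_p / k_d``.
    nx, ny:
        Lattice size: ``nx`` columns (growth axis x), ``ny`` rows (suture
        axis y).
    dx, dt:
        Lattice spacing and time step.
    t_end:
        Simulation length in model time units.
    eps:
        Diffuse-interface width of the phase-field regularisation; must be
        resolvable, ``eps >= 2 dx``.
    seed:
        RNG seed controlling the initial interface perturbation.
    noise_amp:
        Amplitude (standard deviation, length units) of the initial
        per-row interface perturbation.

    All quantities are dimensionless model units; the source publication's
    lattice constants (``128 x 128``, ``dx = 50``, ``dt = 2``, length 6000)
    are the defaults.
    """

    alpha: float = 2.5
    sigma: float = 80.0
    v_c: float = 0.4
    D_v: float = 6.25e4
    c: float = 0.1
    k_p: float = 0.25
    k_d: float = 0.25
    nx: int = 128
    ny: int = 128
    dx: float = 50.0
    dt: float = 2.0
    t_end: float = 6000.0
    eps: float = 100.0
    seed: int = 0
    noise_amp: float = 50.0

    def __post_init__(self) -> None:
        positive = {
            "alpha": self.alpha,
            "sigma": self.sigma,
            "D_v": self.D_v,
            "k_p": self.k_p,
            "k_d": self.k_d,
            "dx": self.dx,
            "dt": self.dt,
            "eps": self.eps,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c!r}")
        if self.v_c < 0:
            raise ValueError(f"v_c must be >= 0, got {self.v_c!r}")
        if self.t_end < 0:
            raise ValueError(f"t_end must be >= 0, got {self.t_end!r}")
        if self.noise_amp < 0:
            raise ValueError(f"noise_amp must be >= 0, got {self.noise_amp!r}")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("lattice must be at least 3x3")
        if self.eps < 2.0 * self.dx:
            raise ValueError(
                f"eps must be >= 2*dx so the interface is resolvable "
                f"(eps={self.eps}, dx={self.dx})"
            )
        if self.dt * self.k_d >= 1.0:
            raise ValueError(
                f"dt*k_d must be < 1 (got {self.dt * self.k_d}); "
                "reduce dt or the decay rate k_d"
            )

    # -- convenience -------------------------------------------------------

    def replace(self, **changes: Any) -> "SimulationParams":
        """Return a copy with some fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def width(self) -> float:
        """Physical domain width along the growth axis, ``nx * dx``."""
        return self.nx * self.dx

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationParams":
        """Build from a flat mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for name in ("nx", "ny", "seed"):
            if name in kwargs:
                kwargs[name] = int(kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationParams":
        """Load from a flat YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"config {path} must be a flat mapping")
        return cls.from_dict(data)


@dataclass
class FieldState:
    """Paired lattices of the two fields at one time point.

    ``u`` is the bone differentiation degree (1 = bone, 0 = mesenchyme),
    ``v`` the factor concentration.  ``inserted_columns`` counts cumulative
    growth insertions; ``growth_accum`` is the fractional column accumulator
    used by the growth operator.
    """

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    inserted_columns: int = 0
    growth_accum: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError(
                f"u and v shapes differ: {self.u.shape} vs {self.v.shape}"
            )
        if self.u.ndim != 2:
            raise ValueError("fields must be 2-D")

    def validate(self) -> None:
        """Raise if any field invariant is violated."""
        if not np.all(np.isfinite(self.u)) or not np.all(np.isfinite(self.v)):
            raise FloatingPointError(f"non-finite field values at t={self.t}")
        if self.u.min() < -1e-12 or self.u.max() > 1 + 1e-12:
            raise ValueError(f"u out of [0,1] at t={self.t}")
        if self.v.min() < -1e-12:
            raise ValueError(f"v negative at t={self.t}")
        if self.inserted_columns < 0:
            raise ValueError("inserted_columns must be >= 0")

    def copy(self) -> "FieldState":
        return FieldState(
            u=self.u.copy(),
            v=self.v.copy(),
            t=self.t,
            inserted_columns=self.inserted_columns,
            growth_accum=self.growth_accum,
        )


@dataclass
class InterfaceCurve:
    """Per-row (transect) left/right interface positions of the u=0.5 level.

    Positions are physical lengths (sub-pixel, linearly interpolated).
    Rows with no crossing are flagged invalid; for rows with a single
    crossing left == right.
    """

    left: np.ndarray
    right: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.left.shape == self.right.shape == self.valid.shape):
            raise ValueError("left/right/valid must share one shape")
        if np.any(self.left[self.valid] > self.right[self.valid] + 1e-9):
            raise ValueError("left > right on a valid row")

    @property
    def widths(self) -> np.ndarray:
        """right - left on valid rows (NaN elsewhere)."""
        w = np.full_like(self.left, np.nan)
        w[self.valid] = self.right[self.valid] - self.left[self.valid]
        return w

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def mean_width(self) -> float:
        """Mean suture width over valid transects (NaN if none)."""
        if self.n_valid == 0:
            return float("nan")
        return float(np.nanmean(self.widths))


def forcing(v_value: float | np.ndarray, params: SimulationParams) -> np.ndarray | float:
    """Differentiation forcing f(v) = alpha * (v - v_c).

    Positive values advance the osteogenic front into mesenchyme (bone
    grows, suture narrows); negative values retreat it.  Vanishes exactly
    at the critical concentration ``v_c`` where osteogenesis and resorption
    balance.
    """
    v_arr = np.asarray(v_value, dtype=float)
    if not np.all(np.isfinite(v_arr)):
        raise ValueError("forcing: non-finite concentration input")
    out = params.alpha * (v_arr - params.v_c)
    if np.isscalar(v_value) or v_arr.ndim == 0:
        return float(out)
    return out


def curvature(u: np.ndarray, dx: float) -> np.ndarray:
    """Signed curvature field kappa = -div(grad u / |grad u|).

    Centered differences with a gradient-magnitude floor so bulk regions
    (where |grad u| ~ 0) return finite values.  Sign convention: kappa > 0
    where the bone region (u ~ 1) is locally convex, protruding into
    mesenchyme, so a velocity term ``-sigma*kappa`` retards protrusions.
    Only meaningful on the interface band.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or min(u.shape) < 3:
        raise ValueError("curvature needs a 2-D field with >=3 sites per axis")
    gy, gx = np.gradient(u, dx)
    gmag = np.sqrt(gx * gx + gy * gy)
    floor = GRADIENT_FLOOR / dx
    gmag = np.maximum(gmag, floor)
    nxc = gx / gmag
    nyc = gy / gmag
    div = np.gradient(nxc, dx, axis=1) + np.gradient(nyc, dx, axis=0)
    # u increases towards bone, so grad u / |grad u| is the inward bone
    # normal; the outward-normal divergence carries the opposite sign.
    return -div


def extract_interface(u: np.ndarray, dx: float) -> InterfaceCurve:
    """Locate the u = 0.5 level per row by linear interpolation.

    For each row (transect perpendicular to the growth axis) the first and
    last crossings of the 0.5 level between adjacent columns give the left
    and right interface positions in physical units.  Rows without any
    crossing are flagged invalid (not an error: a uniform field simply has
    zero valid rows).
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("extract_interface expects a 2-D field")
    if np.nanmin(u) < -1e-9 or np.nanmax(u) > 1 + 1e-9:
        raise ValueError("u must lie in [0, 1]")
    ny = u.shape[0]
    left = np.full(ny, np.nan)
    right = np.full(ny, np.nan)
    valid = np.zeros(ny, dtype=bool)
    s = u - 0.5
    sign_change = s[:, :-1] * s[:, 1:] < 0
    # exact hits on 0.5 at a lattice site
    exact = np.abs(s) < 1e-12
    for j in range(ny):
        xs: list[float] = []
        idx = np.flatnonzero(sign_change[j])
        for i in idx:
            frac = (0.5 - u[j, i]) / (u[j, i + 1] - u[j, i])
            xs.append((i + frac) * dx)
        for i in np.flatnonzero(exact[j]):
            xs.append(i * dx)
        if xs:
            valid[j] = True
            left[j] = min(xs)
            right[j] = max(xs)
    return InterfaceCurve(left=left, right=right, valid=valid)
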