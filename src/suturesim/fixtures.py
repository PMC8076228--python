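"""Synthetic suture images and phase-field test fields with known ground truth.

Sinusoidal bands stand in for specimen photographs: their width, amplitude
and arc length have closed forms, so every morphometric operation can be
validated without real data.  Step and disc fields provide analytic
interfaces for front-speed and curvature oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .morphometrics import SpecimenImage

__all__ = [
    "FixtureSpec",
    "SutureGroundTruth",
    "make_sinusoidal_suture",
    "make_step_field",
    "make_disc_field",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic sinusoidal suture image.

    The band centreline is ``x(y) = center + A sin(2 pi y / wavelength)``;
    the suture mask contains pixels within ``width/2`` of the centreline
    measured along x (``thickness='horizontal'``) or within ``width/2``
    Euclidean distance of the curve (``thickness='normal'``).
    """

    height: int = 256
    width_px: int = 128
    center: float = 64.0
    band_width: float = 5.0
    amplitude: float = 10.0
    wavelength: float = 64.0
    suture_level: float = 20.0
    bone_level: float = 200.0
    noise_sd: float = 0.0
    pixel_size: float = 0.05
    seed: int = 0
    thickness: str = "horizontal"

    def __post_init__(self) -> None:
        if self.band_width < 1:
            raise ValueError("band width must be >= 1 px")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.suture_level == self.bone_level:
            raise ValueError("intensity levels must be distinct")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.thickness not in ("horizontal", "normal"):
            raise ValueError("thickness must be 'horizontal' or 'normal'")
        reach = self.amplitude + 0.5 * self.band_width
        if self.center - reach < 0 or self.center + reach > self.width_px - 1:
            raise ValueError("band exits the image for this amplitude/width")


@dataclass
class SutureGroundTruth:
    """Machine-readable truth emitted alongside every fixture image."""

    mask: np.ndarray
    centerline: np.ndarray
    band_width: float
    amplitude: float
    wavelength: float
    arc_length_px: float
    pixel_size: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "band_width": self.band_width,
            "amplitude": self.amplitude,
            "wavelength": self.wavelength,
            "arc_length_px": self.arc_length_px,
            "pixel_size": self.pixel_size,
        }


def _arc_length_quadrature(amplitude: float, wavelength: float, height: int) -> float:
    """Arc length (px) of the sinusoid over ``height`` rows, by quadrature."""
    y = np.linspace(0.0, height - 1.0, 20 * height + 1)
    slope = amplitude * (2.0 * np.pi / wavelength) * np.cos(2.0 * np.pi * y / wavelength)
    return float(np.trapezoid(np.sqrt(1.0 + slope**2), y))


def make_sinusoidal_suture(
    spec: FixtureSpec,
) -> tuple[SpecimenImage, SutureGroundTruth]:
    """Generate one sinusoidal suture image plus its ground truth.

    Deterministic under ``spec.seed``.
    """
    H, W = spec.height, spec.width_px
    y = np.arange(H)
    cx = spec.center + spec.amplitude * np.sin(2.0 * np.pi * y / spec.wavelength)
    xs = np.arange(W)
    if spec.thickness == "horizontal":
        mask = np.abs(xs[None, :] - cx[:, None]) <= 0.5 * spec.band_width
    else:
        # Euclidean distance to a densely sampled centreline polyline
        from scipy.spatial import cKDTree

        yy = np.linspace(0.0, H - 1.0, 8 * H)
        pts = np.column_stack(
            [yy, spec.center + spec.amplitude * np.sin(2.0 * np.pi * yy / spec.wavelength)]
        )
        tree = cKDTree(pts)
        gy, gx = np.mgrid[0:H, 0:W]
        d, _ = tree.query(np.column_stack([gy.ravel(), gx.ravel()]), workers=-1)
        mask = (d.reshape(H, W)) <= 0.5 * spec.band_width
    img = np.where(mask, spec.suture_level, spec.bone_level).astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = SpecimenImage(
        pixels=img,
        pixel_size=spec.pixel_size,
        suture_axis="y",
        label=f"sinusoid w={spec.band_width} A={spec.amplitude} lam={spec.wavelength}",
    )
    truth = SutureGroundTruth(
        mask=mask,
        centerline=cx,
        band_width=spec.band_width,
        amplitude=spec.amplitude,
        wavelength=spec.wavelength,
        arc_length_px=_arc_length_quadrature(spec.amplitude, spec.wavelength, H),
        pixel_size=spec.pixel_size,
    )
    return image, truth


def make_step_field(
    nx: int, ny: int, position: float, eps: float, dx: float = 1.0
) -> np.ndarray:
    """Planar tanh interface: u(x) = (1 + tanh((x - position)/eps)) / 2.

    ``position`` and ``eps`` are in physical units (``x = col * dx``); bone
    (u=1) lies at large x.  Note the equilibrium profile of the simulator's
    double well has scale ``2*eps_param``, i.e. pass ``eps = 2 * params.eps``
    to build an equilibrium front.
    """
    if not (0 < position < (nx - 1) * dx):
        raise ValueError("step position must be interior")
    x = np.arange(nx) * dx
    row = 0.5 * (1.0 + np.tanh((x - position) / eps))
    return np.tile(row, (ny, 1))


def make_disc_field(
    nx: int,
    ny: int,
    center: tuple[float, float],
    radius: float,
    eps: float,
    phase: str = "bone",
    dx: float = 1.0,
) -> np.ndarray:
    """Radially symmetric tanh disc: bone disc in mesenchyme or the reverse.

    ``phase='bone'`` gives u=1 inside the disc (bone inclusion);
    ``phase='hole'`` gives u=0 inside (mesenchyme hole in bone); the two are
    exact complements.  ``center`` is (x, y) in physical units.  The disc
    must keep a 5*eps margin from every domain edge.
    """
    if phase not in ("bone", "hole"):
        raise ValueError("phase must be 'bone' or 'hole'")
    cx, cy = center
    margin = radius + 5.0 * eps
    if (
        cx - margin < 0
        or cx + margin > (nx - 1) * dx
        or cy - margin < 0
        or cy + margin > (ny - 1) * dx
    ):
        raise ValueError("disc violates the 5*eps margin from the domain edge")
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    r = np.hypot(x[None, :] - cx, y[:, None] - cy)
    inside = 0.5 * (1.0 + np.tanh((radius - r) / eps))
    return inside if phase == "bone" else 1.0 - inside
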