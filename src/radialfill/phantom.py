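"""Analytic ellipse phantoms and their closed-form projections.

Every test and experiment in this package runs on synthetic data built
here: a phantom is a list of constant-intensity ellipses, its parallel-beam
projections have a closed form (the Radon transform of an ellipse), and the
matching radial k-space follows from the projection-slice theorem by taking
the centered 1D DFT of each projection.

The image field of view is the unit square: radial positions span the
interval [-1, 1) on the centered grid ``s_n = (n - L//2) * (2/L)``, so the
chord-length formulas are unitless and the rotation center falls exactly on
the sample at index ``L//2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .containers import RadialKSpace, Sinogram

__all__ = [
    "Ellipse",
    "Phantom",
    "make_phantom",
    "analytic_projection",
    "sinogram_from_phantom",
    "kspace_from_sinogram",
    "rasterize_phantom",
    "radial_positions",
    "PHANTOM_NAMES",
]


@dataclass(frozen=True)
class Ellipse:
    """Constant-intensity ellipse: center, semi-axes, rotation, intensity.

    ``rho`` is additive and may be negative (overlapping ellipses sum), the
    standard construction of head phantoms.
    """

    cx: float
    cy: float
    a: float
    b: float
    phi_deg: float
    rho: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class Phantom:
    ellipses: list[Ellipse]

    def __post_init__(self) -> None:
        if not self.ellipses:
            raise ValueError("phantom must contain at least one ellipse")
        self.ellipses = [e if isinstance(e, Ellipse) else Ellipse(*e)
                         for e in self.ellipses]

    @classmethod
    def from_json(cls, path) -> "Phantom":
        """Load a phantom from a JSON list of 6-element rows
        ``[cx, cy, a, b, phi_deg, rho]``."""
        with open(path) as fh:
            rows = json.load(fh)
        return cls([Ellipse(*row) for row in rows])

    def to_json(self, path) -> None:
        rows = [[e.cx, e.cy, e.a, e.b, e.phi_deg, e.rho] for e in self.ellipses]
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)

    def area_integral(self) -> float:
        """Total mass: sum of rho × ellipse area."""
        return float(sum(np.pi * e.a * e.b * e.rho for e in self.ellipses))


# Classic 10-ellipse head phantom (Shepp & Logan parameter table).
_SHEPP_LOGAN = [
    (0.0, 0.0, 0.69, 0.92, 0.0, 2.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.98),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.02),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.02),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.01),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.01),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.01),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.01),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.01),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.01),
]

# Packaged default for the view-interpolation experiments: a faint centered
# circular background (its projections are identical at every angle, so it
# is neutral to all view-filling methods) plus two equal compact features on
# a ring at radius 0.7.  Off-center structure is what makes the
# rotated-ghost artifacts of convolution-based view interpolation visible —
# they grow with distance from the rotation center.  Each feature is a
# stack of nested concentric shells, giving a smooth-edged dome profile:
# its projection trace sweeps several radial samples per view gap (the
# regime the displacement estimator is designed for) without the
# unbounded edge slope of a single hard disk.  The 20° separation makes
# the two traces merge slowly when they cross.
def _bead(r: float, angle_deg: float, w: float, rho: float,
          n_shells: int = 6) -> list[tuple]:
    cx = r * np.cos(np.deg2rad(angle_deg))
    cy = r * np.sin(np.deg2rad(angle_deg))
    return [(cx, cy, w * j / n_shells, w * j / n_shells, 0.0, rho / n_shells)
            for j in range(1, n_shells + 1)]


_ROTATING_FEATURES = (
    [(0.0, 0.0, 0.88, 0.88, 0.0, 0.2)]
    + _bead(0.7, 10.0, 0.12, 1.0)
    + _bead(0.7, 30.0, 0.12, 1.0)
)

_PHANTOMS = {
    "disk": [(0.0, 0.0, 0.6, 0.6, 0.0, 1.0)],
    "rotating_features": _ROTATING_FEATURES,
    "shepp_logan_like": _SHEPP_LOGAN,
}

PHANTOM_NAMES = tuple(sorted(_PHANTOMS))


def make_phantom(name: str) -> Phantom:
    """Return a packaged phantom by name.

    ``"disk"`` — a single centered circle (rotationally symmetric; every
    projection is identical).  ``"rotating_features"`` — background ellipse
    plus off-center features, the default for interpolation experiments.
    ``"shepp_logan_like"`` — the standard 10-ellipse head phantom.
    """
    try:
        rows = _PHANTOMS[name]
    except KeyError:
        raise ValueError(
            f"unknown phantom {name!r}; valid names: {', '.join(PHANTOM_NAMES)}"
        ) from None
    return Phantom([Ellipse(*row) for row in rows])


def radial_positions(n_radial: int) -> np.ndarray:
    """Centered radial grid ``s_n = (n - L//2) * (2/L)`` spanning [-1, 1)."""
    return (np.arange(n_radial) - n_radial // 2) * (2.0 / n_radial)


def analytic_projection(ph: Phantom, angle_deg: float,
                        radial_positions: np.ndarray) -> np.ndarray:
    """Closed-form parallel projection of the phantom at one angle.

    For an ellipse with semi-axes ``a, b``, rotation ``phi`` and center
    ``(cx, cy)``, the line integral along the ray at angle θ and signed
    distance s is ``2·rho·a·b·sqrt(A² − s'²)/A²`` where
    ``A² = a²cos²(θ−phi) + b²sin²(θ−phi)`` and
    ``s' = s − cx·cosθ − cy·sinθ``; zero outside the support.  For a
    centered disk this reduces to the chord length ``2·rho·sqrt(r² − s²)``.
    """
    s = np.asarray(radial_positions, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("radial positions must be finite")
    theta = np.deg2rad(angle_deg)
    out = np.zeros_like(s)
    for e in ph.ellipses:
        rel = theta - np.deg2rad(e.phi_deg)
        A2 = (e.a * np.cos(rel)) ** 2 + (e.b * np.sin(rel)) ** 2
        sp = s - e.cx * np.cos(theta) - e.cy * np.sin(theta)
        inside = sp ** 2 < A2
        out[inside] += 2.0 * e.rho * e.a * e.b * np.sqrt(A2 - sp[inside] ** 2) / A2
    return out


def sinogram_from_phantom(ph: Phantom, n_views: int, coverage_deg: float,
                          n_radial: int) -> Sinogram:
    """Noise-free analytic sinogram on a uniform angular grid.

    View ``m`` sits at angle ``m · coverage_deg / n_views``; the endpoint
    angle is excluded because it duplicates view 0 (360°) or its conjugate
    (180°).
    """
    if n_views < 2:
        raise ValueError("need at least 2 views")
    if n_radial < 3:
        raise ValueError("need at least 3 radial samples")
    s = radial_positions(n_radial)
    angles = np.arange(n_views) * (coverage_deg / n_views)
    values = np.empty((n_radial, n_views))
    for m, ang in enumerate(angles):
        values[:, m] = analytic_projection(ph, ang, s)
    return Sinogram(values=values, angles_deg=angles,
                    coverage_deg=coverage_deg,
                    delta_gamma_deg=coverage_deg / n_views)


def kspace_from_sinogram(s: Sinogram) -> RadialKSpace:
    """Centered forward 1D DFT of each projection: sinogram → radial spokes.

    Exact inverse of :func:`radialfill.containers.ifft_radial` (the
    projection-slice theorem in discrete form).
    """
    if s.is_complex:
        raise ValueError("expected a real sinogram")
    spokes = np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(s.values, axes=0), axis=0), axes=0
    )
    return RadialKSpace(samples=spokes, angles_deg=s.angles_deg,
                        coverage_deg=s.coverage_deg)


def rasterize_phantom(ph: Phantom, size: int) -> np.ndarray:
    """Pixel-grid rendering of the phantom on the FBP output grid.

    Pixel (row i, col j) maps to ``x = (j - size//2)·Δs``,
    ``y = (size//2 - i)·Δs`` with ``Δs = 2/size`` — the same geometry the
    reconstruction module uses, so rasterizations are directly comparable
    to FBP outputs.
    """
    ds = 2.0 / size
    j = (np.arange(size) - size // 2) * ds
    i = (size // 2 - np.arange(size)) * ds
    x, y = np.meshgrid(j, i)
    img = np.zeros((size, size))
    for e in ph.ellipses:
        phi = np.deg2rad(e.phi_deg)
        xr = (x - e.cx) * np.cos(phi) + (y - e.cy) * np.sin(phi)
        yr = -(x - e.cx) * np.sin(phi) + (y - e.cy) * np.cos(phi)
        img[(xr / e.a) ** 2 + (yr / e.b) ** 2 <= 1.0] += e.rho
    return img


def add_complex_noise(k: RadialKSpace, sigma: float,
                      rng: np.random.Generator) -> RadialKSpace:
    """Additive circular complex Gaussian noise on the spokes (default-off
    option for simulations; the packaged experiments are noise-free)."""
    noise = rng.normal(scale=sigma, size=k.samples.shape) \
        + 1j * rng.normal(scale=sigma, size=k.samples.shape)
    return RadialKSpace(samples=k.samples + noise,
                        angles_deg=k.angles_deg, coverage_deg=k.coverage_deg)
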