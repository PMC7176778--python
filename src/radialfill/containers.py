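"""Core data containers and spoke-wise transforms for radial MRI data.

A radial acquisition measures complex k-space samples along spokes through
the origin.  By the projection-slice theorem, the centered 1D inverse
Fourier transform of each spoke is one parallel-beam projection of the
object, so the stack of transformed spokes is a sinogram ``p(n, m)`` with
radial index ``n`` and view index ``m``.

Conventions used throughout the package:

* 0-based indexing; the rotation center corresponds to radial index
  ``n_center = readout_len // 2``.
* Spokes are stored with the DC sample at the center index, and all spoke
  transforms use an explicit center-shift (``fftshift``) convention so that
  the radial axis is aligned across views.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RadialKSpace",
    "Sinogram",
    "DisplacementField",
    "ReconImage",
    "ifft_radial",
    "magnitude",
    "undersample_views",
]


@dataclass
class RadialKSpace:
    """Complex radial k-space data: one spoke per view.

    Parameters
    ----------
    samples : (readout_len, n_views) complex ndarray
        Spoke samples, DC at row ``readout_len // 2``.
    angles_deg : (n_views,) float ndarray
        View angles in degrees, strictly increasing within
        ``[0, coverage_deg)``.
    coverage_deg : float
        Total angular span of the acquisition (180 or 360).
    """

    samples: np.ndarray
    angles_deg: np.ndarray
    coverage_deg: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D (readout, view) array")
        if self.angles_deg.ndim != 1 or len(self.angles_deg) != self.n_views:
            raise ValueError(
                f"angles_deg has {self.angles_deg.size} entries for "
                f"{self.n_views} views"
            )
        if self.n_views and (
            np.any(np.diff(self.angles_deg) <= 0)
            or self.angles_deg[0] < 0
            or self.angles_deg[-1] >= self.coverage_deg
        ):
            raise ValueError(
                "angles must be strictly increasing within [0, coverage_deg)"
            )

    @property
    def readout_len(self) -> int:
        return self.samples.shape[0]

    @property
    def n_views(self) -> int:
        return self.samples.shape[1]


@dataclass
class Sinogram:
    """Projection-domain data ``p(n, m)``: radial index × view index.

    ``delta_gamma_deg`` is the nominal spacing between adjacent views; it is
    the quantity halved by every interpolation factor of 2 and the rotation
    angle of the ghost components produced by linear view interpolation.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    coverage_deg: float
    delta_gamma_deg: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (radial, view) array")
        if len(self.angles_deg) != self.n_views:
            raise ValueError(
                f"angles_deg has {self.angles_deg.size} entries for "
                f"{self.n_views} views"
            )
        if self.delta_gamma_deg <= 0:
            raise ValueError("delta_gamma_deg must be positive")

    @property
    def n_radial(self) -> int:
        return self.values.shape[0]

    @property
    def n_views(self) -> int:
        return self.values.shape[1]

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.values)

    def with_values(self, values: np.ndarray) -> "Sinogram":
        """Copy of this sinogram with new values, same geometry."""
        return replace(self, values=np.asarray(values))


@dataclass
class DisplacementField:
    """Integer displacement ``u(n)`` linking an ordered pair of views.

    The field satisfies ``p(n, m2) ≈ p(n + u(n), m1)``: it maps the radial
    coordinate of view ``m2`` back onto view ``m1``.  Every entry is an
    integer bounded by ``|u(n)| <= bound_N``.
    """

    u: np.ndarray
    bound_N: int
    pair: tuple[int, int]
    lambda_reg: float = 0.001

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if not np.issubdtype(self.u.dtype, np.integer):
            if not np.all(self.u == np.round(self.u)):
                raise ValueError("displacement entries must be integers")
            self.u = self.u.astype(np.int64)
        if self.bound_N < 1:
            raise ValueError("bound_N must be a positive integer")
        if np.any(np.abs(self.u) > self.bound_N):
            raise ValueError(f"|u(n)| must not exceed bound_N={self.bound_N}")
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair must contain two distinct view indices")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass
class ReconImage:
    """Square reconstructed image with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def ifft_radial(k: RadialKSpace) -> Sinogram:
    """Centered 1D inverse DFT of every spoke: k-space → (complex) sinogram.

    The DC sample of each spoke (stored at row ``readout_len // 2``) maps to
    the central radial index of the projection.  Angular metadata is carried
    over unchanged.
    """
    if k.n_views == 0:
        raise ValueError("k-space contains no views")
    if k.readout_len < 2:
        raise ValueError("readout length must be at least 2")
    p = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(k.samples, axes=0), axis=0), axes=0)
    dg = _nominal_spacing(k.angles_deg, k.coverage_deg)
    return Sinogram(values=p, angles_deg=k.angles_deg,
                    coverage_deg=k.coverage_deg, delta_gamma_deg=dg)


def magnitude(s: Sinogram) -> Sinogram:
    """Element-wise modulus of a (complex) sinogram; metadata preserved."""
    return s.with_values(np.abs(s.values))


def undersample_views(s: Sinogram, keep_every: int) -> Sinogram:
    """Keep every ``keep_every``-th view (m = 0, k, 2k, ...).

    The view count must be divisible by ``keep_every`` so that the retained
    views stay uniformly spaced over the full angular coverage.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be a positive integer")
    if s.n_views % keep_every != 0:
        raise ValueError(
            f"view count {s.n_views} is not divisible by keep_every={keep_every}"
        )
    return Sinogram(
        values=s.values[:, ::keep_every],
        angles_deg=s.angles_deg[::keep_every],
        coverage_deg=s.coverage_deg,
        delta_gamma_deg=s.delta_gamma_deg * keep_every,
    )


def _nominal_spacing(angles_deg: np.ndarray, coverage_deg: float) -> float:
    """Nominal inter-view spacing; assumes (near-)uniform sampling."""
    n = len(angles_deg)
    if n >= 2:
        return float(coverage_deg) / n
    return float(coverage_deg)


def conjugate_flip(view: np.ndarray) -> np.ndarray:
    """Radial mirror of a projection about the center index ``L // 2``.

    Parallel-beam views at θ and θ+180° are mirror images in the signed
    radial coordinate.  With the centered grid ``s_n = (n - L//2)·Δs`` the
    mirror of index ``n`` is ``L - n``, so for even length the flip is a
    reversed-and-rolled copy; position ``+s_max`` has no measured partner
    and inherits the edge sample, which is zero for objects inside the
    field of view.
    """
    v = np.asarray(view)
    flipped = v[..., ::-1]
    if v.shape[-1] % 2 == 0:
        flipped = np.roll(flipped, 1, axis=-1)
    return flipped
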