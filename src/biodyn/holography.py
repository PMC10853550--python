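"""Off-axis digital holography: optics geometry and FFT reconstruction.

The instrument records holograms at the Fourier plane of the imaging
system: the object beam interferes with a tilted plane reference wave,
writing carrier fringes across the camera.  Because the recording plane
is a Fourier plane, a single 2D FFT of the hologram lands directly in
the image domain, where the two phase-conjugate sidebands appear at
plus/minus the carrier spatial frequency.  Isolating one sideband yields
the complex image-domain field of the optical section.

Conventions: forward FFT unnormalized (numpy default), origin moved to
the array center by a quadrant shift, spatial frequencies in cycles per
camera pixel, pixel indices 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsConfig",
    "FrameStack",
    "ReconstructedStack",
    "fringe_spacing",
    "carrier_offset",
    "reconstruct_frame",
    "reconstruct_stack",
    "spectral_energy_budget",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry and timing of the off-axis holographic recording.

    Defaults correspond to a superluminescent-diode instrument: 840 nm
    center wavelength, 1.5 degree beam crossing angle, 8 um camera
    pixels, 800x800 px frames at 25 fps with 3x demagnification.
    """

    wavelength_nm: float = 840.0
    crossing_deg: float = 1.5
    pixel_um: float = 8.0
    frame_rate_hz: float = 25.0
    image_px: int = 800
    demag: float = 3.0
    exposure_s: float = 0.04

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.crossing_deg <= 90:
            raise ValueError("crossing angle must be in (0, 90] degrees")
        if self.pixel_um <= 0 or self.frame_rate_hz <= 0 or self.image_px <= 0:
            raise ValueError("pixel pitch, frame rate and frame size must be positive")


@dataclass
class FrameStack:
    """Time-ordered stack of 2D camera frames with acquisition metadata.

    ``tier`` records what the frames hold: raw interference patterns
    ("hologram"), reconstructed or directly synthesized intensities
    ("intensity"), or complex object fields ("field").
    """

    frames: np.ndarray  # (T, Y, X)
    frame_rate_hz: float
    tier: str = "intensity"
    optics: OpticsConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, Y, X) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class ReconstructedStack:
    """Complex image-domain fields of one isolated sideband per frame."""

    fields: np.ndarray  # (T, Y', X') complex
    frame_rate_hz: float
    optics: OpticsConfig
    window_radius: int
    sideband: int  # +1 or -1: which carrier sign was isolated

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.fields) ** 2


def fringe_spacing(optics: OpticsConfig) -> float:
    """Carrier fringe period at the camera, Lambda = lambda / sin(theta), in um."""
    theta = math.radians(optics.crossing_deg)
    if theta <= 0:
        raise ValueError("crossing angle must be positive")
    return optics.wavelength_nm * 1e-3 / math.sin(theta)


def carrier_offset(optics: OpticsConfig) -> tuple[float, float]:
    """Carrier spatial frequency (fx, fy) in cycles/pixel along the tilt axis.

    The beam tilt is taken along the camera x axis.  Raises if the
    carrier reaches the pixel Nyquist frequency (0.5 cycles/pixel), i.e.
    fewer than two pixels per fringe.
    """
    fx = optics.pixel_um / fringe_spacing(optics)
    if fx >= 0.5:
        raise ValueError(
            f"carrier frequency {fx:.3f} cycles/pixel is at or above Nyquist; "
            "fringes are undersampled"
        )
    return (fx, 0.0)


def _carrier_px(optics: OpticsConfig, n: int) -> tuple[int, int]:
    """Carrier location in (row, col) offsets from the centered origin."""
    fx, fy = carrier_offset(optics)
    return (int(round(fy * n)), int(round(fx * n)))


def default_window_radius(optics: OpticsConfig, n: int) -> int:
    """Half the carrier offset, in pixels of the transformed frame."""
    dy, dx = _carrier_px(optics, n)
    return max(1, int(round(0.5 * math.hypot(dx, dy))))


def reconstruct_frame(
    hologram: np.ndarray,
    optics: OpticsConfig,
    window_radius: int | None = None,
    sideband: int = -1,
) -> np.ndarray:
    """Isolate one sideband of a Fourier-plane hologram by a single 2D FFT.

    Parameters
    ----------
    hologram : (N, N) real array
        Recorded interference pattern.
    optics : OpticsConfig
    window_radius : int, optional
        Radius in pixels of the circular isolation window; defaults to
        half the carrier offset.
    sideband : {+1, -1}
        Which of the two phase-conjugate sidebands to isolate.  With the
        simulator's reference-wave sign convention the ``-1`` sideband
        holds the direct (un-mirrored) image, so it is the default.

    Returns
    -------
    (2r+1, 2r+1) complex array
        Cropped sideband, zero outside the circular window, centered on
        the carrier.
    """
    h = np.asarray(hologram)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("hologram must be a square 2D frame")
    n = h.shape[0]
    if sideband not in (+1, -1):
        raise ValueError("sideband must be +1 or -1")
    dy, dx = _carrier_px(optics, n)
    r = default_window_radius(optics, n) if window_radius is None else int(window_radius)
    if r < 1:
        raise ValueError("window_radius must be >= 1")
    # zero-order region is taken with the same radius around the origin
    if math.hypot(dx, dy) < 2 * r:  # touching windows are allowed
        raise ValueError(
            "isolation window overlaps the zero-order region; "
            "reduce window_radius or increase the crossing angle"
        )
    F = np.fft.fftshift(np.fft.fft2(h))
    cy = n // 2 + sideband * dy
    cx = n // 2 + sideband * dx
    if not (r <= cy < n - r and r <= cx < n - r):
        raise ValueError("isolation window extends beyond the frame")
    crop = F[cy - r : cy + r + 1, cx - r : cx + r + 1].copy()
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    crop[yy**2 + xx**2 > r**2] = 0.0
    return crop


def reconstruct_stack(
    stack: FrameStack,
    optics: OpticsConfig | None = None,
    window_radius: int | None = None,
    sideband: int = -1,
) -> ReconstructedStack:
    """Frame-wise sideband reconstruction of a hologram stack."""
    optics = optics or stack.optics
    if optics is None:
        raise ValueError("optics configuration required")
    if stack.tier != "hologram":
        raise ValueError(f"expected a hologram-tier stack, got {stack.tier!r}")
    n = stack.frames.shape[1]
    r = default_window_radius(optics, n) if window_radius is None else int(window_radius)
    fields = np.stack(
        [reconstruct_frame(f, optics, r, sideband) for f in stack.frames]
    )
    return ReconstructedStack(
        fields=fields,
        frame_rate_hz=stack.frame_rate_hz,
        optics=optics,
        window_radius=r,
        sideband=sideband,
    )


def spectral_energy_budget(
    hologram: np.ndarray, optics: OpticsConfig, window_radius: int | None = None
) -> dict[str, float]:
    """Partition a hologram's spectral energy into named regions.

    Returns the energy (sum of |F|^2 over the centered 2D FFT) inside
    the zero-order window, each sideband window, the remainder, and the
    total.  The total equals N^2 times the pixel-domain energy
    (Parseval with an unnormalized forward FFT).
    """
    h = np.asarray(hologram, dtype=float)
    n = h.shape[0]
    dy, dx = _carrier_px(optics, n)
    r = default_window_radius(optics, n) if window_radius is None else int(window_radius)
    F2 = np.abs(np.fft.fftshift(np.fft.fft2(h))) ** 2
    yy, xx = np.mgrid[0:n, 0:n]

    def region(cy, cx):
        return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2)

    c = n // 2
    m0 = region(c, c)
    mp = region(c + dy, c + dx)
    mm = region(c - dy, c - dx)
    zero = float(F2[m0].sum())
    side_p = float(F2[mp & ~m0].sum())
    side_m = float(F2[mm & ~m0].sum())
    total = float(F2.sum())
    return {
        "zero_order": zero,
        "sideband": side_p,
        "conjugate": side_m,
        "residual": total - zero - side_p - side_m,
        "total": total,
    }
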