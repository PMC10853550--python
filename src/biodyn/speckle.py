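"""Synthesis of dynamic speckle with a prescribed intensity-fluctuation spectrum.

Fully developed speckle from living tissue is modeled as a complex
circular Gaussian random process per pixel: the recorded intensity is
``I(t) = |E(t)|**2`` of a stationary complex field ``E``.  For such a
process the intensity autocovariance is the squared magnitude of the
field autocovariance (Siegert relation), so the intensity fluctuation
spectrum is the autocorrelation of the field power spectrum.  The
measured quantity in fluctuation spectroscopy is the *intensity*
spectrum, so the field spectrum used for synthesis is obtained by a
deterministic fixed-point deconvolution: find a field spectrum whose
self-correlation matches the target intensity spectrum.

Synthesis is exact in the circular (FFT) sense: each pixel's field is
drawn as independent complex Gaussian Fourier coefficients with the
deconvolved per-bin powers, so the expected intensity periodogram
matches the target model bin by bin.
"""

from __future__ import annotations

import numpy as np

from .holography import FrameStack, OpticsConfig, carrier_offset
from .spectral import SpectralModel

__all__ = [
    "field_bin_powers",
    "synthesize_field_series",
    "synthesize_intensity_stack",
    "synthesize_field_stack",
    "simulate_hologram_stack",
]

_FIXED_POINT_ITERATIONS = 50


def _circular_autocorrelation(u: np.ndarray) -> np.ndarray:
    """(u (*) u)[k] = sum_nu u[nu] u[nu+k mod N], computed via FFT."""
    return np.fft.ifft(np.abs(np.fft.fft(u)) ** 2).real


def _target_intensity_bin_powers(
    model: SpectralModel, n_frames: int, frame_rate: float
) -> np.ndarray:
    """Two-sided per-bin intensity fluctuation powers on the circular grid."""
    N = n_frames
    df = frame_rate / N
    k = np.arange(N)
    folded = np.minimum(k, N - k).astype(float)
    f = folded * df
    s = np.empty(N)
    s[1:] = model(f[1:])
    s[0] = model.s0 + model.floor  # plateau limit at zero frequency
    # Half-weight per two-sided bin; the (single) Nyquist bin keeps the
    # same smooth weighting, so the measured one-sided density there sits
    # at S/2 -- the self-correlation spectrum of Gaussian speckle is
    # smooth and cannot carry an isolated single-bin spike.
    return s * df / 2.0


def field_bin_powers(
    model: SpectralModel,
    n_frames: int,
    frame_rate: float,
    n_iter: int = _FIXED_POINT_ITERATIONS,
) -> np.ndarray:
    """Per-bin field powers whose self-correlation matches the model.

    Solves ``(u (*) u) = q`` for the non-negative field bin powers ``u``
    by the multiplicative fixed-point iteration
    ``u <- u * sqrt(q / (u (*) u))`` (a fixed number of iterations, so
    the result is deterministic), followed by a least-squares rescale.
    """
    if n_frames % 2 != 0:
        raise ValueError("n_frames must be even")
    if n_frames < 64:
        raise ValueError("n_frames must be at least 64")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    q = _target_intensity_bin_powers(model, n_frames, frame_rate)
    # A self-correlation spectrum is positive definite (its DFT is
    # |FFT(u)|^2 >= 0).  Project the target onto its realizable part so
    # the iteration has a fixed point to converge to; for knee-shaped
    # targets the projection is a no-op to rounding error.
    qhat = np.fft.fft(q).real
    q_feasible = np.fft.ifft(np.maximum(qhat, 0.0)).real
    q_feasible = np.maximum(q_feasible, 1e-12 * q.max())
    u = q_feasible / np.sqrt(q_feasible.sum())
    for _ in range(n_iter):
        c = np.maximum(_circular_autocorrelation(u), 1e-300)
        u = u * np.sqrt(q_feasible / c)
        u *= (q_feasible.sum() / _circular_autocorrelation(u).sum()) ** 0.25
    c = _circular_autocorrelation(u)
    scale2 = float(np.dot(q, c) / np.dot(c, c))
    return u * np.sqrt(max(scale2, 0.0))


def synthesize_field_series(
    model: SpectralModel,
    n_frames: int,
    frame_rate: float,
    n_series: int,
    seed,
) -> np.ndarray:
    """Draw independent complex circular Gaussian field time series.

    Returns a complex array of shape (n_series, n_frames) whose
    intensity ``|E|**2`` has expected one-sided fluctuation spectrum
    equal to the model.
    """
    u = field_bin_powers(model, n_frames, frame_rate)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amp = n_frames * np.sqrt(u / 2.0)
    z = amp * (
        rng.standard_normal((n_series, n_frames))
        + 1j * rng.standard_normal((n_series, n_frames))
    )
    return np.fft.ifft(z, axis=1)


def synthesize_intensity_stack(
    model: SpectralModel,
    n_frames: int = 2000,
    frame_rate: float = 25.0,
    n_pixels: int = 256,
    seed: int = 0,
) -> FrameStack:
    """Synthesize an intensity-tier speckle stack with the model spectrum.

    Each pixel carries an independent realization; frames are arranged
    as a square image when ``n_pixels`` is a perfect square, else as a
    single row.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    E = synthesize_field_series(model, n_frames, frame_rate, n_pixels, seed)
    I = np.abs(E) ** 2
    side = int(round(np.sqrt(n_pixels)))
    shape = (side, side) if side * side == n_pixels else (1, n_pixels)
    frames = I.T.reshape(n_frames, *shape)
    return FrameStack(
        frames=frames,
        frame_rate_hz=frame_rate,
        tier="intensity",
        meta={"model": model, "seed": seed},
    )


def synthesize_field_stack(
    model: SpectralModel,
    n_frames: int,
    frame_rate: float,
    shape: tuple[int, int],
    seed: int = 0,
) -> np.ndarray:
    """Complex dynamic-speckle image patch, one Gaussian process per pixel.

    Returns a (T, ny, nx) complex array suitable as the image-domain
    object for hologram simulation.
    """
    ny, nx = shape
    E = synthesize_field_series(model, n_frames, frame_rate, ny * nx, seed)
    return E.T.reshape(n_frames, ny, nx)


def simulate_hologram_stack(
    object_fields: np.ndarray | FrameStack,
    optics: OpticsConfig,
    reference_amplitude: float | None = None,
    image_domain: bool = True,
) -> FrameStack:
    """Record Fourier-plane off-axis holograms of a complex object.

    Parameters
    ----------
    object_fields : (T, Y, X) complex array or field-tier FrameStack
        If ``image_domain`` (default) these are image-domain fields; the
        corresponding Fourier-plane object field at the camera is their
        centered inverse FFT, so a single forward FFT of the hologram
        returns to the image domain.  Frames smaller than the camera are
        zero-padded symmetrically (the object must stay band-limited
        within the sideband window).
    optics : OpticsConfig
        Supplies the camera size and the carrier (validated against the
        pixel Nyquist limit).
    reference_amplitude : float, optional
        Plane reference wave amplitude; defaults to sqrt(10x) the RMS
        object field so the zero order dominates, as in practice.

    Returns
    -------
    FrameStack
        Hologram-tier stack of real frames ``|R + O|**2`` carrying
        fringes at the carrier spacing.
    """
    if isinstance(object_fields, FrameStack):
        object_fields = object_fields.frames
    obj = np.asarray(object_fields, dtype=complex)
    if obj.ndim != 3:
        raise ValueError("object_fields must be (T, Y, X)")
    fx, fy = carrier_offset(optics)  # validates sampling condition
    n = optics.image_px
    T, ny, nx = obj.shape
    if ny > n or nx > n:
        raise ValueError("object frames larger than the camera frame")
    if image_domain:
        pad = np.zeros((T, n, n), dtype=complex)
        y0 = n // 2 - ny // 2  # keep the object centered on the FFT origin
        x0 = n // 2 - nx // 2
        pad[:, y0 : y0 + ny, x0 : x0 + nx] = obj
        O = np.fft.ifft2(np.fft.ifftshift(pad, axes=(1, 2)), axes=(1, 2))
    else:
        if (ny, nx) != (n, n):
            raise ValueError("Fourier-plane object fields must fill the camera frame")
        O = obj
    if reference_amplitude is None:
        rms = float(np.sqrt(np.mean(np.abs(O) ** 2)))
        reference_amplitude = np.sqrt(10.0) * rms if rms > 0 else 1.0
    # snap the carrier to the nearest FFT bin so the plane reference is
    # periodic over the frame (otherwise spectral leakage of the finite
    # aperture smears the carrier across the whole Fourier plane)
    fx_n, fy_n = round(fx * n) / n, round(fy * n) / n
    x = np.arange(n)
    ref = reference_amplitude * np.outer(
        np.exp(2j * np.pi * fy_n * x), np.exp(2j * np.pi * fx_n * x)
    )
    frames = np.abs(ref[None, :, :] + O) ** 2
    return FrameStack(
        frames=frames,
        frame_rate_hz=optics.frame_rate_hz,
        tier="hologram",
        optics=optics,
        meta={"reference_amplitude": reference_amplitude},
    )
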