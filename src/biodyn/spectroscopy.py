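"""Fluctuation spectroscopy of dynamic speckle and drug-response spectrograms.

Each well of an assay plate is revisited on a fixed loop period
(nominally 40 min); on each visit an intensity stack is recorded and
reduced to one fluctuation power spectrum.  The sequence of loop spectra
for a well, split into pre- and post-treatment epochs, is the raw
material of the drug-response spectrogram

    D(omega, t) = ln S(omega, t) - ln Sbar(omega, t0)

where ``Sbar`` is the (geometric) average of the pre-treatment spectra.
For small changes D equals the fractional change in spectral content, so
|D| ~ 0.3 reads as a ~30% spectral shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PowerSpectrum",
    "WellSpectrumSeries",
    "Spectrogram",
    "pixel_power_spectra",
    "resample_log_frequency",
    "baseline_spectrum",
    "drug_response_spectrogram",
]

LOOP_PERIOD_H = 40.0 / 60.0  # nominal well revisit period, hours


@dataclass
class PowerSpectrum:
    """One-sided fluctuation power spectrum of a well at one loop.

    freqs ascend from the spectral resolution Delta-f to the Nyquist
    frequency (frame_rate / 2); density is per Hz in arbitrary units^2.
    """

    freqs: np.ndarray
    density: np.ndarray
    n_pixels: int = 1
    loop_time: float = 0.0  # hours relative to treatment

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.freqs.shape != self.density.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and density must be matching 1D arrays")
        if np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be positive and strictly ascending")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


@dataclass
class WellSpectrumSeries:
    """Per-well sequence of loop spectra with the treatment marker.

    ``treatment_loop`` is the index of the first post-treatment loop;
    loops before it define the baseline.
    """

    well_id: str
    patient: str
    drug: str
    loops: list[PowerSpectrum] = field(default_factory=list)
    treatment_loop: int = 0

    def __post_init__(self) -> None:
        if len(self.loops) == 0:
            raise ValueError("series must contain at least one loop")
        if len(self.loops) > 24:
            raise ValueError("at most 24 loops per well")
        if not 1 <= self.treatment_loop <= len(self.loops):
            raise ValueError("need at least one pre-treatment loop")
        times = [ps.loop_time for ps in self.loops]
        if np.any(np.diff(times) <= 0):
            raise ValueError("loop times must be strictly increasing")

    @property
    def freqs(self) -> np.ndarray:
        return self.loops[0].freqs

    @property
    def loop_times(self) -> np.ndarray:
        return np.array([ps.loop_time for ps in self.loops])

    @property
    def spectra(self) -> np.ndarray:
        """Densities as a (n_freq, n_loop) matrix."""
        return np.column_stack([ps.density for ps in self.loops])


@dataclass
class Spectrogram:
    """Differential drug-response spectrogram on a (frequency x loop) grid."""

    freqs: np.ndarray  # Hz, ascending (log-spaced for display/features)
    loop_times: np.ndarray  # hours relative to treatment
    D: np.ndarray  # (n_freq, n_loop), natural-log units
    baseline: np.ndarray  # Sbar(omega, t0)
    treatment_loop: int

    @property
    def log_freqs(self) -> np.ndarray:
        return np.log10(self.freqs)

    @property
    def post_slice(self) -> slice:
        return slice(self.treatment_loop, self.D.shape[1])


def pixel_power_spectra(
    stack, frame_rate: float | None = None, combine: str = "quadrature"
) -> PowerSpectrum:
    """Reduce an intensity stack to one per-well fluctuation spectrum.

    Each pixel's mean-subtracted time series is turned into a one-sided
    periodogram (DC excluded, frequencies k * frame_rate / T for
    k = 1..T/2); pixel spectra are then combined in quadrature
    (root-sum-of-squares, the default) or by plain averaging.  Both
    choices give identical drug-response spectrograms, which depend only
    on ratios of spectra.

    Per pixel the one-sided periodogram satisfies Parseval exactly:
    sum(density) * Delta_f equals the series variance.
    """
    if isinstance(stack, np.ndarray):
        frames = stack
        if frame_rate is None:
            raise ValueError("frame_rate required with a bare array")
    else:  # FrameStack or ReconstructedStack-like
        if getattr(stack, "tier", "intensity") not in ("intensity",):
            frames = np.abs(stack.fields) ** 2 if hasattr(stack, "fields") else None
            if frames is None:
                raise ValueError("stack must be intensity-tier")
        else:
            frames = stack.frames
        frame_rate = frame_rate or stack.frame_rate_hz
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    if T < 64:
        raise ValueError("need at least 64 frames")
    if T % 2 != 0:
        raise ValueError("n_frames must be even")
    x = frames.reshape(T, -1).T  # (n_pixels, T)
    n_pixels = x.shape[0]
    df = frame_rate / T
    z = np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)
    p = np.abs(z) ** 2 / (T**2 * df)
    p[:, 1:-1] *= 2.0  # one-sided doubling, Nyquist bin excluded
    p = p[:, 1:]  # drop DC
    freqs = np.arange(1, T // 2 + 1) * df
    if combine == "quadrature":
        density = np.sqrt(np.sum(p**2, axis=0))
    elif combine == "mean":
        density = p.mean(axis=0)
    else:
        raise ValueError("combine must be 'quadrature' or 'mean'")
    return PowerSpectrum(freqs=freqs, density=density, n_pixels=n_pixels)


def resample_log_frequency(ps: PowerSpectrum, bins_per_decade: int = 20) -> PowerSpectrum:
    """Rebin a spectrum onto a logarithmic frequency axis.

    Nominal bins are geometric with ``bins_per_decade`` per decade from
    the lowest measured frequency; each output density is the mean of
    the member input bins and each center the geometric mean of its bin
    edges.  Bins that receive no input frequency (the sparse low end of
    a linear FFT grid) are dropped.
    """
    if bins_per_decade < 5:
        raise ValueError("bins_per_decade must be >= 5")
    fmin, fmax = ps.freqs[0], ps.freqs[-1]
    decades = np.log10(fmax / fmin)
    n_bins = int(np.ceil(round(decades * bins_per_decade, 9)))
    edges = fmin * 10 ** (np.arange(n_bins + 1) / bins_per_decade)
    edges[-1] = fmax * (1 + 1e-12)  # clamp the top edge to the measured band
    idx = np.clip(np.searchsorted(edges, ps.freqs, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=ps.density, minlength=n_bins)
    keep = counts > 0
    centers = np.sqrt(edges[:-1] * edges[1:])[keep]
    density = sums[keep] / counts[keep]
    return PowerSpectrum(
        freqs=centers, density=density, n_pixels=ps.n_pixels, loop_time=ps.loop_time
    )


def resample_series(series: WellSpectrumSeries, bins_per_decade: int = 20) -> WellSpectrumSeries:
    """Apply log-frequency resampling to every loop of a well series."""
    loops = [resample_log_frequency(ps, bins_per_decade) for ps in series.loops]
    return replace(series, loops=loops)


def baseline_spectrum(series: WellSpectrumSeries, eps_rel: float = 1e-12) -> np.ndarray:
    """Geometric mean of the pre-treatment loop spectra at each frequency.

    The average is taken in the log domain, consistent with the log
    differencing of the spectrogram.  Zero densities are floored at
    ``eps_rel`` times the spectrum maximum before the log.
    """
    pre = series.spectra[:, : series.treatment_loop]
    top = pre.max()
    if top <= 0:
        raise ValueError("pre-treatment spectra are identically zero")
    floored = np.maximum(pre, eps_rel * top)
    return np.exp(np.mean(np.log(floored), axis=1))


def drug_response_spectrogram(series: WellSpectrumSeries, eps_rel: float = 1e-12) -> Spectrogram:
    """Differential drug-response spectrogram D = ln S - ln Sbar.

    Natural logarithm, so small values of D read directly as fractional
    spectral change.  Pre-treatment columns are included; their mean is
    zero by construction of the geometric baseline.
    """
    sbar = baseline_spectrum(series, eps_rel)
    spectra = series.spectra
    top = spectra.max()
    floored = np.maximum(spectra, eps_rel * top)
    D = np.log(floored) - np.log(sbar)[:, None]
    return Spectrogram(
        freqs=series.freqs,
        loop_times=series.loop_times,
        D=D,
        baseline=sbar,
        treatment_loop=series.treatment_loop,
    )
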