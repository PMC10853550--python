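"""Parametric fluctuation-spectrum model for dynamic tissue speckle.

The intensity-fluctuation power spectrum of light scattered from living
tissue is well described by a knee-shaped ("Lorentzian-like") curve: a
low-frequency plateau, a knee at the characteristic Doppler frequency set
by the dominant intracellular speeds, and a power-law roll-off at high
frequency, sitting on an additive detection-noise floor::

    S(f) = s0 / (1 + (f / knee_freq)**slope) + floor

All densities are one-sided, in arbitrary units^2 per Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralModel", "eval_spectrum", "fit_spectral_model"]


@dataclass(frozen=True)
class SpectralModel:
    """Knee-shaped fluctuation power-spectrum model.

    Parameters
    ----------
    s0 : float
        Low-frequency plateau spectral density (arb. units^2/Hz), > 0.
    knee_freq : float
        Knee (half-power) frequency in Hz, > 0.
    slope : float
        High-frequency roll-off exponent, > 0.  At f >> knee_freq the
        density falls as f**-slope (before the floor takes over).
    floor : float
        Additive noise floor (arb. units^2/Hz), >= 0.
    """

    s0: float
    knee_freq: float
    slope: float = 2.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.knee_freq <= 0:
            raise ValueError("knee_freq must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.floor < 0:
            raise ValueError("floor must be non-negative")

    def __call__(self, freqs) -> np.ndarray:
        return eval_spectrum(self, freqs)


def eval_spectrum(model: SpectralModel, freqs) -> np.ndarray:
    """Evaluate the model spectral density at positive frequencies.

    Parameters
    ----------
    model : SpectralModel
    freqs : array-like of float
        Frequencies in Hz; must be strictly positive.

    Returns
    -------
    ndarray
        Spectral densities, positive and non-increasing in frequency.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    return model.s0 / (1.0 + (f / model.knee_freq) ** model.slope) + model.floor


def _grid_solutions(freqs, density, knees, slope):
    """Closed-form (s0, floor) fits for a whole knee grid at one slope.

    Solves the 2x2 normal equations per knee candidate, clipping the
    floor at zero (refit of s0 alone) and rejecting non-positive
    plateaus.  Returns arrays (s0, floor, rss) with rss = inf where the
    fit is invalid.
    """
    g = 1.0 / (1.0 + (freqs[None, :] / knees[:, None]) ** slope)  # (K, n)
    n = freqs.size
    sgg = np.einsum("kn,kn->k", g, g)
    sg = g.sum(axis=1)
    sgd = g @ density
    sd = density.sum()
    det = sgg * n - sg**2
    with np.errstate(divide="ignore", invalid="ignore"):
        s0 = (sgd * n - sg * sd) / det
        floor = (sgg * sd - sg * sgd) / det
    bad = (det <= 0) | (floor < 0) | (s0 <= 0)
    if bad.any():  # floor clipped at zero: fit the plateau alone
        s0 = np.where(bad, sgd / sgg, s0)
        floor = np.where(bad, 0.0, floor)
    rss = (
        np.einsum("n,n->", density, density)
        - 2 * s0 * sgd
        - 2 * floor * sd
        + s0**2 * sgg
        + 2 * s0 * floor * sg
        + floor**2 * n
    )
    rss = np.where(s0 > 0, rss, np.inf)
    return s0, floor, rss


def fit_spectral_model(
    freqs,
    density,
    slopes=(0.8, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0),
    n_knee: int = 60,
) -> SpectralModel:
    """Fit a knee model to a measured spectrum.

    Grid search over (knee, slope) with the plateau and floor solved in
    closed form at each grid point, followed by parabolic refinement of
    the knee on its log grid.  Deterministic, no iterative optimizer.

    Parameters
    ----------
    freqs, density : array-like
        Measured one-sided spectrum; freqs ascending and positive.
    slopes : sequence of float
        Candidate roll-off exponents.
    n_knee : int
        Number of logarithmically spaced knee candidates spanning the
        measured band.

    Returns
    -------
    SpectralModel
    """
    f = np.asarray(freqs, dtype=float)
    d = np.asarray(density, dtype=float)
    if f.ndim != 1 or f.size < 8:
        raise ValueError("need at least 8 spectral bins to fit")
    if np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise ValueError("freqs must be positive and ascending")
    if np.any(d < 0) or not np.all(np.isfinite(d)) or d.max() <= 0:
        raise ValueError("density must be finite, non-negative, not all zero")

    log_knees = np.linspace(np.log(f[0]), np.log(f[-1]), n_knee)
    knees = np.exp(log_knees)
    best = None
    for slope in slopes:
        s0, floor, rss = _grid_solutions(f, d, knees, slope)
        i = int(np.argmin(rss))
        if not np.isfinite(rss[i]):
            continue
        # parabolic refinement of log-knee on the grid
        lk = log_knees[i]
        if 0 < i < n_knee - 1 and np.isfinite(rss[i - 1]) and np.isfinite(rss[i + 1]):
            denom = rss[i - 1] - 2 * rss[i] + rss[i + 1]
            if denom > 0:
                shift = 0.5 * (rss[i - 1] - rss[i + 1]) / denom
                lk = lk + np.clip(shift, -1, 1) * (log_knees[1] - log_knees[0])
        s0r, floorr, rssr = _grid_solutions(f, d, np.array([np.exp(lk)]), slope)
        if np.isfinite(rssr[0]) and rssr[0] <= rss[i]:
            cand = (rssr[0], SpectralModel(float(s0r[0]), float(np.exp(lk)), slope, float(floorr[0])))
        else:
            cand = (rss[i], SpectralModel(float(s0[i]), float(knees[i]), slope, float(floor[i])))
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise RuntimeError("spectral model fit failed")
    return best[1]
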