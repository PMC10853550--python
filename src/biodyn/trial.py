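"""Synthetic two-cohort drug-response trials at the spectral tier.

The generator emulates the structure of a chemosensitivity assay: a
resistant and a sensitive patient cohort, several drugs plus a growth-
medium negative control, ~5 replicate wells per treatment, 40-minute
loop timing with a 4-hour pre-treatment baseline, and a planted
fraction of "unhealthy" red-shifted wells whose drug response carries
no cohort information.

Well responses are built from the four archetypal spectrogram shapes --
the lowest-order Legendre patterns in normalized log-frequency x:

* blueshift       +P1(x)   spectral weight moves to high frequency
* redshift        -P1(x)   spectral weight moves to low frequency
* mid_enhanced    -P2(x)   mid-band enhancement
* mid_suppressed  +P2(x)   mid-band suppression
* null            0        negative control

each ramped linearly in time from its onset loop.  The planted
chemosensitivity signal is the response amplitude on the informative
drugs: sensitive patients respond more strongly, with the cohort mean
separation expressed in units of the patient-to-patient amplitude
standard deviation (``effect_size``).  Shape and amplitude are
deliberately separated: well similarity (a normalized correlation) sees
only the response shape, while patient-level biomarker averages carry
the amplitude signal.  The planted "unhealthy" wells are red-shifted
with a cohort-independent random amplitude: their projection onto the
informative response direction corrupts the replicate averages without
carrying any signal, which is what phenotype censoring removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import SpectralModel
from .spectroscopy import LOOP_PERIOD_H, PowerSpectrum, WellSpectrumSeries

__all__ = [
    "ResponseArchetype",
    "TrialDesign",
    "TrialDataset",
    "archetype_profile",
    "archetype_field",
    "simulate_well",
    "simulate_trial",
    "default_log_freqs",
]

ARCHETYPE_NAMES = ("blueshift", "redshift", "mid_enhanced", "mid_suppressed", "null")

# phenotype numbering used throughout: 1 blue, 2 red, 3 mid-enhanced, 4 mid-suppressed
ARCHETYPE_PHENOTYPE = {
    "blueshift": 1,
    "redshift": 2,
    "mid_enhanced": 3,
    "mid_suppressed": 4,
}

# blue-shifted responses form the majority phenotype; mid-frequency
# enhancement is the minority; the mid-suppressed drug carries no cohort
# signal, so censoring phenotype 4 removes nothing informative
DRUG_ARCHETYPES = {
    "cisplatin": "blueshift",
    "fluorouracil": "blueshift",
    "carboplatin": "mid_enhanced",
    "paclitaxel": "mid_suppressed",
    "medium": "null",
}

INFORMATIVE_DRUGS = ("cisplatin", "fluorouracil")

# study-condition constants of the generator (log-units unless noted)
BASE_AMPLITUDE = 0.3  # mean archetype peak |D|, ~30% spectral change
PATIENT_AMP_SD = 0.05  # patient-to-patient amplitude spread
WELL_AMP_SD = 0.02  # replicate-to-replicate amplitude jitter
NOISE_WELL_AMP_MEAN = 0.35  # red-shifted noise wells: amplitude distribution
NOISE_WELL_AMP_SD = 0.15

BASE_MODEL = SpectralModel(s0=1.0, knee_freq=0.4, slope=1.7, floor=1e-3)
PATIENT_S0_LOGSD = 0.3
PATIENT_KNEE_LOGSD = 0.2


def default_log_freqs(
    fmin: float = 12.5e-3, fmax: float = 12.5, bins_per_decade: int = 20
) -> np.ndarray:
    """Default logarithmic frequency grid, 12.5 mHz to 12.5 Hz."""
    n = int(np.ceil(round(np.log10(fmax / fmin) * bins_per_decade, 9)))
    return fmin * 10 ** (np.arange(n + 1) / bins_per_decade)


@dataclass(frozen=True)
class ResponseArchetype:
    """One of the archetypal drug-response spectrogram shapes."""

    name: str
    amplitude: float = BASE_AMPLITUDE  # peak |D|, natural-log units
    onset_loop: int = 0  # post-treatment loop at which the response begins

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPE_NAMES:
            raise ValueError(f"unknown archetype {self.name!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.onset_loop < 0:
            raise ValueError("onset_loop must be non-negative")


def archetype_profile(name: str, x) -> np.ndarray:
    """Frequency profile of an archetype on normalized log-frequency x in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    if name == "blueshift":
        return x
    if name == "redshift":
        return -x
    if name == "mid_enhanced":
        return -(3.0 * x**2 - 1.0) / 2.0
    if name == "mid_suppressed":
        return (3.0 * x**2 - 1.0) / 2.0
    if name == "null":
        return np.zeros_like(x)
    raise ValueError(f"unknown archetype {name!r}")


def _time_ramp(n_post: int, onset: int) -> np.ndarray:
    """Linear ramp from 0 at the onset loop to 1 at the final loop."""
    r = np.zeros(n_post)
    if onset >= n_post:
        return r
    span = max(n_post - 1 - onset, 1)
    idx = np.arange(n_post)
    r = np.clip((idx - onset) / span, 0.0, 1.0)
    if n_post == 1:
        r[:] = 1.0
    return r


def archetype_field(
    archetype: ResponseArchetype, x: np.ndarray, n_post: int, broad: float = 0.0
) -> np.ndarray:
    """Planted D_true(x, t) over the post-treatment loops, (n_freq, n_post)."""
    ramp = _time_ramp(n_post, archetype.onset_loop)
    profile = archetype.amplitude * archetype_profile(archetype.name, x)
    return np.outer(profile, ramp) + broad * ramp[None, :]


def _normalized_log_freq(freqs: np.ndarray) -> np.ndarray:
    lf = np.log10(freqs)
    lo, hi = lf[0], lf[-1]
    return 2.0 * (lf - lo) / (hi - lo) - 1.0


def simulate_well(
    archetype: ResponseArchetype,
    base: SpectralModel,
    loops_pre: int = 6,
    loops_post: int = 18,
    noise_sd: float = 0.05,
    seed=0,
    freqs: np.ndarray | None = None,
    broad: float = 0.0,
    well_id: str = "well",
    patient: str = "pt",
    drug: str = "drug",
) -> WellSpectrumSeries:
    """Simulate one well's sequence of loop spectra.

    Loop spectra are ``S(omega, t) = Sbar(omega) * exp(D_true + eps)``
    with i.i.d. normal log-domain noise ``eps`` of standard deviation
    ``noise_sd`` per (frequency, loop) bin.  Pre-treatment loops carry
    no planted response (D_true = 0).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if loops_pre < 1 or loops_post < 0:
        raise ValueError("need at least one pre-treatment loop")
    if loops_pre + loops_post > 24:
        raise ValueError("at most 24 loops per well")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = default_log_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    x = _normalized_log_freq(f)
    n_loops = loops_pre + loops_post
    sbar = base(f)
    D_true = np.zeros((f.size, n_loops))
    if loops_post > 0:
        D_true[:, loops_pre:] = archetype_field(archetype, x, loops_post, broad)
    eps = rng.normal(0.0, noise_sd, size=D_true.shape) if noise_sd > 0 else 0.0
    spectra = sbar[:, None] * np.exp(D_true + eps)
    times = (np.arange(n_loops) - loops_pre) * LOOP_PERIOD_H
    loops = [
        PowerSpectrum(freqs=f, density=spectra[:, i], loop_time=times[i])
        for i in range(n_loops)
    ]
    return WellSpectrumSeries(
        well_id=well_id,
        patient=patient,
        drug=drug,
        loops=loops,
        treatment_loop=loops_pre,
    )


@dataclass(frozen=True)
class TrialDesign:
    """Design of a synthetic two-cohort trial.

    ``effect_size`` is the cohort separation of the broad drug-response
    coefficient on the informative drugs, in units of the patient-level
    standard deviation.  ``redshift_noise_fraction`` is the fraction of
    treated wells replaced by uninformative red-shifted ("unhealthy")
    wells whose amplitude is independent of cohort.
    """

    n_resistant: int = 14
    n_sensitive: int = 14
    drugs: tuple[str, ...] = ("cisplatin", "fluorouracil", "carboplatin", "paclitaxel", "medium")
    wells_per_drug: int = 5
    n_control_wells: int = 6
    redshift_noise_fraction: float = 0.2
    effect_size: float = 2.0
    loops_pre: int = 6
    loops_post: int = 18
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resistant < 1 or self.n_sensitive < 1:
            raise ValueError("both cohorts must be non-empty")
        if self.wells_per_drug < 1 or self.n_control_wells < 1:
            raise ValueError("well counts must be >= 1")
        if not 0 <= self.redshift_noise_fraction < 1:
            raise ValueError("redshift_noise_fraction must be in [0, 1)")
        if self.loops_pre < 1 or self.loops_pre + self.loops_post > 24:
            raise ValueError("loops_pre >= 1 and loops_pre + loops_post <= 24")
        if len(self.drugs) < 1:
            raise ValueError("at least one treatment required")


@dataclass
class TrialDataset:
    """Simulated trial: well spectra, outcomes, and hidden ground truth.

    ``truth`` (planted archetype and health per well) is retained for
    validation only; no pipeline stage reads it.
    """

    wells: list[WellSpectrumSeries]
    outcomes: pd.Series  # patient -> "resistant" | "sensitive"
    truth: pd.DataFrame  # well_id, patient, drug, archetype, phenotype, healthy
    design: TrialDesign | None = None

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    def well(self, well_id: str) -> WellSpectrumSeries:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)


def simulate_trial(design: TrialDesign) -> TrialDataset:
    """Generate a full two-cohort trial of well spectrum series.

    Reproducible: identical designs (including seed) give identical
    datasets.
    """
    rng = np.random.default_rng(design.seed)
    n_pat = design.n_resistant + design.n_sensitive
    patients = [f"pt{i + 1:02d}" for i in range(n_pat)]
    cohorts = ["resistant"] * design.n_resistant + ["sensitive"] * design.n_sensitive
    freqs = default_log_freqs()
    wells: list[WellSpectrumSeries] = []
    truth_rows = []
    for patient, cohort in zip(patients, cohorts):
        base = SpectralModel(
            s0=BASE_MODEL.s0 * float(np.exp(rng.normal(0, PATIENT_S0_LOGSD))),
            knee_freq=BASE_MODEL.knee_freq * float(np.exp(rng.normal(0, PATIENT_KNEE_LOGSD))),
            slope=BASE_MODEL.slope,
            floor=BASE_MODEL.floor * BASE_MODEL.s0,
        )
        for drug in design.drugs:
            n_wells = design.n_control_wells if drug == "medium" else design.wells_per_drug
            arch_name = DRUG_ARCHETYPES.get(drug, "blueshift")
            shift = (
                design.effect_size * PATIENT_AMP_SD
                if (cohort == "sensitive" and drug in INFORMATIVE_DRUGS)
                else 0.0
            )
            a_pd = max(0.05, rng.normal(BASE_AMPLITUDE + shift, PATIENT_AMP_SD))
            for k in range(n_wells):
                well_id = f"{patient}_{drug}_{k}"
                is_noise = drug != "medium" and rng.random() < design.redshift_noise_fraction
                if is_noise:
                    arch = ResponseArchetype(
                        "redshift",
                        amplitude=max(0.05, rng.normal(NOISE_WELL_AMP_MEAN, NOISE_WELL_AMP_SD)),
                    )
                    broad = 0.0
                    healthy = False
                elif drug == "medium":
                    arch = ResponseArchetype("null", amplitude=0.0)
                    broad = 0.0
                    healthy = True
                else:
                    arch = ResponseArchetype(
                        arch_name, amplitude=max(0.0, a_pd + rng.normal(0, WELL_AMP_SD))
                    )
                    broad = 0.0
                    healthy = True
                wells.append(
                    simulate_well(
                        arch,
                        base,
                        loops_pre=design.loops_pre,
                        loops_post=design.loops_post,
                        noise_sd=design.noise_sd,
                        seed=rng,
                        freqs=freqs,
                        broad=broad,
                        well_id=well_id,
                        patient=patient,
                        drug=drug,
                    )
                )
                truth_rows.append(
                    {
                        "well_id": well_id,
                        "patient": patient,
                        "drug": drug,
                        "archetype": arch.name,
                        "phenotype": ARCHETYPE_PHENOTYPE.get(arch.name, 0),
                        "healthy": healthy,
                    }
                )
    outcomes = pd.Series(cohorts, index=pd.Index(patients, name="patient"), name="cohort")
    truth = pd.DataFrame(truth_rows).set_index("well_id")
    return TrialDataset(wells=wells, outcomes=outcomes, truth=truth, design=design)
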