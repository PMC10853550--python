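"""HDF5/CSV/YAML persistence for stacks, trials, spectrograms and tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .holography import FrameStack, OpticsConfig
from .spectroscopy import PowerSpectrum, Spectrogram, WellSpectrumSeries
from .trial import TrialDataset

__all__ = [
    "save_frame_stack",
    "load_frame_stack",
    "save_trial",
    "load_trial",
    "save_spectrograms",
    "load_spectrograms",
    "load_config",
]

_OPTICS_ATTRS = [
    "wavelength_nm",
    "crossing_deg",
    "pixel_um",
    "frame_rate_hz",
    "image_px",
    "demag",
    "exposure_s",
]


def save_frame_stack(stack: FrameStack, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames, compression="gzip", compression_opts=1)
        f.attrs["frame_rate_hz"] = stack.frame_rate_hz
        f.attrs["tier"] = stack.tier
        if stack.optics is not None:
            for k in _OPTICS_ATTRS:
                f.attrs[f"optics_{k}"] = getattr(stack.optics, k)
    return path


def load_frame_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        frames = f["frames"][...]
        optics = None
        if "optics_wavelength_nm" in f.attrs:
            kw = {k: f.attrs[f"optics_{k}"] for k in _OPTICS_ATTRS}
            kw["image_px"] = int(kw["image_px"])
            optics = OpticsConfig(**kw)
        return FrameStack(
            frames=frames,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            tier=str(f.attrs.get("tier", "intensity")),
            optics=optics,
        )


def save_trial(dataset: TrialDataset, path) -> Path:
    """Write a trial to HDF5 plus CSV manifest and outcome tables.

    ``<stem>.h5`` holds per-well spectra; ``<stem>.manifest.csv`` the
    well layout and ``<stem>.outcomes.csv`` the patient cohorts.
    Planted ground truth is stored under /truth for validation use.
    """
    path = Path(path)
    stem = path.with_suffix("")
    with h5py.File(path, "w") as f:
        g = f.create_group("wells")
        for w in dataset.wells:
            gw = g.create_group(w.well_id)
            gw.create_dataset("freqs", data=w.freqs)
            gw.create_dataset("spectra", data=w.spectra)
            gw.create_dataset("loop_times", data=w.loop_times)
            gw.attrs["patient"] = w.patient
            gw.attrs["drug"] = w.drug
            gw.attrs["treatment_loop"] = w.treatment_loop
        t = f.create_group("truth")
        for col in dataset.truth.columns:
            vals = dataset.truth[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                vals = np.array([str(v) for v in vals], dtype=h5py.string_dtype())
            t.create_dataset(col, data=vals)
        t.create_dataset(
            "well_id",
            data=np.array(list(dataset.truth.index), dtype=h5py.string_dtype()),
        )
    manifest = pd.DataFrame(
        {
            "well_id": [w.well_id for w in dataset.wells],
            "patient": [w.patient for w in dataset.wells],
            "drug": [w.drug for w in dataset.wells],
            "n_loops": [len(w.loops) for w in dataset.wells],
            "treatment_loop": [w.treatment_loop for w in dataset.wells],
        }
    )
    manifest.to_csv(stem.with_suffix(".manifest.csv"), index=False)
    dataset.outcomes.rename("cohort").to_csv(stem.with_suffix(".outcomes.csv"))
    return path


def load_trial(path) -> TrialDataset:
    path = Path(path)
    stem = path.with_suffix("")
    wells = []
    with h5py.File(path, "r") as f:
        for wid, gw in f["wells"].items():
            freqs = gw["freqs"][...]
            spectra = gw["spectra"][...]
            times = gw["loop_times"][...]
            loops = [
                PowerSpectrum(freqs=freqs, density=spectra[:, i], loop_time=float(times[i]))
                for i in range(spectra.shape[1])
            ]
            wells.append(
                WellSpectrumSeries(
                    well_id=wid,
                    patient=str(gw.attrs["patient"]),
                    drug=str(gw.attrs["drug"]),
                    loops=loops,
                    treatment_loop=int(gw.attrs["treatment_loop"]),
                )
            )
        truth = pd.DataFrame(
            {
                col: [
                    v.decode() if isinstance(v, bytes) else v
                    for v in f["truth"][col][...]
                ]
                for col in f["truth"]
                if col != "well_id"
            },
            index=pd.Index(
                [v.decode() for v in f["truth"]["well_id"][...]], name="well_id"
            ),
        )
    truth["healthy"] = truth["healthy"].astype(bool) if "healthy" in truth else True
    if "phenotype" in truth:
        truth["phenotype"] = truth["phenotype"].astype(int)
    outcomes = pd.read_csv(stem.with_suffix(".outcomes.csv"), index_col=0)["cohort"]
    order = {w.well_id: i for i, w in enumerate(wells)}
    truth = truth.loc[sorted(truth.index, key=lambda k: order.get(k, len(order)))]
    return TrialDataset(wells=wells, outcomes=outcomes, truth=truth)


def save_spectrograms(spectrograms: dict[str, Spectrogram], path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("wells")
        for wid, sg in spectrograms.items():
            gw = g.create_group(wid)
            gw.create_dataset("D", data=sg.D)
            gw.create_dataset("freqs", data=sg.freqs)
            gw.create_dataset("loop_times", data=sg.loop_times)
            gw.create_dataset("baseline", data=sg.baseline)
            gw.attrs["treatment_loop"] = sg.treatment_loop
    return path


def load_spectrograms(path) -> dict[str, Spectrogram]:
    out = {}
    with h5py.File(path, "r") as f:
        for wid, gw in f["wells"].items():
            out[wid] = Spectrogram(
                freqs=gw["freqs"][...],
                loop_times=gw["loop_times"][...],
                D=gw["D"][...],
                baseline=gw["baseline"][...],
                treatment_loop=int(gw.attrs["treatment_loop"]),
            )
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg
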