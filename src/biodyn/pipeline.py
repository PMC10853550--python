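"""End-to-end pipeline orchestration: simulate -> spectrograms -> features
-> biomarkers -> phenotypes -> censoring-compared prediction -> report.

A run is driven by a single configuration mapping (YAML on disk) with
one section per stage.  Every stage's random seed is derived
deterministically from the global seed and the stage name, stage
outputs are written with checksums into the run directory, and the run
manifest echoes the configuration verbatim so a run can be reproduced
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemosensitivity as chemo
from . import features as feat
from . import io as bio_io
from . import phenotyping as pheno
from .spectroscopy import drug_response_spectrogram
from .trial import TrialDesign, simulate_trial

__all__ = ["default_config", "validate_config", "stage_seed", "run_pipeline", "render_report"]

_STAGES = ("trial", "spectrogram", "features", "phenotype", "predict")

_DESIGN_FIELDS = {f.name for f in dataclasses.fields(TrialDesign)}


def default_config() -> dict:
    return {
        "seed": 0,
        "outdir": "biodyn_run",
        "trial": {},  # TrialDesign overrides
        "phenotype": {"k": 4},
        "predict": {"n_runs": 60, "top_n": 10, "permanent_holdouts": [], "compare_censoring": True},
    }


def validate_config(config: dict) -> dict:
    """Schema-check a run configuration, filling defaults."""
    cfg = default_config()
    known = set(cfg)
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key, val in config.items():
        if isinstance(cfg.get(key), dict):
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            bad = set(val) - set(cfg[key]) if key != "trial" else set(val) - _DESIGN_FIELDS
            if bad:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(bad)}")
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    TrialDesign(**{**cfg["trial"], "seed": 0})  # validates trial section
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed folded with a stage hash."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Outputs per stage: trial HDF5 + CSVs, spectrogram HDF5, feature and
    biomarker CSVs, phenotype assignment CSV, censoring-compared ROC
    tables and a JSON prediction summary.
    """
    if not isinstance(config, dict):
        config = bio_io.load_config(config)
    cfg = validate_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": {}, "outputs": {}}

    def record(stage: str, t0: float, files: list[Path]):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for p in files:
            manifest["outputs"][p.name] = _sha256(p)

    # --- trial -----------------------------------------------------------
    t0 = time.time()
    design = TrialDesign(**{**cfg["trial"], "seed": stage_seed(cfg["seed"], "trial")})
    dataset = simulate_trial(design)
    trial_h5 = out / "trial.h5"
    bio_io.save_trial(dataset, trial_h5)
    record("trial", t0, [trial_h5, out / "trial.manifest.csv", out / "trial.outcomes.csv"])

    # --- spectrograms ----------------------------------------------------
    t0 = time.time()
    spectrograms = {w.well_id: drug_response_spectrogram(w) for w in dataset.wells}
    sg_h5 = out / "spectrograms.h5"
    bio_io.save_spectrograms(spectrograms, sg_h5)
    record("spectrogram", t0, [sg_h5])

    # --- features + biomarkers ------------------------------------------
    t0 = time.time()
    meta, features = feat.extract_feature_table(dataset.wells)
    zstats = feat.fit_zscores(features)
    biomarkers = feat.pool_features(features, zstats=zstats)
    feat_csv = out / "features.csv"
    bm_csv = out / "biomarkers.csv"
    meta.join(features).to_csv(feat_csv)
    meta.join(biomarkers).to_csv(bm_csv)
    record("features", t0, [feat_csv, bm_csv])

    # --- phenotyping -----------------------------------------------------
    t0 = time.time()
    # negative-control (medium) wells have no drug response to classify;
    # they stay unlabeled and are never censored
    treated = meta.index[meta["drug"] != "medium"]
    sim = pheno.similarity_matrix(biomarkers.loc[treated, feat.RESPONSE_BIOMARKERS])
    linkage = pheno.cluster_wells(sim)
    clusters = pheno.prune_to_phenotypes(linkage, k=cfg["phenotype"]["k"], well_ids=sim.well_ids)
    assignment = pheno.assign_archetypes(clusters, spectrograms, linkage)
    ph_csv = out / "phenotypes.csv"
    pd.DataFrame(
        {"cluster": assignment.clusters, "phenotype": assignment.labels}
    ).rename_axis("well_id").to_csv(ph_csv)
    sim_csv = out / "similarity.csv"
    pd.DataFrame(sim.sim, index=sim.well_ids, columns=sim.well_ids).to_csv(sim_csv)
    record("phenotype", t0, [ph_csv, sim_csv])

    # --- prediction with censoring comparison ---------------------------
    t0 = time.time()
    pcfg = cfg["predict"]
    seed = stage_seed(cfg["seed"], "predict")
    results = chemo.censoring_experiment(
        meta,
        biomarkers,
        dataset.outcomes,
        assignment,
        permanent_holdouts=tuple(pcfg["permanent_holdouts"]),
        n_runs=pcfg["n_runs"],
        top_n=pcfg["top_n"],
        seed=seed,
    )
    if not pcfg["compare_censoring"]:
        results = {"full": results["full"]}
    files = []
    summary = {}
    for name, res in results.items():
        roc_csv = out / f"roc_{name}.csv"
        res["roc"].to_csv(roc_csv, index=False)
        files.append(roc_csv)
        prev = chemo.biomarker_prevalence(res["cv"])
        prev_csv = out / f"prevalence_{name}.csv"
        prev["by_feature"].rename("prevalence").to_csv(prev_csv)
        files.append(prev_csv)
        summary[name] = {
            "auc": res["auc"],
            "scores": res["cv"].scores.round(6).to_dict(),
        }
    # patient matrix of selected biomarkers (trial-level WB selection)
    table = chemo.aggregate_patient_biomarkers(
        meta, biomarkers, dataset.outcomes,
        permanent_holdouts=tuple(pcfg["permanent_holdouts"]),
    )
    train = [p for p in dataset.outcomes.index if p not in pcfg["permanent_holdouts"]]
    Xa = pd.concat(
        [table.X, chemo.bilinear_columns(table.X, table.precond, train)], axis=1
    )
    sel = chemo.select_biomarkers(
        Xa.loc[train], (dataset.outcomes.loc[train] == "sensitive").astype(int),
        top_n=pcfg["top_n"],
    )
    pt_csv = out / "patient_biomarkers.csv"
    Xa[sel.columns].to_csv(pt_csv)
    files.append(pt_csv)
    summary_json = out / "prediction.json"
    summary_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(summary_json)
    record("predict", t0, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_report(run_dir: str | Path) -> list[Path]:
    """Render summary figures from a completed run directory.

    Produces the clustered similarity heatmap, the four phenotype mean
    spectrograms, the censoring-compared ROC curves, the biomarker
    prevalence bars and the patient similarity matrix.  Deterministic:
    re-rendering the same run directory writes identical figures.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    if not (run / "manifest.json").exists():
        raise FileNotFoundError(f"{run} is not a completed run directory")
    figures = []

    phen = pd.read_csv(run / "phenotypes.csv", index_col=0)
    sim = pd.read_csv(run / "similarity.csv", index_col=0)
    order = phen.sort_values(["phenotype", "cluster"]).index
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim.loc[order, order].to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title("Well similarity (clustered by phenotype)")
    fig.colorbar(im, ax=ax, label="correlation")
    p = run / "report_similarity.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)

    sgs = bio_io.load_spectrograms(run / "spectrograms.h5")
    fig, axes = plt.subplots(1, 4, figsize=(14, 3), sharey=True)
    for ph, ax in zip((1, 2, 3, 4), axes):
        ids = phen.index[phen["phenotype"] == ph]
        ax.set_title(f"phenotype {ph} (n={len(ids)})")
        if len(ids) == 0:
            continue
        D = np.mean([sgs[w].D for w in ids], axis=0)
        sg0 = sgs[ids[0]]
        ax.pcolormesh(sg0.loop_times, sg0.log_freqs, D, cmap="RdBu_r", vmin=-0.4, vmax=0.4)
        ax.set_xlabel("time (h)")
    axes[0].set_ylabel("log10 f (Hz)")
    p = run / "report_phenotype_spectrograms.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)

    summary = json.loads((run / "prediction.json").read_text())
    fig, ax = plt.subplots(figsize=(5, 5))
    for name in summary:
        roc = pd.read_csv(run / f"roc_{name}.csv")
        ax.plot(roc["fpr"], roc["tpr"], label=f"{name} (AUC={summary[name]['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    ax.set_title("Chemosensitivity prediction")
    p = run / "report_roc.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)

    fig, axes = plt.subplots(1, len(summary), figsize=(4 * len(summary), 3.2), squeeze=False)
    for ax, name in zip(axes[0], summary):
        prev = pd.read_csv(run / f"prevalence_{name}.csv", index_col=0)["prevalence"]
        prev.head(10).plot.bar(ax=ax)
        ax.set_title(f"persistent features: {name}")
        ax.set_ylabel("prevalence")
    fig.tight_layout()
    p = run / "report_prevalence.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)

    pt = pd.read_csv(run / "patient_biomarkers.csv", index_col=0)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.imshow(np.corrcoef(pt.to_numpy()), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title("Patient similarity (selected biomarkers)")
    ax.set_xlabel("patient")
    ax.set_ylabel("patient")
    p = run / "report_patient_similarity.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    figures.append(p)
    return figures
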