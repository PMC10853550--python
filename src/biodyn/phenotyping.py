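"""Spectral-phenotype clustering and censoring of wells.

Wells are compared by the normalized correlation of their 12-element
biomarker vectors; the similarity matrix is clustered by unsupervised
agglomerative (average-linkage) hierarchical clustering on the distance
1 - correlation, pruned to approximately four groups, and each group is
assigned to one of the four archetypal spectral phenotypes by
correlating its mean post-treatment frequency profile with the
lowest-order Legendre templates:

    phenotype 1  blue-shifted          +P1(x)
    phenotype 2  red-shifted           -P1(x)
    phenotype 3  mid-frequency enhanced -P2(x)
    phenotype 4  mid-frequency suppressed +P2(x)

Censoring removes all wells of selected phenotypes (typically the
red-shifted, metabolically declining samples) before patient-level
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .spectroscopy import Spectrogram
from .trial import archetype_profile

__all__ = [
    "SimilarityMatrix",
    "PhenotypeAssignment",
    "similarity_matrix",
    "cluster_wells",
    "prune_to_phenotypes",
    "gap_rule_k",
    "assign_archetypes",
    "phenotype_wells",
    "censor_wells",
]

PHENOTYPE_TEMPLATES = {
    1: "blueshift",
    2: "redshift",
    3: "mid_enhanced",
    4: "mid_suppressed",
}


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of normalized correlations between well vectors."""

    well_ids: list[str]
    sim: np.ndarray
    flagged: list[str] = field(default_factory=list)  # zero-variance wells

    def __post_init__(self) -> None:
        s = np.asarray(self.sim, dtype=float)
        if s.shape != (len(self.well_ids), len(self.well_ids)):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        self.sim = s


@dataclass
class PhenotypeAssignment:
    """Well -> phenotype labels with the cluster-to-archetype evidence."""

    labels: pd.Series  # well_id -> phenotype in {1..4} (0 = unassigned)
    clusters: pd.Series  # well_id -> cluster id
    cluster_scores: pd.DataFrame  # cluster x phenotype template correlations
    linkage: np.ndarray
    flagged: list[str] = field(default_factory=list)


def similarity_matrix(vectors: pd.DataFrame) -> SimilarityMatrix:
    """Pearson correlation between the biomarker vectors of all well pairs.

    Zero-variance vectors get zero correlation to every other well
    (diagonal stays 1) and are flagged.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two wells")
    X = vectors.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("biomarker vectors must be finite")
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(X)
    sim[degenerate, :] = 0.0
    sim[:, degenerate] = 0.0
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(
        well_ids=list(vectors.index),
        sim=sim,
        flagged=list(vectors.index[degenerate]),
    )


def cluster_wells(sim: SimilarityMatrix) -> np.ndarray:
    """Average-linkage agglomerative clustering on distance 1 - similarity.

    Returns the scipy linkage matrix (merge list with heights).
    """
    d = 1.0 - sim.sim
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method="average")


def gap_rule_k(linkage: np.ndarray, k_max: int = 8) -> int:
    """Number of clusters suggested by the largest merge-height gap."""
    heights = linkage[:, 2]
    n = len(heights) + 1
    if n < 3:
        return n
    # a cut in the gap between heights[i] and heights[i+1] yields n-i-1 clusters
    gaps = np.diff(heights)
    lo = max(0, n - 1 - k_max)
    i = lo + int(np.argmax(gaps[lo:]))
    return int(n - i - 1)


def prune_to_phenotypes(linkage: np.ndarray, k: int = 4, well_ids=None) -> pd.Series:
    """Cut the dendrogram into exactly k clusters.

    Cluster ids are renumbered 1..k in order of first appearance so the
    labeling is independent of input ordering conventions.
    """
    n = linkage.shape[0] + 1
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k cannot exceed the number of wells")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    order = pd.unique(raw)
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap[c] for c in raw])
    index = well_ids if well_ids is not None else range(n)
    return pd.Series(labels, index=index, name="cluster")


def assign_archetypes(
    clusters: pd.Series,
    spectrograms: dict[str, Spectrogram],
    linkage: np.ndarray | None = None,
) -> PhenotypeAssignment:
    """Map each cluster to its best-matching archetypal phenotype.

    The cluster's wells' spectrograms are averaged over post-treatment
    time into a frequency profile and correlated with the four canonical
    templates; ties break toward the lower phenotype number.  A cluster
    with a (near-)zero profile is left unassigned (label 0) and flagged.
    Two clusters may map to the same archetype; that is permitted and
    visible in the score table.
    """
    rows = {}
    labels = {}
    flagged = []
    for c in sorted(clusters.unique()):
        ids = clusters.index[clusters == c]
        profiles = []
        for wid in ids:
            sg = spectrograms[wid]
            x = _norm_unit(sg.log_freqs)
            profiles.append((x, sg.D[:, sg.post_slice].mean(axis=1)))
        x = profiles[0][0]
        prof = np.mean([p for _, p in profiles], axis=0)
        scores = {}
        for ph, name in PHENOTYPE_TEMPLATES.items():
            t = archetype_profile(name, x)
            denom = np.linalg.norm(prof) * np.linalg.norm(t)
            scores[ph] = float(np.dot(prof, t) / denom) if denom > 0 else 0.0
        rows[c] = scores
        if np.linalg.norm(prof) < 1e-12 or max(scores.values()) <= 0:
            best = 0
            flagged.extend(ids)
        else:
            best = min(ph for ph, s in scores.items() if s == max(scores.values()))
        for wid in ids:
            labels[wid] = best
    label_s = pd.Series({wid: labels[wid] for wid in clusters.index}, name="phenotype")
    score_df = pd.DataFrame(rows).T
    score_df.index.name = "cluster"
    return PhenotypeAssignment(
        labels=label_s,
        clusters=clusters,
        cluster_scores=score_df,
        linkage=linkage if linkage is not None else np.empty((0, 4)),
        flagged=flagged,
    )


def _norm_unit(v: np.ndarray) -> np.ndarray:
    lo, hi = v[0], v[-1]
    return 2.0 * (v - lo) / (hi - lo) - 1.0


def phenotype_wells(
    biomarkers: pd.DataFrame,
    spectrograms: dict[str, Spectrogram],
    k: int = 4,
    response_only: bool = True,
) -> PhenotypeAssignment:
    """Similarity -> clustering -> pruning -> archetype labels in one call.

    By default the correlation is taken over the drug-response
    biomarkers of the vector: the static sample preconditions are
    shared by all wells of a patient, so including them clusters wells
    by patient identity rather than by response shape.  Pass
    ``response_only=False`` to correlate the full 12-element vectors.
    """
    from .features import RESPONSE_BIOMARKERS

    vectors = biomarkers
    if response_only:
        cols = [c for c in RESPONSE_BIOMARKERS if c in biomarkers.columns]
        vectors = biomarkers[cols]
    sim = similarity_matrix(vectors)
    linkage = cluster_wells(sim)
    clusters = prune_to_phenotypes(linkage, k=k, well_ids=sim.well_ids)
    return assign_archetypes(clusters, spectrograms, linkage)


def censor_wells(
    well_meta: pd.DataFrame,
    assignment: PhenotypeAssignment,
    remove: set[int],
) -> pd.DataFrame:
    """Drop wells whose phenotype label is in ``remove``.

    Returns the surviving rows of ``well_meta`` (indexed by well id,
    with patient and drug columns).  Patients losing every well of some
    drug are reported in the ``dropped_cells`` attribute of the result.
    """
    if not set(remove) <= {0, 1, 2, 3, 4}:
        raise ValueError("phenotype labels must be in {0..4}")
    labels = assignment.labels.reindex(well_meta.index)
    keep = ~labels.isin(list(remove))
    survivors = well_meta.loc[keep].copy()
    if survivors.empty:
        raise ValueError("censoring removed every well")
    before = well_meta.groupby(["patient", "drug"]).size()
    after = survivors.groupby(["patient", "drug"]).size()
    lost = before.index.difference(after.index)
    survivors.attrs["dropped_cells"] = [tuple(ix) for ix in lost]
    return survivors
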