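"""Patient-level chemosensitivity prediction from well biomarkers.

Well biomarker vectors are averaged into a patients x (drug, biomarker)
trial matrix (after optional phenotype censoring), augmented with
bilinear biomarkers -- mean-subtracted products of drug-response
biomarkers with the preconditions NSD, DR and HW that capture
precondition-dependent response biases.  Inside every pass of a
double-holdout cross-validation (one resistant and one sensitive
patient removed at random, repeated 60 times), the most discriminating
columns are selected by their WB ratio -- the between-cohort standard
deviation over the pooled within-cohort standard deviation, ranked in
decreasing order so the highest WB is the most discriminating -- and a
minimal shallow feed-forward neural network (two hidden layers of 8
tanh units, sigmoid output) is trained on the remaining patients and
scored on the held-out pair.  Collated held-out scores yield the ROC
curve and its AUC; tabulating the per-pass selections yields the
persistent-biomarker prevalence tables.

All fold-level statistics (bilinear centering means, WB ranking,
feature standardization) are computed on the training patients only, so
biomarker selection is provably independent of the held-out pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import RESPONSE_BIOMARKERS
from .phenotyping import PhenotypeAssignment, censor_wells

__all__ = [
    "TrialTable",
    "SelectedBiomarkers",
    "CVResult",
    "aggregate_patient_biomarkers",
    "bilinear_biomarkers",
    "wb_ratio",
    "select_biomarkers",
    "train_classifier",
    "double_holdout_cv",
    "roc_auc",
    "biomarker_prevalence",
    "censoring_experiment",
]

PRECONDITION_COLUMNS = ["NSD", "DR", "HW"]
WB_CAP = 100.0


@dataclass
class TrialTable:
    """Patients x (drug, biomarker) matrix with cohort labels.

    ``X`` holds the linear biomarker columns named ``"<drug>:<biomarker>"``;
    ``precond`` the patient-level preconditions used to build bilinear
    columns; ``permanent_holdouts`` lists patients excluded from all
    training (still scored).
    """

    X: pd.DataFrame
    precond: pd.DataFrame
    outcomes: pd.Series
    permanent_holdouts: tuple[str, ...] = ()
    imputed: list = field(default_factory=list)
    imputed_frac: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate column names")
        trained = self.outcomes.index.difference(self.permanent_holdouts)
        if self.outcomes.loc[trained].isna().any():
            raise ValueError("missing outcomes for trained patients")

    @property
    def patients(self) -> pd.Index:
        return self.X.index


@dataclass
class SelectedBiomarkers:
    """WB-ranked biomarker columns chosen on a training split."""

    ranking: list[tuple[str, float]]  # (column, WB ratio), WB descending
    top_n: int

    @property
    def columns(self) -> list[str]:
        return [c for c, _ in self.ranking[: self.top_n]]


@dataclass
class CVResult:
    """Collated double-holdout cross-validation output."""

    scores: pd.Series  # patient -> mean held-out prediction in [0, 1]
    holdout_pairs: list[tuple[str, str]]
    selections: list[list[str]]  # per-run selected columns
    n_runs: int
    seed: int


def aggregate_patient_biomarkers(
    well_meta: pd.DataFrame,
    biomarkers: pd.DataFrame,
    outcomes: pd.Series,
    assignment: PhenotypeAssignment | None = None,
    censor: set[int] = frozenset(),
    permanent_holdouts: tuple[str, ...] = (),
) -> TrialTable:
    """Average well biomarkers to the patient level per drug.

    Wells of censored phenotypes are removed first (when an assignment
    is given).  Each (patient, drug) cell is the mean biomarker vector
    over the surviving replicate wells; patient preconditions are
    averaged over all the patient's surviving wells.  Empty cells are
    imputed by the trial column mean and flagged.
    """
    meta = well_meta
    if censor:
        if assignment is None:
            raise ValueError("censoring requires a phenotype assignment")
        meta = censor_wells(well_meta, assignment, set(censor))
    joined = meta.join(biomarkers, how="inner")
    bm_cols = list(biomarkers.columns)
    cell = joined.groupby(["patient", "drug"])[bm_cols].mean()
    wide = cell.unstack("drug")
    wide.columns = [f"{drug}:{bm}" for bm, drug in wide.columns]
    wide = wide.reindex(sorted(wide.columns), axis=1)
    wide = wide.reindex(outcomes.index)
    imputed = [
        (p, c) for p in wide.index for c in wide.columns[wide.loc[p].isna()]
    ]
    imputed_frac = wide.isna().mean(axis=0)
    wide = wide.fillna(wide.mean(axis=0))
    precond = (
        joined.groupby("patient")[PRECONDITION_COLUMNS].mean().reindex(outcomes.index)
    )
    precond = precond.fillna(precond.mean(axis=0))
    return TrialTable(
        X=wide,
        precond=precond,
        outcomes=outcomes,
        permanent_holdouts=tuple(permanent_holdouts),
        imputed=imputed,
        imputed_frac=imputed_frac,
    )


def _response_columns(X: pd.DataFrame) -> list[str]:
    return [
        c for c in X.columns if ":" in c and c.split(":", 1)[1] in RESPONSE_BIOMARKERS
    ]


def bilinear_columns(
    X: pd.DataFrame, precond: pd.DataFrame, train_patients
) -> pd.DataFrame:
    """Bilinear biomarkers centered on the training patients.

    For each drug-response column x and precondition p in {NSD, DR, HW}
    the new column is ``(x - mean_train(x)) * (p - mean_train(p))``,
    evaluated for every patient but centered with training means only,
    so held-out patients never influence the construction.
    """
    cols = {}
    x_mean = X.loc[train_patients].mean(axis=0)
    p_mean = precond.loc[train_patients].mean(axis=0)
    for c in _response_columns(X):
        xc = X[c] - x_mean[c]
        for p in PRECONDITION_COLUMNS:
            cols[f"{c}x{p}"] = xc * (precond[p] - p_mean[p])
    return pd.DataFrame(cols, index=X.index)


def bilinear_biomarkers(table: TrialTable) -> TrialTable:
    """Augment a trial table with its bilinear biomarker set.

    Centering means are taken over the non-permanently-held-out
    patients.  (Cross-validation recomputes the bilinear set per fold
    with training-only means; this table-level form is for inspection
    and export.)
    """
    missing = [p for p in PRECONDITION_COLUMNS if p not in table.precond.columns]
    if missing:
        raise ValueError(f"missing precondition columns: {missing}")
    train = table.outcomes.index.difference(table.permanent_holdouts)
    extra = bilinear_columns(table.X, table.precond, train)
    return replace(table, X=pd.concat([table.X, extra], axis=1))


def wb_ratio(values, labels, cap: float = WB_CAP) -> float:
    """Between-cohort over within-cohort standard-deviation ratio.

    The between part is the standard deviation of the two cohort means;
    the within part is the pooled within-cohort standard deviation.
    Zero within-cohort spread returns the cap.  Identical cohort means
    give 0; the most discriminating columns have the largest WB.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two cohorts")
    a, b = v[y == classes[0]], v[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two patients per cohort")
    between = abs(a.mean() - b.mean()) / 2.0
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    within = np.sqrt(pooled)
    if within == 0:
        return cap if between > 0 else 0.0
    return float(min(between / within, cap))


def _wb_vector(X: pd.DataFrame, y: np.ndarray, cap: float = WB_CAP) -> pd.Series:
    mask = y == np.unique(y)[0]
    A, B = X.to_numpy(dtype=float)[mask], X.to_numpy(dtype=float)[~mask]
    between = np.abs(A.mean(0) - B.mean(0)) / 2.0
    pooled = ((len(A) - 1) * A.var(0, ddof=1) + (len(B) - 1) * B.var(0, ddof=1)) / (
        len(A) + len(B) - 2
    )
    within = np.sqrt(pooled)
    with np.errstate(divide="ignore", invalid="ignore"):
        wb = np.where(within > 0, between / within, np.where(between > 0, cap, 0.0))
    return pd.Series(np.minimum(wb, cap), index=X.columns)


def select_biomarkers(
    X_train: pd.DataFrame, y_train, top_n: int = 10
) -> SelectedBiomarkers:
    """Rank columns by WB ratio on the training patients only."""
    y = np.asarray(y_train)
    if len(np.unique(y)) != 2 or min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need two cohorts with >= 2 training patients each")
    wb = _wb_vector(X_train, y)
    order = wb.sort_values(ascending=False, kind="stable")
    return SelectedBiomarkers(
        ranking=[(c, float(v)) for c, v in order.items()], top_n=int(top_n)
    )


def train_classifier(X, y, seed: int = 0) -> Pipeline:
    """Minimal shallow feed-forward network: two hidden layers of 8 units.

    tanh hidden activations, sigmoid (logistic) output trained against
    cross-entropy with an L2 penalty of 1e-3 by a full-batch
    quasi-Newton optimizer; deterministic under a fixed seed.  Features
    are standardized inside the pipeline.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 4:
        raise ValueError("need at least 4 training patients")
    net = MLPClassifier(
        hidden_layer_sizes=(8, 8),
        activation="tanh",
        solver="lbfgs",
        alpha=1e-3,
        max_iter=2000,
        random_state=int(seed),
    )
    model = Pipeline([("scale", StandardScaler()), ("net", net)])
    model.fit(X, y)
    return model


# linear columns imputed for more than this fraction of patients (after
# censoring) are too thin to rank reliably and are excluded, together
# with their bilinear descendants, from selection
MAX_IMPUTED_FRACTION = 0.3


def _reliable_table(table: TrialTable) -> TrialTable:
    if table.imputed_frac is None:
        return table
    keep = table.imputed_frac.index[table.imputed_frac <= MAX_IMPUTED_FRACTION]
    keep = [c for c in table.X.columns if c in set(keep)]
    return replace(table, X=table.X[keep])


def _augmented_fold(table: TrialTable, train_patients) -> pd.DataFrame:
    extra = bilinear_columns(table.X, table.precond, train_patients)
    return pd.concat([table.X, extra], axis=1)


def double_holdout_cv(
    table: TrialTable,
    n_runs: int = 60,
    top_n: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated double-holdout cross-validation with per-fold selection.

    Each run draws one resistant and one sensitive patient uniformly at
    random (with replacement across runs), selects the top WB columns on
    the remaining training patients, trains the shallow network and
    scores the held-out pair (and any permanent hold-outs).  Per-patient
    scores are the mean over the runs in which the patient was scored.
    """
    outcomes = table.outcomes
    perm = set(table.permanent_holdouts)
    res_pool = [p for p in outcomes.index if outcomes[p] == "resistant" and p not in perm]
    sen_pool = [p for p in outcomes.index if outcomes[p] == "sensitive" and p not in perm]
    if len(res_pool) < 3 or len(sen_pool) < 3:
        raise ValueError("need at least 3 patients per cohort after permanent hold-outs")
    table = _reliable_table(table)
    rng = np.random.default_rng(seed)
    collected: dict[str, list[float]] = {p: [] for p in outcomes.index}
    pairs: list[tuple[str, str]] = []
    selections: list[list[str]] = []
    y_all = (outcomes == "sensitive").astype(int)
    for _ in range(n_runs):
        pair = (res_pool[rng.integers(len(res_pool))], sen_pool[rng.integers(len(sen_pool))])
        pairs.append(pair)
        train = [p for p in outcomes.index if p not in perm and p not in pair]
        Xa = _augmented_fold(table, train)
        sel = select_biomarkers(Xa.loc[train], y_all.loc[train], top_n=top_n)
        cols = sel.columns
        selections.append(cols)
        net_seed = int(rng.integers(2**31 - 1))
        model = train_classifier(Xa.loc[train, cols], y_all.loc[train], seed=net_seed)
        to_score = list(pair) + sorted(perm)
        proba = model.predict_proba(Xa.loc[to_score, cols].to_numpy(dtype=float))[:, 1]
        for p, s in zip(to_score, proba):
            collected[p].append(float(s))
    scored = {p: float(np.mean(v)) for p, v in collected.items() if v}
    unscored = [p for p in outcomes.index if p not in scored and p not in perm]
    if unscored:
        import warnings

        warnings.warn(f"patients never held out in {n_runs} runs: {unscored}")
    return CVResult(
        scores=pd.Series(scored, name="score"),
        holdout_pairs=pairs,
        selections=selections,
        n_runs=n_runs,
        seed=seed,
    )


def roc_auc(result: CVResult | pd.Series, outcomes: pd.Series):
    """ROC points (threshold sweep) and the trapezoid AUC.

    Sensitive is the positive class; ties between scores are handled by
    midpoint ranking (Mann-Whitney convention).

    Returns ``(points, auc)`` with points as a DataFrame of (fpr, tpr,
    threshold).
    """
    scores = result.scores if isinstance(result, CVResult) else result
    y = (outcomes.loc[scores.index] == "sensitive").astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need both cohorts among scored patients")
    s = scores.to_numpy(dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return points, auc


def biomarker_prevalence(result: CVResult) -> dict[str, pd.Series]:
    """Prevalence of selected columns, features and drugs across runs.

    Returns three tables: by full column, by feature name (bilinear
    columns count both their response biomarker and their precondition
    partner), and by drug -- each as the fraction of hold-out passes in
    which the item was selected.
    """
    if not result.selections or not any(result.selections):
        raise ValueError("no selections recorded")
    n = len(result.selections)
    col_counts: dict[str, int] = {}
    feat_counts: dict[str, int] = {}
    drug_counts: dict[str, int] = {}
    for sel in result.selections:
        feats = set()
        drugs = set()
        for col in sorted(set(sel)):
            col_counts[col] = col_counts.get(col, 0) + 1
            drug, rest = col.split(":", 1)
            drugs.add(drug)
            if "x" in rest and rest.rsplit("x", 1)[1] in PRECONDITION_COLUMNS:
                bm, p = rest.rsplit("x", 1)
                feats.update({bm, p})
            else:
                feats.add(rest)
        for f in feats:
            feat_counts[f] = feat_counts.get(f, 0) + 1
        for d in drugs:
            drug_counts[d] = drug_counts.get(d, 0) + 1
    def as_series(d: dict) -> pd.Series:
        s = pd.Series(d).div(n)
        return s.iloc[np.lexsort((s.index, -s.to_numpy()))]  # prevalence desc, name asc
    return {
        "by_column": as_series(col_counts),
        "by_feature": as_series(feat_counts),
        "by_drug": as_series(drug_counts),
    }


def censoring_experiment(
    well_meta: pd.DataFrame,
    biomarkers: pd.DataFrame,
    outcomes: pd.Series,
    assignment: PhenotypeAssignment,
    permanent_holdouts: tuple[str, ...] = (),
    n_runs: int = 60,
    top_n: int = 10,
    seed: int = 0,
) -> dict[str, dict]:
    """Compare prediction with and without phenotype censoring.

    Runs three complete cross-validation passes sharing the same
    hold-out schedule seed: all wells ("full"), red-shifted wells
    removed ("no_pheno2"), and mid-frequency-suppressed wells removed
    ("no_pheno4").  Returns per-pass AUC, ROC points and the CV result.
    """
    out = {}
    for name, censor in (("full", set()), ("no_pheno2", {2}), ("no_pheno4", {4})):
        table = aggregate_patient_biomarkers(
            well_meta,
            biomarkers,
            outcomes,
            assignment=assignment,
            censor=censor,
            permanent_holdouts=permanent_holdouts,
        )
        cv = double_holdout_cv(table, n_runs=n_runs, top_n=top_n, seed=seed)
        points, auc = roc_auc(cv, outcomes)
        out[name] = {"auc": auc, "roc": points, "cv": cv}
    return out
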