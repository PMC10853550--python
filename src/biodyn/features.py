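"""Per-well drug-response features and pooled biomarkers.

Each well's spectrogram plus its baseline statistics are reduced to a
40-element feature vector, grouped as:

* 9 global features ``g_mn``: inner products of D(x, y) with discrete
  Legendre-type polynomials of order m in normalized log-frequency x and
  order n in normalized post-treatment time y, m, n in {0, 1, 2};
* 9 local features: mean of D over each cell of a 3x3 partition into
  frequency thirds (low/mid/high in log-frequency) and time thirds
  (early/mid/late post-treatment);
* 9 precondition features of the pre-treatment sample: NSD (temporal
  speckle contrast), DR (spectral dynamic range, dB), HW (average
  Doppler frequency as log-frequency centroid), KN (knee frequency),
  BB (backscatter brightness), SF (high-frequency log-log slope),
  SE (normalized spectral entropy), S0 (low-frequency plateau),
  HT (sample extent proxy);
* 9 drug-induced changes of the preconditions, recomputed on the final
  third of the post-treatment loops;
* 3 baseline features: pre-treatment drift magnitude, drift slope and
  residual noise;
* 1 data-quality value in [0, 1].

Strongly covarying features are pooled into 12 named biomarkers
(ALLF, ALLFT, SDIP, CDIP, HI, SDIP2, DNSD, DKN, NSD, DR, HW, DQ) by a
weighted mean of z-scored members; the pooling map ships as an editable
YAML file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .spectral import fit_spectral_model
from .spectroscopy import Spectrogram, WellSpectrumSeries, drug_response_spectrogram

__all__ = [
    "FEATURE_NAMES",
    "BIOMARKER_NAMES",
    "PRECONDITION_NAMES",
    "PoolingMap",
    "ZScoreStats",
    "global_legendre_features",
    "local_band_features",
    "precondition_features",
    "precondition_deltas",
    "baseline_features",
    "data_quality",
    "assemble_feature_vector",
    "extract_features",
    "extract_feature_table",
    "fit_zscores",
    "pool_features",
    "load_pooling_map",
    "default_pooling_map",
]

PRECONDITION_NAMES = ["nsd", "dr", "hw", "kn", "bb", "sf", "se", "s0", "ht"]

GLOBAL_NAMES = [f"g{m}{n}" for m in range(3) for n in range(3)]
LOCAL_NAMES = [f"loc_f{i}_t{j}" for i in range(3) for j in range(3)]
DELTA_NAMES = [f"d_{p}" for p in PRECONDITION_NAMES]
BASELINE_NAMES = ["b_drift", "b_slope", "b_resid"]

FEATURE_NAMES = GLOBAL_NAMES + LOCAL_NAMES + PRECONDITION_NAMES + DELTA_NAMES + BASELINE_NAMES + ["dq"]

BIOMARKER_NAMES = [
    "ALLF", "ALLFT", "SDIP", "CDIP", "HI", "SDIP2", "DNSD", "DKN", "NSD", "DR", "HW", "DQ",
]

# biomarkers that describe the drug response (as opposed to sample preconditions)
RESPONSE_BIOMARKERS = ["ALLF", "ALLFT", "SDIP", "CDIP", "HI", "SDIP2", "DNSD", "DKN"]


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2
    w[1:] += dx / 2
    return w / w.sum()


def _affine_to_unit(v: np.ndarray) -> np.ndarray:
    lo, hi = v[0], v[-1]
    if hi == lo:
        return np.zeros_like(v)
    return 2.0 * (v - lo) / (hi - lo) - 1.0


def _discrete_polys(x: np.ndarray, w: np.ndarray) -> list[np.ndarray]:
    """Monic polynomials of degree 0..2, orthogonal under the weights.

    Gram-Schmidt on the actual grid, so the orthogonality used by the
    feature inner products is exact regardless of grid spacing.  p1 and
    p2 agree with the Legendre polynomials x and (3x^2-1)/2 up to scale
    and O(h^2) grid corrections.
    """
    p0 = np.ones_like(x)
    m1 = float(np.dot(w, x))
    p1 = x - m1
    x2 = x * x
    b = float(np.dot(w, x2))
    denom = float(np.dot(w, p1 * p1))
    a = float(np.dot(w, x2 * p1)) / denom if denom > 0 else 0.0
    p2 = x2 - a * p1 - b
    return [p0, p1, p2]


def global_legendre_features(sg: Spectrogram) -> pd.Series:
    """Global time-frequency decomposition of the post-treatment response.

    ``g_mn`` is the weighted inner product of D with the degree-m
    polynomial in normalized log-frequency and the degree-n polynomial
    in normalized post-treatment time (trapezoidal weights on both
    axes).  Raw inner products are reported, not normalized by the
    polynomial norms, so for D = x the feature g10 equals <x^2>.
    """
    D = sg.D[:, sg.post_slice]
    if D.shape[1] < 3:
        raise ValueError("need at least 3 post-treatment loops")
    if D.shape[0] < 9:
        raise ValueError("need at least 9 frequency bins")
    x = _affine_to_unit(sg.log_freqs)
    y = _affine_to_unit(sg.loop_times[sg.post_slice])
    wx = _trapezoid_weights(x)
    wy = _trapezoid_weights(y)
    px = _discrete_polys(x, wx)
    py = _discrete_polys(y, wy)
    out = {}
    for m in range(3):
        for n in range(3):
            out[f"g{m}{n}"] = float((wx * px[m]) @ D @ (wy * py[n]))
    return pd.Series(out)


def local_band_features(sg: Spectrogram) -> pd.Series:
    """Mean of D over a 3x3 frequency-band x time-epoch partition."""
    D = sg.D[:, sg.post_slice]
    if D.shape[1] < 3:
        raise ValueError("need at least 3 post-treatment loops")
    if D.shape[0] < 9:
        raise ValueError("need at least 9 frequency bins")
    f_edges = np.linspace(0, D.shape[0], 4).astype(int)
    t_edges = np.linspace(0, D.shape[1], 4).astype(int)
    out = {}
    for i in range(3):
        for j in range(3):
            cell = D[f_edges[i] : f_edges[i + 1], t_edges[j] : t_edges[j + 1]]
            out[f"loc_f{i}_t{j}"] = float(cell.mean())
    return pd.Series(out)


def _spectrum_metrics(freqs: np.ndarray, S: np.ndarray, stack_stats: dict | None) -> dict:
    """The nine precondition metrics of a single (averaged) spectrum."""
    out = dict.fromkeys(PRECONDITION_NAMES, 0.0)
    if not np.all(np.isfinite(S)) or S.max() <= 0:
        out["ht"] = 1.0
        return out
    lf = np.log10(freqs)
    total = float(np.trapezoid(S, freqs))
    if stack_stats and "mean_intensity" in stack_stats and stack_stats["mean_intensity"] > 0:
        out["nsd"] = float(stack_stats.get("std_intensity", 0.0) / stack_stats["mean_intensity"])
        out["bb"] = float(stack_stats["mean_intensity"])
    else:
        # spectral surrogates when only spectra exist for the well
        out["nsd"] = float(np.sqrt(total))
        out["bb"] = total
    out["dr"] = float(10.0 * np.log10(S[0] / S[-1])) if S[0] > 0 and S[-1] > 0 else 0.0
    w = _trapezoid_weights(lf)
    out["hw"] = float(np.dot(w * S, lf) / np.dot(w, S))
    try:
        out["kn"] = float(fit_spectral_model(freqs, S).knee_freq)
    except (ValueError, RuntimeError):
        out["kn"] = float(freqs[0])
    hi = freqs >= freqs[-1] / 10.0
    if hi.sum() >= 2 and np.all(S[hi] > 0):
        out["sf"] = float(np.polyfit(lf[hi], np.log10(S[hi]), 1)[0])
    p = S / S.sum()
    nz = p > 0
    out["se"] = float(-(p[nz] * np.log(p[nz])).sum() / np.log(len(S)))
    lo = freqs <= freqs[0] * 10**0.5
    out["s0"] = float(S[lo].mean()) if lo.any() else float(S[0])
    out["ht"] = float(stack_stats["bright_fraction"]) if stack_stats and "bright_fraction" in stack_stats else 1.0
    return out


def _geometric_mean_spectrum(spectra: np.ndarray, eps_rel: float = 1e-12) -> np.ndarray:
    top = spectra.max()
    if top <= 0:
        return np.zeros(spectra.shape[0])
    return np.exp(np.mean(np.log(np.maximum(spectra, eps_rel * top)), axis=1))


def precondition_features(
    series: WellSpectrumSeries, stack_stats: dict | None = None
) -> pd.Series:
    """Sample-health metrics computed on pre-treatment data only.

    ``stack_stats`` may carry intensity-domain statistics
    (``mean_intensity``, ``std_intensity``, ``bright_fraction``) when the
    raw stacks are available; otherwise spectral surrogates are used for
    NSD, BB and HT.
    """
    pre = series.spectra[:, : series.treatment_loop]
    S = _geometric_mean_spectrum(pre)
    return pd.Series(_spectrum_metrics(series.freqs, S, stack_stats))


def precondition_deltas(
    series: WellSpectrumSeries,
    stack_stats_post: dict | None = None,
    pre: pd.Series | None = None,
) -> pd.Series:
    """Treatment-induced change of each precondition.

    Each metric is recomputed on the final third of the post-treatment
    loops and differenced against its pre-treatment value (``pre`` may
    be passed to avoid recomputing it).
    """
    n_post = len(series.loops) - series.treatment_loop
    if n_post < 1:
        raise ValueError("need at least one post-treatment loop")
    n_late = max(1, n_post // 3)
    late = series.spectra[:, len(series.loops) - n_late :]
    if pre is None:
        pre = precondition_features(series)
    post = _spectrum_metrics(series.freqs, _geometric_mean_spectrum(late), stack_stats_post)
    return pd.Series({f"d_{k}": float(post[k] - pre[k]) for k in PRECONDITION_NAMES})


def baseline_features(sg: Spectrogram) -> pd.Series:
    """Pre-treatment drift magnitude, drift slope, and residual noise.

    Computed on the pre-treatment columns of D: mean |D|, the slope of
    the frequency-averaged D against time (per hour), and the residual
    standard deviation after removing that linear trend.
    """
    pre = sg.D[:, : sg.treatment_loop]
    t = sg.loop_times[: sg.treatment_loop]
    drift = float(np.abs(pre).mean())
    mean_t = pre.mean(axis=0)
    if len(t) >= 2:
        coef = np.polyfit(t, mean_t, 1)
        slope = float(coef[0])
        resid = float(np.std(mean_t - np.polyval(coef, t)))
    else:
        slope, resid = 0.0, 0.0
    return pd.Series({"b_drift": drift, "b_slope": slope, "b_resid": resid})


def data_quality(series: WellSpectrumSeries, snr_threshold: float = 3.0) -> float:
    """Fraction of loops passing finiteness, positivity and SNR checks.

    SNR per loop is the median mid-band density over the median density
    of the top half-decade (a noise-floor estimate); floor-dominated
    spectra have SNR near 1 and fail the default threshold.
    """
    f = series.freqs
    n = f.size
    S = series.spectra
    mid = slice(n // 3, 2 * n // 3)
    floor_band = f >= f[-1] / 10**0.5
    clean = np.all(np.isfinite(S), axis=0) & np.all(S >= 0, axis=0) & (S.max(axis=0) > 0)
    floors = np.median(S[floor_band], axis=0)
    mids = np.median(S[mid], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(floors > 0, mids / floors, np.inf)
    ok = int(np.sum(clean & (snr >= snr_threshold)))
    return ok / len(series.loops)


def assemble_feature_vector(
    global_f: pd.Series,
    local_f: pd.Series,
    precond: pd.Series,
    dprecond: pd.Series,
    baseline: pd.Series,
    dq: float,
) -> pd.Series:
    """Concatenate the six feature groups in canonical order (length 40)."""
    fv = pd.concat([global_f, local_f, precond, dprecond, baseline, pd.Series({"dq": dq})])
    missing = [n for n in FEATURE_NAMES if n not in fv.index]
    if missing:
        raise ValueError(f"missing features: {missing}")
    fv = fv.reindex(FEATURE_NAMES)
    if len(fv) != 40:
        raise ValueError("feature vector must have exactly 40 entries")
    if not np.all(np.isfinite(fv.to_numpy(dtype=float))):
        raise ValueError("feature vector contains non-finite values")
    return fv


def extract_features(
    series: WellSpectrumSeries,
    stack_stats: dict | None = None,
    spectrogram: Spectrogram | None = None,
) -> pd.Series:
    """Full 40-element feature vector of one well."""
    sg = spectrogram or drug_response_spectrogram(series)
    pre = precondition_features(series, stack_stats)
    return assemble_feature_vector(
        global_legendre_features(sg),
        local_band_features(sg),
        pre,
        precondition_deltas(series, pre=pre),
        baseline_features(sg),
        data_quality(series),
    )


def extract_feature_table(wells: list[WellSpectrumSeries]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature vectors for a list of wells.

    Returns ``(meta, features)``: well metadata (patient, drug) and the
    wells x 40 feature matrix, both indexed by well id.
    """
    meta = pd.DataFrame(
        {"patient": [w.patient for w in wells], "drug": [w.drug for w in wells]},
        index=pd.Index([w.well_id for w in wells], name="well_id"),
    )
    feats = pd.DataFrame(
        [extract_features(w) for w in wells],
        index=meta.index,
    )
    return meta, feats


@dataclass(frozen=True)
class ZScoreStats:
    """Per-feature standardization statistics fitted over a trial's wells."""

    mean: pd.Series
    std: pd.Series

    def transform(self, features: pd.DataFrame | pd.Series):
        z = (features - self.mean) / self.std.replace(0.0, np.nan)
        return z.fillna(0.0)


def fit_zscores(features: pd.DataFrame) -> ZScoreStats:
    return ZScoreStats(mean=features.mean(axis=0), std=features.std(axis=0, ddof=0))


class PoolingMap(dict):
    """Biomarker name -> list of (feature name, weight); weights sum to 1."""

    @classmethod
    def from_dict(cls, raw: dict) -> "PoolingMap":
        pm = cls()
        for name in BIOMARKER_NAMES:
            if name not in raw:
                raise ValueError(f"pooling map missing biomarker {name!r}")
        for name, members in raw.items():
            if name not in BIOMARKER_NAMES:
                raise ValueError(f"unknown biomarker {name!r}")
            if not members:
                raise ValueError(f"empty pool for {name!r}")
            total = float(sum(members.values()))
            if total <= 0:
                raise ValueError(f"non-positive pool weights for {name!r}")
            pool = []
            for feat, w in members.items():
                if feat not in FEATURE_NAMES:
                    raise ValueError(f"unknown feature {feat!r} in pool {name!r}")
                pool.append((feat, float(w) / total))
            pm[name] = pool
        return pm


def load_pooling_map(path) -> PoolingMap:
    with open(path) as fh:
        return PoolingMap.from_dict(yaml.safe_load(fh))


def default_pooling_map() -> PoolingMap:
    ref = importlib.resources.files("biodyn").joinpath("pooling_map.yaml")
    return PoolingMap.from_dict(yaml.safe_load(ref.read_text()))


def pool_features(
    features: pd.DataFrame | pd.Series,
    pooling_map: PoolingMap | None = None,
    zstats: ZScoreStats | None = None,
):
    """Pool z-scored features into the 12 named biomarkers.

    ``zstats`` should be fitted over the trial's wells and reused so the
    mapping is deterministic; when omitted and a DataFrame is given, the
    statistics are fitted on that table.
    """
    pm = pooling_map or default_pooling_map()
    if zstats is None:
        if isinstance(features, pd.Series):
            raise ValueError("zstats required when pooling a single well")
        zstats = fit_zscores(features)
    z = zstats.transform(features)
    if isinstance(z, pd.Series):
        vals = {b: float(sum(w * z[f] for f, w in pm[b])) for b in BIOMARKER_NAMES}
        return pd.Series(vals).reindex(BIOMARKER_NAMES)
    out = pd.DataFrame(index=z.index, columns=BIOMARKER_NAMES, dtype=float)
    for b in BIOMARKER_NAMES:
        acc = np.zeros(len(z))
        for f, w in pm[b]:
            acc = acc + w * z[f].to_numpy(dtype=float)
        out[b] = acc
    return out
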