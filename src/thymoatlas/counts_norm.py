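"""Count-matrix normalization, accessibility patterns, and PCA.

Holds the pipeline's central container (:class:`CountMatrix`),
median-of-ratios size factors, a closed-form negative-binomial
variance-stabilizing transform, the four-way accessibility-pattern
rules applied across the maturation axis, and a PCA model that supports
out-of-sample projection and peak-importance ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

STAGE_ORDER = ("DN2", "DN3", "ISP", "DPCD3neg", "DPCD3pos", "SPCD4", "SPCD8")


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-sample metadata.

    ``metadata`` is indexed by sample id and carries at least
    ``stage``, ``donor`` and ``cohort`` columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.metadata.loc[list(sample_ids)])

    def to_tsv(self, counts_path, metadata_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts, meta)


@dataclass
class PatternConfig:
    """Thresholds of the accessibility-pattern rules (normalized read counts)."""

    sd_threshold: float = 12.0
    step_threshold: float = 24.0

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0 or self.step_threshold <= 0:
            raise ValueError("pattern thresholds must be > 0")


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    reference: pd.Series | None = None,
    pseudo_reference: bool = False,
) -> pd.Series:
    """Median-of-ratios size factors.

    ``factor_s = median_f(count_fs / geomean_f)`` over features with
    nonzero counts in every sample.  ``reference`` supplies an external
    geometric-mean reference profile (used by leave-one-out folds so a
    held-out sample cannot shape its own reference).  With
    ``pseudo_reference`` the geometric mean is taken over nonzero
    entries only, a fallback for sparse matrices.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    if reference is None:
        with np.errstate(divide="ignore"):
            log = np.log(arr)
        if pseudo_reference:
            log = np.where(np.isfinite(log), log, np.nan)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                ref = np.exp(np.nanmean(log, axis=1))
            ref = np.where(np.isfinite(ref), ref, 0.0)
        else:
            ref = np.exp(log.mean(axis=1))
    else:
        ref = reference.reindex(mat.index).to_numpy(dtype=float)
    usable = ref > 0
    if not usable.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "retry with pseudo_reference=True"
        )
    ratios = arr[usable] / ref[usable, None]
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise ValueError("non-positive size factor; matrix too sparse for median-of-ratios")
    if reference is None:
        # unit geometric mean makes re-normalization idempotent; skipped when an
        # external reference anchors the scale (e.g. cross-validation folds)
        factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=mat.columns, name="size_factor")


def geometric_reference(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-feature geometric mean across samples (zero where any count is zero)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    with np.errstate(divide="ignore"):
        log = np.log(mat.to_numpy(dtype=float))
    return pd.Series(np.exp(log.mean(axis=1)), index=mat.index, name="geomean")


def normalize(counts: CountMatrix | pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample by its size factor."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(mat)
    return mat / factors


def vst(x, dispersion: float):
    """Closed-form variance-stabilizing transform for NB counts.

    For dispersion ``a > 0`` this is ``(2/ln 2) * asinh(sqrt(a x))``
    (the antiderivative of ``1/sqrt(v(mu))`` with ``v = mu + a mu^2``,
    rescaled so large-count differences approach log2 differences).
    At ``a = 0`` the Poisson limit ``(2/ln 2) * sqrt(x)`` is used.
    Monotone in ``x`` and finite at 0.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if dispersion == 0:
        out = 2.0 * np.sqrt(arr) / np.log(2.0)
    else:
        out = 2.0 * np.arcsinh(np.sqrt(dispersion * arr)) / np.log(2.0)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def inverse_vst(v, dispersion: float):
    """Invert :func:`vst`: map transformed values back to the count scale."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    arr = np.asarray(v, dtype=float)
    if dispersion == 0:
        out = (arr * np.log(2.0) / 2.0) ** 2
    else:
        out = np.sinh(arr * np.log(2.0) / 2.0) ** 2 / dispersion
    if isinstance(v, pd.DataFrame):
        return pd.DataFrame(out, index=v.index, columns=v.columns)
    if isinstance(v, pd.Series):
        return pd.Series(out, index=v.index, name=v.name)
    return out


def moment_dispersion(norm_counts: pd.DataFrame, trim: float = 0.2) -> float:
    """Single genome-wide NB dispersion: trimmed mean of per-feature
    method-of-moments estimates on normalized counts."""
    arr = norm_counts.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    var = arr.var(axis=1, ddof=1)
    ok = mean > 0
    alpha = np.maximum(0.0, (var[ok] - mean[ok]) / mean[ok] ** 2)
    if alpha.size == 0:
        return 0.0
    return float(stats.trim_mean(alpha, trim))


def row_center(values: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-style row normalization: subtract each row's mean."""
    return values.sub(values.mean(axis=1), axis=0)


def categorize_patterns(
    stage_means: pd.DataFrame, cfg: PatternConfig | None = None
) -> pd.Series:
    """Assign each peak one of increasing/decreasing/fluctuating/steady.

    ``stage_means`` holds normalized mean read counts, peaks x ordered
    stages.  With the stage-mean standard deviation below the SD
    threshold a peak is steady; otherwise a monotone profile (non-strict
    with at least one strict step) is increasing or decreasing, a
    profile whose consecutive steps all stay within the step threshold
    is steady, and anything else fluctuates.
    """
    cfg = cfg or PatternConfig()
    if stage_means.shape[1] < 2:
        raise ValueError("need >= 2 stages")
    arr = stage_means.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("stage means contain NaN")
    sd = arr.std(axis=1, ddof=1)
    diffs = np.diff(arr, axis=1)
    up = (diffs >= 0).all(axis=1) & (diffs > 0).any(axis=1)
    down = (diffs <= 0).all(axis=1) & (diffs < 0).any(axis=1)
    small_steps = (np.abs(diffs) <= cfg.step_threshold).all(axis=1)
    labels = np.full(len(arr), "steady", dtype=object)
    high = sd >= cfg.sd_threshold
    labels[high & up] = "increasing"
    labels[high & down] = "decreasing"
    rest = high & ~up & ~down & ~small_steps
    labels[rest] = "fluctuating"
    return pd.Series(labels, index=stage_means.index, name="pattern")


@dataclass
class PcaModel:
    """Centering vector, rotation (features x components), explained variance."""

    center: pd.Series
    rotation: pd.DataFrame
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        rot = self.rotation.to_numpy()
        gram = rot.T @ rot
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("rotation columns must be orthonormal")

    @property
    def n_components(self) -> int:
        return self.rotation.shape[1]


def fit_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaModel:
    """PCA over samples (columns) in feature space (rows are variables)."""
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n_components = n_components or min(X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    rotation = pd.DataFrame(
        pca.components_.T,
        index=matrix.index,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)],
    )
    center = pd.Series(pca.mean_, index=matrix.index, name="center")
    return PcaModel(center, rotation, pca.explained_variance_)


def project(model: PcaModel, new_samples: pd.DataFrame) -> pd.DataFrame:
    """Project columns of ``new_samples`` into the model's component space."""
    missing = model.rotation.index.difference(new_samples.index)
    if len(missing):
        raise ValueError(f"new samples missing model features: {list(missing[:5])}")
    X = new_samples.loc[model.rotation.index].to_numpy(dtype=float).T
    scores = (X - model.center.to_numpy()) @ model.rotation.to_numpy()
    return pd.DataFrame(scores, index=new_samples.columns, columns=model.rotation.columns)


def peak_importance(model: PcaModel, k: int = 2) -> pd.DataFrame:
    """Rank peaks by their largest absolute loading on the first k components.

    Ties break by peak id.
    """
    if k > model.n_components:
        raise ValueError(f"k={k} exceeds {model.n_components} fitted components")
    loading = model.rotation.iloc[:, :k].abs().max(axis=1)
    out = pd.DataFrame({"importance": loading})
    out = out.sort_values(
        by=["importance"], ascending=False, kind="mergesort"
    )
    # stable sort on descending importance; break exact ties by peak id
    out["_id"] = out.index
    out = out.sort_values(["importance", "_id"], ascending=[False, True], kind="mergesort")
    out = out.drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
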