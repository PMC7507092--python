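"""Stage-signature construction, deconvolution, and cross-validation.

The signature matrix collects, for every developmental group, the
``n_base`` one-vs-all significant peaks with the largest positive
log2 fold change (hyper-accessible in that group), de-duplicated, with
VST-normalized group-mean reference profiles.  ``n_base`` is chosen by
a sweep minimizing the matrix 2-norm condition number (the kappa of
CIBERSORT-style signature optimization); Cohen's kappa is computed
separately as the chance-corrected agreement of cross-validation
confusion matrices.  Deconvolution solves a non-negative least-squares
problem on z-scored profiles, with an optional nu-SVR mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from thymoatlas.counts_norm import (
    CountMatrix,
    geometric_reference,
    moment_dispersion,
    normalize,
    size_factors,
    vst,
)
from thymoatlas.differential import DifferentialConfig, one_vs_all

DEFAULT_MERGE_MAP = {
    "DN2": "DN2",
    "DN3": "DN3.ISP",
    "ISP": "DN3.ISP",
    "DPCD3neg": "DP",
    "DPCD3pos": "DP",
    "SPCD4": "SPCD4",
    "SPCD8": "SPCD8",
}


@dataclass
class SignatureConfig:
    """Sweep bounds and the stage-to-group merge map."""

    n_min: int = 300
    n_max: int = 800
    n_step: int = 10
    merge_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGE_MAP))
    fdr: float = 0.3

    def __post_init__(self) -> None:
        if self.n_min > self.n_max or self.n_step <= 0:
            raise ValueError("need n_min <= n_max and n_step > 0")


@dataclass
class SignatureMatrix:
    """Signature peaks x groups VST reference profiles with provenance."""

    values: pd.DataFrame  # peaks x groups
    n_base: int
    metric: float | None = None
    vst_dispersion: float | None = None  # dispersion used by the VST, if known

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("signature contains duplicate peaks")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty signature matrix")

    @property
    def peaks(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> pd.Index:
        return self.values.columns


@dataclass
class DeconvolutionResult:
    """Per-sample stage fractions with goodness of fit."""

    fractions: pd.Series
    correlation: float
    rmse: float

    def __post_init__(self) -> None:
        if (self.fractions < -1e-12).any():
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")


@dataclass
class CVReport:
    """Leave-one-out cross-validation summary."""

    per_sample: pd.DataFrame  # true, predicted, passed
    correct_rate: float
    confusion: pd.DataFrame
    cohens_kappa: float


def merge_labels(labels, merge_map: Mapping[str, str] | None = None) -> pd.Series:
    """Map stage labels onto merged developmental groups."""
    merge_map = merge_map or DEFAULT_MERGE_MAP
    labels = pd.Series(labels)
    unmapped = set(labels.unique()) - set(merge_map)
    if unmapped:
        raise KeyError(f"labels without a merge mapping: {sorted(unmapped)}")
    return labels.map(merge_map)


def build_signature(
    diff: Mapping[str, pd.DataFrame],
    vst_counts: pd.DataFrame,
    group_labels: pd.Series,
    n_base: int,
    vst_dispersion: float | None = None,
) -> SignatureMatrix:
    """Collect per-group top-LFC significant peaks into a signature.

    For each group the ``n_base`` significant peaks with the largest
    positive log2 fold change are taken; the union is de-duplicated and
    reference values are per-group means of the VST counts.  A group
    with fewer than ``n_base`` significant peaks contributes all of
    them with a warning; a group with none at all falls back to its
    ``n_base`` largest positive-LFC peaks so the signature keeps a
    column for every group.
    """
    group_labels = pd.Series(group_labels)
    selected: list[pd.Index] = []
    for group, res in diff.items():
        positive = res[res["log2FoldChange"] > 0]
        hits = positive[positive["significant"]].sort_values(
            "log2FoldChange", ascending=False, kind="mergesort"
        )
        if len(hits) == 0:
            warnings.warn(
                f"group {group}: no significant peaks; falling back to top-LFC peaks",
                stacklevel=2,
            )
            hits = positive.sort_values("log2FoldChange", ascending=False, kind="mergesort")
        elif len(hits) < n_base:
            warnings.warn(
                f"group {group}: only {len(hits)} significant peaks (< n_base={n_base})",
                stacklevel=2,
            )
        selected.append(hits.index[:n_base])
    peak_ids = pd.Index([])
    for idx in selected:
        peak_ids = peak_ids.union(idx, sort=False)
    peak_ids = pd.Index(pd.unique(peak_ids))
    groups = list(diff.keys())
    ref = pd.DataFrame(index=peak_ids, columns=groups, dtype=float)
    for group in groups:
        ids = group_labels.index[group_labels == group]
        ref[group] = vst_counts.loc[peak_ids, list(ids)].mean(axis=1)
    return SignatureMatrix(values=ref, n_base=n_base, vst_dispersion=vst_dispersion)


def condition_metric(sig: SignatureMatrix | pd.DataFrame) -> float:
    """2-norm condition number (sigma_max / sigma_min) of the group profiles."""
    values = sig.values if isinstance(sig, SignatureMatrix) else sig
    arr = np.asarray(values, dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("need >= 2 groups")
    s = np.linalg.svd(arr, compute_uv=False)
    if s[-1] <= s[0] * np.finfo(float).eps * max(arr.shape):
        return np.inf
    return float(s[0] / s[-1])


def sweep_signature(
    diff: Mapping[str, pd.DataFrame],
    vst_counts: pd.DataFrame,
    group_labels: pd.Series,
    cfg: SignatureConfig | None = None,
) -> tuple[SignatureMatrix, pd.DataFrame]:
    """Build signatures over the n_base sweep; keep the best-conditioned one."""
    cfg = cfg or SignatureConfig()
    if not diff or all(len(r) == 0 for r in diff.values()):
        raise ValueError("empty differential results")
    rows = []
    best: SignatureMatrix | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n in range(cfg.n_min, cfg.n_max + 1, cfg.n_step):
            sig = build_signature(diff, vst_counts, group_labels, n)
            metric = condition_metric(sig)
            sig.metric = metric
            rows.append({"n_base": n, "n_peaks": len(sig.peaks), "condition_number": metric})
            if best is None or metric < best.metric:
                best = sig
    table = pd.DataFrame(rows)
    return best, table


def deconvolve(
    sig: SignatureMatrix,
    mixture_profile: pd.Series,
    method: str = "nnls",
    dispersion: float | None = None,
) -> DeconvolutionResult:
    """Estimate group fractions of a mixture restricted to signature peaks.

    Profiles enter VST-normalized.  Because mixing is linear on the
    count scale, both signature and mixture are mapped back through the
    inverse VST (using ``dispersion`` or the signature's recorded VST
    dispersion; skipped when neither is known) before solving.  They
    are then z-scored — the signature by its global mean/SD, the
    mixture by its own, making the result invariant to positive
    rescaling of the underlying mixture counts.  ``nnls`` solves
    non-negative least squares with a free intercept; ``nusvr`` fits
    linear nu-SVR over nu in {0.25, 0.5, 0.75}, clips negative
    coefficients and keeps the lowest-RMSE fit.  Fractions are
    renormalized to sum to one.
    """
    m = mixture_profile.reindex(sig.peaks)
    if m.isna().any():
        raise ValueError("mixture profile missing signature peaks")
    m = m.to_numpy(dtype=float)
    if np.allclose(m, 0):
        raise ValueError("all-zero mixture profile")
    S = sig.values.to_numpy(dtype=float)
    if dispersion is None:
        dispersion = sig.vst_dispersion
    if dispersion is not None:
        from thymoatlas.counts_norm import inverse_vst

        S = inverse_vst(S, dispersion)
        m = inverse_vst(m, dispersion)
    S_z = (S - S.mean()) / S.std()
    m_sd = m.std()
    if m_sd == 0:
        raise ValueError("constant mixture profile")
    m_z = (m - m.mean()) / m_sd

    def _fit_quality(w: np.ndarray, intercept: float = 0.0) -> tuple[float, float]:
        recon = S_z @ w + intercept
        corr = float(pearsonr(recon, m_z)[0]) if recon.std() > 0 else 0.0
        rmse = float(np.sqrt(np.mean((recon - m_z) ** 2)))
        return corr, rmse

    intercept = 0.0
    if method == "nnls":
        ones = np.ones((S_z.shape[0], 1))
        aug = np.hstack([S_z, ones, -ones])  # +/- columns give a free-sign intercept
        w_aug, _ = nnls(aug, m_z)
        w = w_aug[: S_z.shape[1]]
        intercept = float(w_aug[-2] - w_aug[-1])
    elif method == "nusvr":
        from sklearn.svm import NuSVR

        best, best_rmse = None, np.inf
        for nu in (0.25, 0.5, 0.75):
            svr = NuSVR(nu=nu, C=1.0, kernel="linear")
            svr.fit(S_z, m_z)
            w_nu = np.maximum(svr.coef_.ravel(), 0.0)
            if w_nu.sum() == 0:
                continue
            _, rmse = _fit_quality(w_nu, float(np.ravel(svr.intercept_)[0]))
            if rmse < best_rmse:
                best, best_rmse = (w_nu, float(np.ravel(svr.intercept_)[0])), rmse
        if best is None:
            raise ValueError("nu-SVR produced no non-negative solution")
        w, intercept = best
    else:
        raise ValueError(f"unknown method {method!r}")
    corr, rmse = _fit_quality(w, intercept)
    total = w.sum()
    if total == 0:
        fractions = np.full(len(w), 1.0 / len(w))
    else:
        fractions = w / total
    return DeconvolutionResult(
        fractions=pd.Series(fractions, index=sig.groups, name="fraction"),
        correlation=corr,
        rmse=rmse,
    )


def cohens_kappa(confusion: pd.DataFrame | np.ndarray) -> float:
    """Chance-corrected agreement of a square confusion matrix."""
    arr = np.asarray(confusion, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (arr < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("confusion matrix total must be > 0")
    p_o = np.trace(arr) / total
    p_e = float((arr.sum(axis=1) / total) @ (arr.sum(axis=0) / total))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def loo_cross_validate(
    counts: CountMatrix,
    labels: pd.Series | None = None,
    n_base: int = 100,
    cfg: SignatureConfig | None = None,
) -> CVReport:
    """Leave-one-out cross-validation of stage assignment by deconvolution.

    For every sample, a signature is rebuilt from the remaining samples
    on the fixed joined peak set (normalization reference and group
    means exclude the held-out column), the sample is deconvoluted, and
    the fold passes iff the dominant fraction matches its merged group.
    Dominant-fraction ties break by group (column) order.
    """
    cfg = cfg or SignatureConfig()
    if labels is None:
        labels = merge_labels(counts.metadata["stage"], cfg.merge_map)
    else:
        labels = pd.Series(labels).reindex(counts.samples)
    group_order = list(pd.unique(labels))
    records = []
    for held_out in counts.samples:
        train_ids = [s for s in counts.samples if s != held_out]
        train_labels = labels.loc[train_ids]
        if (train_labels.value_counts() < 2).any():
            warnings.warn(f"fold {held_out}: a group dropped below 2 samples; skipped")
            continue
        train = counts.subset_samples(train_ids)
        ref = geometric_reference(train.counts)
        factors = size_factors(train.counts, reference=ref)
        norm = train.counts / factors
        alpha = moment_dispersion(norm)
        vst_train = vst(norm, alpha)
        diff = one_vs_all(train, train_labels, DifferentialConfig(fdr=cfg.fdr))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig = build_signature(diff, vst_train, train_labels, n_base, vst_dispersion=alpha)
        held_factor = size_factors(
            counts.counts[[held_out]], reference=ref
        ).iloc[0]
        held_profile = vst(counts.counts[held_out] / held_factor, alpha)
        result = deconvolve(sig, held_profile)
        # ties resolve to the earlier group in column order
        predicted = result.fractions.index[int(np.argmax(result.fractions.to_numpy()))]
        records.append(
            {
                "sample": held_out,
                "true": labels.loc[held_out],
                "predicted": predicted,
                "passed": predicted == labels.loc[held_out],
            }
        )
    per_sample = pd.DataFrame(records).set_index("sample")
    confusion = pd.DataFrame(
        0, index=group_order, columns=group_order, dtype=int
    )
    for _, row in per_sample.iterrows():
        confusion.loc[row["true"], row["predicted"]] += 1
    rate = float(per_sample["passed"].mean())
    return CVReport(
        per_sample=per_sample,
        correct_rate=rate,
        confusion=confusion,
        cohens_kappa=cohens_kappa(confusion),
    )
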