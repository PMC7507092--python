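"""Negative-binomial differential testing for counts.

A deliberately simple DESeq2-style test: median-of-ratios size factors,
method-of-moments dispersion shrunk toward a mean-dispersion trend, a
per-feature NB GLM with log link fitted by IRLS (vectorized across
features), and a Wald test that supports a fold-change threshold null
(``lfc_null > 0`` tests ``|log2FC| > lfc_null`` rather than filtering
post hoc).  No Cox-Reid adjustment, outlier handling, or independent
filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from thymoatlas.counts_norm import CountMatrix, normalize, size_factors

LN2 = np.log(2.0)
_MAX_BETA = 30.0  # natural-log scale bound; keeps all-zero groups finite
_MU_FLOOR = 0.5  # fitted group means floored at half a normalized count so a
# group with all-zero counts stays identifiable with a finite standard error


@dataclass
class DifferentialConfig:
    """Thresholds of a differential contrast.

    ``lfc_null`` is the threshold null on the log2 scale (0 tests
    against no change); ``fdr`` the BH significance level;
    ``min_mean_count`` drops low-count features before testing.
    """

    lfc_null: float = 0.0
    fdr: float = 0.05
    min_mean_count: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if self.min_mean_count < 0 or self.lfc_null < 0:
            raise ValueError("min_mean_count and lfc_null must be >= 0")


def adjust_pvalues(p_values, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg or Bonferroni adjustment."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}; use 'BH' or 'bonferroni'")
    return multipletests(arr, method=key)[1]


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: Sequence[str],
    norm: bool = True,
) -> pd.Series:
    """Per-feature NB dispersion, method of moments shrunk toward a trend.

    The raw estimate is ``max(0, (pooled within-group variance - mean) /
    mean^2)`` on size-factor-normalized counts; it is then averaged
    50/50 with a fitted ``a0 + a1/mu`` mean-dispersion trend.  Features
    with zero observed variance keep dispersion 0.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    groups = pd.Series(list(groups), index=mat.columns)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(
            f"groups {small} have a single sample; dispersion is not estimable — "
            "pass a fixed dispersion instead"
        )
    data = normalize(mat) if norm else mat.astype(float)
    arr = data.to_numpy()
    mean = arr.mean(axis=1)
    # pooled within-group variance
    ss = np.zeros(arr.shape[0])
    dof = 0
    for g in sizes.index:
        sub = arr[:, (groups == g).to_numpy()]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    var = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    raw = np.maximum(raw, 0.0)
    # trend alpha(mu) = a0 + a1/mu on informative features
    ok = (mean > 0) & (raw > 0)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        coef = np.maximum(coef, 0.0)
    else:
        coef = np.array([float(np.median(raw[ok])) if ok.any() else 0.0, 0.0])
    with np.errstate(divide="ignore"):
        trend = np.where(mean > 0, coef[0] + coef[1] / mean, 0.0)
    alpha = 0.5 * raw + 0.5 * trend
    alpha[var == 0] = 0.0
    alpha = np.maximum(alpha, 0.0)
    return pd.Series(alpha, index=mat.index, name="dispersion")


def _fit_log_mean(
    y: np.ndarray,
    sf: np.ndarray,
    alpha: np.ndarray,
    n_iter: int = 50,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """NB ML fit of the log group mean per feature (log link, known alpha).

    Newton iterations on ``b`` in ``y_fj ~ NB(sf_j * exp(b_f), alpha_f)``;
    fitted means are floored at ``_MU_FLOOR`` so all-zero groups remain
    identifiable with finite information.  Returns (b, fisher_info).
    """
    alpha = alpha[:, None]
    log_floor = np.log(_MU_FLOOR)
    b = np.log(np.maximum((y / sf[None, :]).mean(axis=1), _MU_FLOOR))
    for _ in range(n_iter):
        mu = np.exp(np.clip(b[:, None] + np.log(sf)[None, :], -50, 50))
        score = ((y - mu) / (1.0 + alpha * mu)).sum(axis=1)
        info = (mu / (1.0 + alpha * mu)).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        b_new = np.clip(b + step, log_floor, _MAX_BETA)
        shift = np.max(np.abs(b_new - b)) if len(b) else 0.0
        b = b_new
        if shift < tol:
            break
    mu = np.exp(np.clip(b[:, None] + np.log(sf)[None, :], -50, 50))
    info = (mu / (1.0 + alpha * mu)).sum(axis=1)
    return b, info


def _irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group NB GLM fit; the MLE decouples into per-group means.

    Returns (b0, b1, se1) on the natural-log scale, where ``b0`` is the
    log mean of group B and ``b1`` the log fold change of A over B with
    Wald standard error ``sqrt(1/I_A + 1/I_B)``.
    """
    sf = np.exp(log_sf)
    in_a = x == 1.0
    ba, info_a = _fit_log_mean(y[:, in_a], sf[in_a], alpha)
    bb, info_b = _fit_log_mean(y[:, ~in_a], sf[~in_a], alpha)
    se1 = np.sqrt(1.0 / np.maximum(info_a, 1e-12) + 1.0 / np.maximum(info_b, 1e-12))
    return bb, ba - bb, se1


def nb_wald_test(
    counts: CountMatrix | pd.DataFrame,
    contrast: tuple[Sequence[str], Sequence[str]],
    cfg: DifferentialConfig | None = None,
    dispersions: pd.Series | float | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of group A vs group B on NB GLM fits (log2FC of A over B).

    ``contrast`` gives the sample ids of the two groups.  With
    ``cfg.lfc_null > 0`` the statistic is ``(|lfc| - lfc_null)/SE``
    against a standard normal (threshold null); otherwise ``lfc/SE``.
    Returns a DataFrame with baseMean, log2FoldChange, lfcSE, stat,
    pvalue, padj and a ``significant`` flag; all-zero features are
    dropped and listed in ``result.attrs['skipped']``.
    """
    cfg = cfg or DifferentialConfig()
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    ids_a, ids_b = list(contrast[0]), list(contrast[1])
    missing = [s for s in ids_a + ids_b if s not in mat.columns]
    if missing:
        raise KeyError(f"unknown sample ids {missing!r}")
    sub = mat[ids_a + ids_b].astype(float)
    if factors is None:
        factors = size_factors(sub, pseudo_reference=True)
    else:
        factors = factors.loc[ids_a + ids_b]
    norm = sub / factors
    base_mean = norm.mean(axis=1)
    keep = base_mean >= cfg.min_mean_count
    keep &= sub.sum(axis=1) > 0
    skipped = list(sub.index[~keep])
    sub = sub.loc[keep]
    base_mean = base_mean.loc[keep]
    if dispersions is None:
        labels = ["A"] * len(ids_a) + ["B"] * len(ids_b)
        if min(len(ids_a), len(ids_b)) >= 2:
            disp = estimate_dispersion(sub, labels).to_numpy()
        else:
            raise ValueError(
                "a contrast group has a single sample; supply dispersions "
                "estimated from a reference cohort"
            )
    elif np.isscalar(dispersions):
        disp = np.full(len(sub), float(dispersions))
    else:
        disp = dispersions.reindex(sub.index).fillna(0.0).to_numpy()
    x = np.array([1.0] * len(ids_a) + [0.0] * len(ids_b))
    log_sf = np.log(factors.to_numpy())
    b0, b1, se1 = _irls_two_group(sub.to_numpy(), x, log_sf, disp)
    lfc = b1 / LN2
    se = se1 / LN2
    se = np.where(se > 0, se, np.inf)
    if cfg.lfc_null > 0:
        stat = (np.abs(lfc) - cfg.lfc_null) / se
        pval = np.minimum(1.0, 2.0 * stats.norm.sf(stat))
    else:
        stat = lfc / se
        pval = 2.0 * stats.norm.sf(np.abs(stat))
    padj = adjust_pvalues(pval, "BH")
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
        },
        index=sub.index,
    )
    out["significant"] = (out["padj"] < cfg.fdr) & (np.abs(out["log2FoldChange"]) > cfg.lfc_null)
    out.attrs["skipped"] = skipped
    return out


def one_vs_all(
    counts: CountMatrix,
    stage_labels: Mapping[str, str] | pd.Series | None = None,
    cfg: DifferentialConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """One-versus-all contrasts: each stage against all other samples pooled."""
    cfg = cfg or DifferentialConfig(fdr=0.3)
    if stage_labels is None:
        labels = counts.metadata["stage"]
    else:
        labels = pd.Series(stage_labels).reindex(counts.samples)
    stages = labels.unique()
    if len(stages) < 2:
        raise ValueError("need >= 2 stages")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"stages with < 2 samples: {sizes[sizes < 2].index.tolist()}")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    factors = size_factors(mat, pseudo_reference=True)
    dispersions = estimate_dispersion(mat, labels)
    results = {}
    for stage in stages:
        ids_a = list(labels.index[labels == stage])
        ids_b = list(labels.index[labels != stage])
        results[stage] = nb_wald_test(
            mat, (ids_a, ids_b), cfg, dispersions=dispersions, factors=factors
        )
    return results
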