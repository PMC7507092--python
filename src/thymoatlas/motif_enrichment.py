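"""Footprint-aware TF-motif enrichment across developmental groups.

Motif occurrences are retained only when they fall inside a TF
footprint with score above a cutoff; near-identical motifs (shared
locations above a containment threshold) collapse to one
representative; per (motif, group) a 2x2 contingency table (this motif
vs all others, this group vs all others) is scored by a two-sided
Fisher exact test with Bonferroni and BH adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from thymoatlas.differential import adjust_pvalues
from thymoatlas.peak_atlas import PeakSet, merge_peaks, _overlap_flags


@dataclass
class MotifConfig:
    """Filters of the motif-enrichment pipeline (all boundaries strict)."""

    footprint_score_min: float = 25.0
    redundancy_share: float = 0.9
    fpkm_min: float = 0.5
    sd_count_min: float = 10.0
    top_k: int = 50

    def __post_init__(self) -> None:
        for name in ("footprint_score_min", "redundancy_share", "fpkm_min", "sd_count_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.top_k <= 0:
            raise ValueError("top_k must be > 0")


def filter_expressed_tfs(
    tf_list: Sequence[str],
    fpkm_table: pd.Series | Mapping[str, float],
    cfg: MotifConfig | None = None,
) -> list[str]:
    """Keep TFs expressed above the FPKM cutoff (strictly greater)."""
    cfg = cfg or MotifConfig()
    fpkm = pd.Series(fpkm_table)
    kept = []
    for tf in tf_list:
        if tf not in fpkm.index:
            warnings.warn(f"TF {tf} has no FPKM value; dropped", stacklevel=2)
            continue
        if fpkm[tf] > cfg.fpkm_min:
            kept.append(tf)
    if not kept:
        raise ValueError("no TF passes the expression filter")
    return kept


def intersect_footprints(
    occurrences: pd.DataFrame,
    footprints: pd.DataFrame,
    cfg: MotifConfig | None = None,
) -> pd.DataFrame:
    """Keep occurrences overlapping (>= 1 bp) a footprint scoring above the cutoff."""
    cfg = cfg or MotifConfig()
    strong = footprints[footprints["score"] > cfg.footprint_score_min]
    if strong.empty or occurrences.empty:
        return occurrences.iloc[0:0]
    fp = merge_peaks([PeakSet(strong[["chrom", "start", "end"]].assign(name="fp"))])
    fp_by_chrom = dict(tuple(fp.df.groupby("chrom", sort=False)))
    keep = np.zeros(len(occurrences), dtype=bool)
    pos = {c: i for i, c in enumerate(occurrences.index)}
    for chrom, sub in occurrences.groupby("chrom", sort=False):
        fsub = fp_by_chrom.get(chrom)
        if fsub is None:
            continue
        flags = _overlap_flags(
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            fsub["start"].to_numpy(),
            fsub["end"].to_numpy(),
        )
        keep[[pos[i] for i in sub.index]] = flags
    return occurrences[keep]


def redundancy_filter(
    location_sets: Mapping[str, Iterable],
    cfg: MotifConfig | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Collapse motifs sharing more than the cutoff fraction of locations.

    Sharing is the containment coefficient (shared / smaller set).
    Connected groups keep the motif with the most locations (ties keep
    the lexicographically earlier id); the rest map to the survivor.
    """
    cfg = cfg or MotifConfig()
    sets = {m: set(v) for m, v in location_sets.items()}
    motifs = sorted(sets)
    parent = {m: m for m in motifs}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for a, b in itertools.combinations(motifs, 2):
        small = min(len(sets[a]), len(sets[b]))
        if small == 0:
            continue
        share = len(sets[a] & sets[b]) / small
        if share > cfg.redundancy_share:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    components: dict[str, list[str]] = {}
    for m in motifs:
        components.setdefault(find(m), []).append(m)
    retained, dropped = [], {}
    for members in components.values():
        rep = min(members, key=lambda m: (-len(sets[m]), m))
        retained.append(rep)
        for m in members:
            if m != rep:
                dropped[m] = rep
    return sorted(retained), dropped


def build_motif_count_matrix(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Motifs x groups occurrence counts (summed per group)."""
    table = occurrences.groupby(["motif", "group"]).size().unstack(fill_value=0)
    table.columns.name = None
    table.index.name = None
    return table


def _contingency(counts: pd.DataFrame, motif: str, group: str) -> tuple[int, int, int, int]:
    a = int(counts.loc[motif, group])
    b = int(counts.loc[motif].sum() - a)
    c = int(counts[group].sum() - a)
    d = int(counts.to_numpy().sum() - a - b - c)
    return a, b, c, d


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p of one 2x2 table (minimum-likelihood criterion)."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be >= 0")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(counts: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact test for every (motif, group) pair.

    The contingency compares a motif's occurrences in one group against
    all other motifs and all other groups.  The sample odds ratio is
    ``ad/bc``; 0.5 is added to every cell only when a cell is zero and
    only for the OR.  Bonferroni and BH adjust across all pairs.
    """
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need >= 2 motifs and >= 2 groups")
    if counts.to_numpy().sum() <= 0:
        raise ValueError("zero grand total")
    rows = []
    for motif in counts.index:
        for group in counts.columns:
            a, b, c, d = _contingency(counts, motif, group)
            p = fisher_test(a, b, c, d)
            odds = _odds_ratio(a, b, c, d)
            rows.append(
                {
                    "motif": motif,
                    "group": group,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "ln_odds_ratio": float(np.log(odds)),
                    "pvalue": float(p),
                }
            )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = adjust_pvalues(out["pvalue"], "bonferroni")
    out["p_fdr"] = adjust_pvalues(out["pvalue"], "BH")
    return out


def select_top_tfs(
    results: pd.DataFrame,
    counts: pd.DataFrame,
    cfg: MotifConfig | None = None,
) -> pd.DataFrame:
    """Rank significant motifs by the spread of their odds ratios.

    Motifs with count SD across groups below the cutoff are excluded;
    among motifs significant (BH-adjusted p < 0.05) in any group, the
    ``top_k`` with the highest SD of odds ratios are returned.
    """
    cfg = cfg or MotifConfig()
    count_sd = counts.std(axis=1, ddof=1)
    eligible = count_sd[count_sd >= cfg.sd_count_min].index
    res = results[results["motif"].isin(eligible)]
    sig = res.groupby("motif")["p_fdr"].min()
    sig_motifs = sig[sig < 0.05].index
    or_sd = (
        res[res["motif"].isin(sig_motifs)]
        .groupby("motif")["odds_ratio"]
        .std(ddof=1)
        .sort_values(ascending=False, kind="mergesort")
    )
    if len(or_sd) < cfg.top_k:
        warnings.warn(
            f"only {len(or_sd)} significant motifs (< top_k={cfg.top_k})", stacklevel=2
        )
    table = or_sd.iloc[: cfg.top_k].rename("or_sd").reset_index()
    table.columns = ["motif", "or_sd"]
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def leukemia_contrast(
    m_healthy: pd.DataFrame | pd.Series,
    m_leukemia: pd.DataFrame | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Motif enrichment/depletion of leukemia columns against a healthy pool.

    ``m_healthy`` columns are pooled; each leukemia column (or the
    single pooled column) is contrasted separately, giving per-motif
    odds ratios, two-sided Fisher p-values, BH adjustment, and a call
    in {enriched, depleted, ns}.
    """
    healthy = m_healthy.sum(axis=1) if isinstance(m_healthy, pd.DataFrame) else m_healthy
    leuk = m_leukemia.to_frame() if isinstance(m_leukemia, pd.Series) else m_leukemia
    if not healthy.index.equals(leuk.index):
        raise ValueError("motif universe mismatch between cohorts")
    frames = []
    for col in leuk.columns:
        counts = pd.DataFrame({"leukemia": leuk[col], "healthy": healthy})
        res = fisher_enrichment(counts)
        res = res[res["group"] == "leukemia"].drop(columns="group")
        res.insert(1, "contrast", col)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["p_fdr"] = adjust_pvalues(out["pvalue"], "BH")
    out["call"] = "ns"
    sig = out["p_fdr"] < alpha
    out.loc[sig & (out["odds_ratio"] > 1), "call"] = "enriched"
    out.loc[sig & (out["odds_ratio"] < 1), "call"] = "depleted"
    return out
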