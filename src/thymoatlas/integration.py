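"""Per-patient integration of differential accessibility and expression.

Peaks are linked to genes whose TSS lies within a fixed distance;
per-patient differential calls (patient vs the sorted-population ATAC
cohort, patient vs bulk-thymus RNA references) are intersected through
that annotation; every significant (gene, patient) pair is placed in a
sign quadrant — Q1 (RNA up, ATAC up), Q2 (up, down), Q3 (down, down),
Q4 (down, up) — and recurrence across patients is counted once per
gene-patient pair per quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from thymoatlas.counts_norm import CountMatrix
from thymoatlas.differential import DifferentialConfig, estimate_dispersion, nb_wald_test
from thymoatlas.peak_atlas import PeakSet


@dataclass
class IntegrationConfig:
    """Distances, floors and reporting thresholds of the integration step."""

    annotation_distance_bp: int = 10_000
    rna_min_mean_per_patient: float = 5.0
    report_min_frequency: int = 5
    label_min_frequency: int = 12
    lfc_null: float = 0.5
    fdr: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "annotation_distance_bp",
            "rna_min_mean_per_patient",
            "report_min_frequency",
            "label_min_frequency",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def annotate_peaks_to_genes(
    peaks: PeakSet, genome, cfg: IntegrationConfig | None = None
) -> pd.DataFrame:
    """Many-to-many peak/gene links by peak-edge-to-TSS distance.

    Distance is 0 when the peak overlaps the TSS; links require
    distance <= the annotation distance (inclusive).  Returns a
    DataFrame with peak, gene and distance columns.
    """
    cfg = cfg or IntegrationConfig()
    d = cfg.annotation_distance_bp
    rows = []
    tss_by_chrom = dict(tuple(genome.tss_catalog.groupby("chrom")))
    for chrom, start, end, name in zip(
        peaks.df["chrom"], peaks.df["start"], peaks.df["end"], peaks.df["name"]
    ):
        sub = tss_by_chrom.get(chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        # peak covers bases start..end-1
        dist = np.maximum(0, np.maximum(start - pos, pos - (end - 1)))
        hit = dist <= d
        for gene, dd in zip(sub["gene_id"].to_numpy()[hit], dist[hit]):
            rows.append((name, gene, int(dd)))
    return pd.DataFrame(rows, columns=["peak", "gene", "distance"])


def per_patient_differential(
    atac_counts: CountMatrix,
    rna_counts: CountMatrix,
    patient: str,
    references: Mapping[str, Sequence[str]],
    cfg: IntegrationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential ATAC and RNA calls for one patient against references.

    ``references`` maps ``"atac"``/``"rna"`` to reference sample ids.
    Biological replicates of the patient (samples whose metadata
    ``patient`` or ``donor`` column equals the patient id) are averaged
    into a single column.  Dispersions come from the reference cohorts,
    since a single patient cannot inform them.  RNA genes below the
    mean-count floor are excluded.
    """
    cfg = cfg or IntegrationConfig()
    results = []
    for assay, counts, min_mean in (
        ("atac", atac_counts, 0.0),
        ("rna", rna_counts, cfg.rna_min_mean_per_patient),
    ):
        ref_ids = list(references[assay])
        key = "patient" if "patient" in counts.metadata.columns else "donor"
        reps = [s for s in counts.samples if counts.metadata.loc[s, key] == patient]
        if not reps:
            raise KeyError(f"patient {patient!r} absent from {assay} matrix")
        mat = counts.counts
        patient_col = mat[reps].mean(axis=1).round().astype(int)
        work = mat[ref_ids].copy()
        work[patient] = patient_col
        # dispersion from the reference cohort, pooled within its stages
        ref_meta = counts.metadata.loc[ref_ids]
        stage_sizes = ref_meta["stage"].value_counts()
        if "stage" in ref_meta.columns and (stage_sizes >= 2).all():
            ref_groups = list(ref_meta["stage"])
        else:
            ref_groups = ["ref"] * len(ref_ids)
        disp = estimate_dispersion(mat[ref_ids], ref_groups)
        res = nb_wald_test(
            work,
            ([patient], ref_ids),
            DifferentialConfig(lfc_null=cfg.lfc_null, fdr=cfg.fdr, min_mean_count=min_mean),
            dispersions=disp,
        )
        res.attrs["n_replicates"] = len(reps)
        results.append(res)
    return results[0], results[1]


def quadrant_assign(lfc_rna: float, lfc_atac: float) -> str:
    """Sign quadrant of a (RNA, ATAC) log2 fold-change pair."""
    if lfc_rna == 0 or lfc_atac == 0:
        raise ValueError("zero log fold change cannot arise from a significant call")
    if lfc_rna > 0:
        return "Q1" if lfc_atac > 0 else "Q2"
    return "Q3" if lfc_atac < 0 else "Q4"


def intersect_patient_calls(
    atac_result: pd.DataFrame,
    rna_result: pd.DataFrame,
    annotation: pd.DataFrame,
    patient: str,
) -> pd.DataFrame:
    """Quadrant records for one patient: significant gene/peak pairs joined
    through the peak-gene annotation."""
    sig_peaks = atac_result[atac_result["significant"]]
    sig_genes = rna_result[rna_result["significant"]]
    ann = annotation[
        annotation["peak"].isin(sig_peaks.index) & annotation["gene"].isin(sig_genes.index)
    ]
    rows = []
    for gene, sub in ann.groupby("gene"):
        lfc_rna = float(sig_genes.loc[gene, "log2FoldChange"])
        for quadrant, peaks in _split_by_quadrant(sub, sig_peaks, lfc_rna):
            lfc_atac = float(sig_peaks.loc[peaks, "log2FoldChange"].mean())
            rows.append(
                {
                    "gene": gene,
                    "patient": patient,
                    "quadrant": quadrant,
                    "lfc_rna": lfc_rna,
                    "lfc_atac": lfc_atac,
                    "peaks": ",".join(peaks),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "patient", "quadrant", "lfc_rna", "lfc_atac", "peaks"])


def _split_by_quadrant(ann_sub: pd.DataFrame, sig_peaks: pd.DataFrame, lfc_rna: float):
    """A gene supported by peaks of both ATAC signs lands in both quadrants."""
    peaks = ann_sub["peak"].unique()
    lfc_atac = sig_peaks.loc[peaks, "log2FoldChange"]
    for sign in (1, -1):
        chosen = [p for p in peaks if np.sign(lfc_atac[p]) == sign]
        if chosen:
            yield quadrant_assign(lfc_rna, float(sign)), chosen


def recurrence_table(
    records: pd.DataFrame, cfg: IntegrationConfig | None = None
) -> pd.DataFrame:
    """Gene x quadrant recurrence: distinct patients per (gene, quadrant).

    A gene-patient pair counts once per quadrant regardless of how many
    peaks support it.  Mean LFC values per gene per quadrant are kept
    for plotting; genes reaching the reporting/labeling frequency are
    flagged.
    """
    cfg = cfg or IntegrationConfig()
    if records.empty:
        return pd.DataFrame(
            columns=["gene", "quadrant", "frequency", "mean_lfc_rna", "mean_lfc_atac", "reported", "labeled"]
        )
    dedup = records.drop_duplicates(subset=["gene", "patient", "quadrant"])
    grouped = dedup.groupby(["gene", "quadrant"])
    out = grouped.agg(
        frequency=("patient", "nunique"),
        mean_lfc_rna=("lfc_rna", "mean"),
        mean_lfc_atac=("lfc_atac", "mean"),
    ).reset_index()
    max_freq = out.groupby("gene")["frequency"].transform("max")
    out["reported"] = max_freq >= cfg.report_min_frequency
    out["labeled"] = max_freq >= cfg.label_min_frequency
    return out
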