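"""Integrate per-patient differential accessibility and expression.

For each leukemia patient, contrasts ATAC counts against the sorted
thymocyte cohort and RNA counts against bulk-thymus references
(LFC threshold 0.5, FDR 0.05, RNA mean-count floor 5), links
significant peaks to genes within 10 kb of a TSS, places every
significant (gene, patient) pair in a sign quadrant, and counts
recurrence across patients — recovering the generator's designated
DAB1-style (up/up) and CDKN2A-style (down/down) genes.

Usage: python analysis/05_integration.py [--seed 1] [--outdir results]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from thymoatlas import integration as ig
from thymoatlas import peak_atlas as pa
from thymoatlas.synthetic_data import (
    combined_count_matrix,
    default_cohort_config,
    simulate_cohort,
)

warnings.filterwarnings("ignore")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(default_cohort_config(), seed=args.seed)
    atac = combined_count_matrix(cohort.thymus_counts, cohort.leukemia_counts)
    all_peaks = pa.PeakSet(
        pd.concat(
            [cohort.stage_truth.peak_catalog.df, cohort.mixture_truth.leukemia_specific_peaks.df],
            ignore_index=True,
        )
    )
    annotation = ig.annotate_peaks_to_genes(all_peaks, cohort.genome)
    annotation.to_csv(args.outdir / "peak_gene_annotation.tsv", sep="\t", index=False)
    print(f"peak-gene links within 10 kb: {len(annotation)}")

    refs = {
        "atac": list(cohort.thymus_counts.samples),
        "rna": [
            s
            for s in cohort.rna_counts.samples
            if cohort.rna_counts.metadata.loc[s, "cohort"] == "thymus_bulk"
        ],
    }
    patients = list(cohort.mixture_truth.weights.index)
    records = []
    for patient in patients:
        res_atac, res_rna = ig.per_patient_differential(atac, cohort.rna_counts, patient, refs)
        records.append(ig.intersect_patient_calls(res_atac, res_rna, annotation, patient))
    records = pd.concat(records, ignore_index=True)
    records.to_csv(args.outdir / "quadrant_records.tsv", sep="\t", index=False)

    table = ig.recurrence_table(records)
    table.to_csv(args.outdir / "recurrence_table.tsv", sep="\t", index=False)
    print("\nrecurrently dysregulated genes (distinct patients per quadrant):")
    print(table.sort_values("frequency", ascending=False).head(10).to_string(index=False))

    truth = cohort.rna_truth
    for quadrant in ("Q1", "Q3"):
        genes = truth[truth.quadrant == quadrant]["gene"].unique()
        for gene in genes:
            designated = truth[(truth.gene == gene) & (truth.quadrant == quadrant)]
            hit = table[(table.gene == gene) & (table.quadrant == quadrant)]
            found = int(hit["frequency"].iloc[0]) if len(hit) else 0
            print(f"{gene} designated {quadrant} in {designated.patient.nunique()} patients; "
                  f"recovered in {found} ({found / len(patients):.0%})")


if __name__ == "__main__":
    main()
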