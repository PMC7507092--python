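"""Synthetic thymocyte / leukemia cohorts with stored ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, with every quantity of interest recorded as truth:

* seven sorted thymocyte stages (DN2 .. SPCD8) of negative-binomial
  peak counts whose accessible-peak totals shrink monotonically along
  maturation (progressive chromatin condensation);
* per-peak accessibility patterns drawn to a configured steady /
  decreasing / fluctuating / increasing mix, each realized by a stage-
  mean profile that is unambiguous under the pattern rules;
* leukemia samples built as known convex mixtures of stage profiles
  plus leukemia-specific peaks absent from every healthy stage;
* motif occurrences and scored footprints with designated per-group
  odds enrichment, a constructed redundant motif pair, and a fraction
  of occurrences left uncovered by strong footprints;
* bulk-reference and per-patient RNA counts with designated
  dysregulated (gene, patient, quadrant) pairs coupled to nearby peaks.

All randomness flows from one integer seed: each operation consumes an
explicit seed, and :func:`simulate_cohort` derives per-step seeds from
its seed via ``numpy.random.SeedSequence``.

Distributions are configuration, not claims about any real dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from thymoatlas.counts_norm import CountMatrix, STAGE_ORDER
from thymoatlas.peak_atlas import PeakSet, write_bed

MERGED_GROUPS = ("DN2", "DN3.ISP", "DP", "SPCD4", "SPCD8")
ACCESSIBILITY_FLOOR = 10.0


# ---------------------------------------------------------------------------
# genome model


@dataclass
class GenomeConfig:
    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 15_000_000), ("chr2", 15_000_000))
    genes_per_chromosome: int = 200
    min_tss_spacing: int = 5_000
    seed: int = 0


@dataclass
class GenomeModel:
    """Chromosome sizes plus a TSS catalog (gene_id, chrom, pos, strand)."""

    chromosomes: list[tuple[str, int]]
    tss_catalog: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        lengths = dict(self.chromosomes)
        for _, length in self.chromosomes:
            if length <= 0:
                raise ValueError("zero-length chromosome")
        if self.tss_catalog["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        for chrom, sub in self.tss_catalog.groupby("chrom"):
            if (sub["pos"] >= lengths[chrom]).any():
                raise ValueError(f"TSS beyond the end of {chrom}")

    def gene_ids(self) -> set:
        return set(self.tss_catalog["gene_id"])

    def tss_of(self, gene_id: str) -> tuple[str, int]:
        row = self.tss_catalog[self.tss_catalog["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"gene {gene_id!r} not in genome model")
        return str(row.iloc[0]["chrom"]), int(row.iloc[0]["pos"])


def generate_genome_model(config: GenomeConfig) -> GenomeModel:
    """Place gene TSSs with a guaranteed minimum spacing per chromosome."""
    if config.genes_per_chromosome < 1:
        raise ValueError("need >= 1 gene per chromosome")
    rng = np.random.default_rng(config.seed)
    rows = []
    for chrom, length in config.chromosomes:
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        slots = length // config.genes_per_chromosome
        if slots < config.min_tss_spacing:
            raise ValueError(
                f"{chrom}: {config.genes_per_chromosome} genes with spacing "
                f"{config.min_tss_spacing} exceed chromosome capacity"
            )
        jitter = rng.integers(0, slots - config.min_tss_spacing + 1, config.genes_per_chromosome)
        for i in range(config.genes_per_chromosome):
            rows.append(
                (
                    f"gene_{chrom}_{i:03d}",
                    chrom,
                    int(i * slots + jitter[i]),
                    "+" if rng.random() < 0.5 else "-",
                )
            )
    catalog = pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "strand"])
    return GenomeModel(chromosomes=list(config.chromosomes), tss_catalog=catalog)


# ---------------------------------------------------------------------------
# stage profiles


@dataclass
class StageProfileConfig:
    stage_order: tuple[str, ...] = STAGE_ORDER
    n_peaks: int = 3_000
    donors_per_stage: int = 5
    dispersion: float = 0.1
    pattern_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "steady": 0.59,
            "decreasing": 0.29,
            "fluctuating": 0.117,
            "increasing": 0.003,
        }
    )
    steep_decreasing_fraction: float = 0.5
    peak_width: tuple[int, int] = (200, 800)
    peak_gap: tuple[int, int] = (200, 2_000)
    gene_anchored_peaks: tuple[str, ...] = ()


@dataclass
class StageTruth:
    """Ground truth of the sorted-stage simulation."""

    stage_order: tuple[str, ...]
    peak_catalog: PeakSet
    stage_mean_matrix: pd.DataFrame  # peaks x stages
    pattern_labels: pd.Series
    dispersion: pd.Series

    def __post_init__(self) -> None:
        arr = self.stage_mean_matrix.to_numpy()
        if (arr < 0).any():
            raise ValueError("expected counts must be >= 0")
        if (self.dispersion < 0).any():
            raise ValueError("dispersion must be >= 0")
        accessible = (arr >= ACCESSIBILITY_FLOOR).sum(axis=0)
        if (np.diff(accessible) > 0).any():
            raise ValueError(
                "accessible-peak totals must be non-increasing along maturation"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha) -> np.ndarray:
    """NB(mean, alpha) with var = mean + alpha*mean^2; alpha=0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha_arr == 0
    out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        a = alpha_arr[~pois]
        m = mean[~pois]
        n = 1.0 / a
        p = n / (n + np.maximum(m, 1e-12))
        drawn = np.where(m > 0, rng.negative_binomial(n, p), 0)
        out[~pois] = drawn
    return out


def _place_intervals(
    chromosomes: Sequence[tuple[str, int]],
    n: int,
    width_range: tuple[int, int],
    gap_range: tuple[int, int],
    rng: np.random.Generator,
    reserved: Mapping[str, list[tuple[int, int]]] | None = None,
    cursors: Mapping[str, int] | None = None,
    prefix: str = "peak",
) -> pd.DataFrame:
    """Sequential non-overlapping placement, skipping reserved intervals."""
    reserved = {c: sorted(v) for c, v in (reserved or {}).items()}
    cursors = dict(cursors or {})
    rows = []
    chrom_cycle = list(chromosomes)
    ci = 0
    placed = 0
    exhausted = 0
    while placed < n:
        if exhausted >= len(chrom_cycle):
            raise ValueError("chromosomes too short for the requested peak count")
        chrom, length = chrom_cycle[ci % len(chrom_cycle)]
        cursor = cursors.get(chrom, 0)
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        gap = int(rng.integers(gap_range[0], gap_range[1] + 1))
        start = cursor + gap
        end = start + width
        for rs, re_ in reserved.get(chrom, []):
            if start < re_ and rs < end:  # collision: jump past the reservation
                start = re_ + gap
                end = start + width
        if end > length:
            exhausted += 1
            ci += 1
            continue
        exhausted = 0
        rows.append((chrom, start, end, f"{prefix}_{len(rows):05d}", 0.0))
        cursors[chrom] = end
        placed += 1
        ci += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    df.attrs["cursors"] = cursors
    return df


def _pattern_profile(
    rng: np.random.Generator, pattern: str, n_stages: int, steep_fraction: float
) -> np.ndarray:
    """One stage-mean trajectory, unambiguous under the pattern rules."""
    if pattern == "steady":
        return np.full(n_stages, rng.uniform(12.0, 32.0))
    if pattern == "increasing":
        start, end = rng.uniform(12.0, 22.0), rng.uniform(70.0, 150.0)
        return np.geomspace(start, end, n_stages)
    if pattern == "decreasing":
        if rng.random() < steep_fraction:
            start = rng.uniform(120.0, 260.0)
            tail = np.geomspace(rng.uniform(10.0, 22.0), rng.uniform(2.0, 8.0), n_stages - 1)
            return np.concatenate([[start], tail])
        start, end = rng.uniform(80.0, 220.0), rng.uniform(2.0, 14.0)
        return np.geomspace(start, end, n_stages)
    if pattern == "fluctuating":
        base = rng.uniform(36.0, 48.0)
        profile = np.full(n_stages, base)
        spike_stage = int(rng.integers(1, n_stages))
        profile[spike_stage] = rng.uniform(130.0, 260.0)
        if spike_stage == n_stages - 1:
            profile[spike_stage - 1] = base - 26.0  # dip keeps the profile non-monotone
        return profile
    raise ValueError(f"unknown pattern {pattern!r}")


def generate_stage_profiles(
    genome: GenomeModel,
    config: StageProfileConfig,
    seed: int,
) -> tuple[StageTruth, CountMatrix]:
    """Simulate sorted-stage peak counts with recorded pattern truth."""
    fractions = config.pattern_fractions
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("pattern fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_stages = len(config.stage_order)
    reserved: dict[str, list[tuple[int, int]]] = {}
    anchor_rows = []
    for gene in config.gene_anchored_peaks:
        chrom, pos = genome.tss_of(gene)
        start = max(0, pos - 250)
        anchor_rows.append((chrom, start, start + 500, f"peak_anchor_{gene}", 0.0))
        reserved.setdefault(chrom, []).append((start, start + 500))
    peaks_df = _place_intervals(
        genome.chromosomes,
        config.n_peaks,
        config.peak_width,
        config.peak_gap,
        rng,
        reserved=reserved,
    )
    cursors = peaks_df.attrs["cursors"]
    if anchor_rows:
        peaks_df = pd.concat(
            [peaks_df, pd.DataFrame(anchor_rows, columns=peaks_df.columns)],
            ignore_index=True,
        )
    catalog = PeakSet(peaks_df, merged=True)
    names = catalog.names.to_numpy()
    order = {n: i for i, n in enumerate(names)}

    patterns = list(fractions)
    labels = rng.choice(patterns, size=config.n_peaks, p=[fractions[p] for p in patterns])
    labels = np.concatenate([labels, np.array(["steady"] * len(anchor_rows), dtype=object)])
    means = np.zeros((len(names), n_stages))
    placed_names = peaks_df["name"].to_numpy()
    for i, name in enumerate(placed_names):
        if name.startswith("peak_anchor_"):
            means[order[name]] = np.full(n_stages, rng.uniform(100.0, 160.0))
        else:
            means[order[name]] = _pattern_profile(
                rng, labels[i], n_stages, config.steep_decreasing_fraction
            )
    label_series = pd.Series(
        {placed_names[i]: labels[i] for i in range(len(placed_names))}
    ).loc[names]
    mean_df = pd.DataFrame(means, index=names, columns=list(config.stage_order))
    dispersion = pd.Series(config.dispersion, index=names, name="dispersion")
    truth = StageTruth(
        stage_order=tuple(config.stage_order),
        peak_catalog=catalog,
        stage_mean_matrix=mean_df,
        pattern_labels=label_series.rename("pattern"),
        dispersion=dispersion,
    )
    truth.placement_cursors = dict(cursors)

    columns, meta_rows = {}, []
    for stage in config.stage_order:
        mu = mean_df[stage].to_numpy()
        for d in range(1, config.donors_per_stage + 1):
            sid = f"{stage}_d{d}"
            columns[sid] = _nb_draw(rng, mu, config.dispersion)
            meta_rows.append((sid, stage, f"D{d}", "thymus"))
    counts = pd.DataFrame(columns, index=names)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "stage", "donor", "cohort"]
    ).set_index("sample_id")
    return truth, CountMatrix(counts, metadata)


# ---------------------------------------------------------------------------
# leukemia mixtures


@dataclass
class LeukemiaConfig:
    n_patients: int = 19
    dirichlet_concentration: float = 1.0
    n_specific_peaks: int = 500
    dispersion: float = 0.1
    n_replicate_patients: int = 10
    specific_mean_range: tuple[float, float] = (80.0, 250.0)
    # optional fixed weight rows (patients x stages); overrides the Dirichlet draw
    fixed_weights: tuple[tuple[float, ...], ...] | None = None
    # (gene_id, patient ids): a leukemia-specific peak near the gene TSS,
    # accessible only in the listed patients (ATAC-up coupling)
    gene_links_up: tuple[tuple[str, tuple[str, ...]], ...] = ()
    # (gene_id, patient ids): the gene's anchored thymus peak silenced in
    # the listed patients (ATAC-down coupling; CDKN2A-style channel)
    silence_links: tuple[tuple[str, tuple[str, ...]], ...] = ()


@dataclass
class MixtureTruth:
    """Known stage-mixture weights and leukemia-specific peaks."""

    weights: pd.DataFrame  # patients x stages
    leukemia_specific_peaks: PeakSet

    def __post_init__(self) -> None:
        arr = self.weights.to_numpy()
        if (arr < 0).any():
            raise ValueError("mixture weights must be >= 0")
        if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("mixture rows must sum to 1")

    def merged_weights(self, merge_map: Mapping[str, str]) -> pd.DataFrame:
        grouped = self.weights.T.groupby(
            pd.Series(self.weights.columns.map(merge_map), index=self.weights.columns)
        ).sum()
        return grouped.T


def patient_ids(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(1, n + 1)]


def generate_leukemia_samples(
    truth: StageTruth,
    config: LeukemiaConfig,
    seed: int,
    genome: GenomeModel | None = None,
) -> tuple[CountMatrix, MixtureTruth]:
    """Leukemia counts as convex stage mixtures plus leukemia-only peaks."""
    if config.dispersion < 0:
        raise ValueError("noise level (dispersion) must be >= 0")
    if (config.gene_links_up or config.silence_links) and genome is None:
        raise ValueError("gene-linked peaks require the genome model")
    rng = np.random.default_rng(seed)
    patients = patient_ids(config.n_patients)
    stages = list(truth.stage_order)
    if config.fixed_weights is not None:
        weights = np.asarray(config.fixed_weights, dtype=float)
        if weights.shape != (config.n_patients, len(stages)):
            raise ValueError("fixed_weights must be n_patients x n_stages")
    else:
        weights = rng.dirichlet(
            np.full(len(stages), config.dirichlet_concentration), size=config.n_patients
        )
    weights_df = pd.DataFrame(weights, index=patients, columns=stages)

    shared_mean = truth.stage_mean_matrix.to_numpy() @ weights.T  # peaks x patients
    shared_mean = pd.DataFrame(
        shared_mean, index=truth.stage_mean_matrix.index, columns=patients
    )
    for gene, linked in config.silence_links:
        peak_name = f"peak_anchor_{gene}"
        if peak_name not in shared_mean.index:
            raise KeyError(
                f"gene {gene!r} has no anchored peak in the stage catalog"
            )
        unknown = set(linked) - set(patients)
        if unknown:
            raise KeyError(f"unknown patients {sorted(unknown)}")
        shared_mean.loc[peak_name, list(linked)] = 0.0

    # leukemia-specific peaks: random placement beyond the stage catalog,
    # plus one peak near each up-linked gene TSS
    cursors = dict(getattr(truth, "placement_cursors", {}))
    cat_df = truth.peak_catalog.df
    for chrom, sub in cat_df.groupby("chrom"):
        cursors[chrom] = max(cursors.get(chrom, 0), int(sub["end"].max()))
    chrom_sizes = (
        genome.chromosomes
        if genome is not None
        else [(c, int(cursors[c] * 10 + 10_000_000)) for c in cursors]
    )
    spec_df = _place_intervals(
        chrom_sizes,
        config.n_specific_peaks,
        (200, 800),
        (200, 2_000),
        rng,
        cursors=cursors,
        prefix="leukpeak",
    )
    link_rows = []
    occupied = [
        (r.chrom, r.start, r.end)
        for df in (cat_df, spec_df)
        for r in df.itertuples()
    ]
    for gene, linked in config.gene_links_up:
        chrom, pos = genome.tss_of(gene)
        start, width = pos + 1_500, 500
        taken = sorted((s, e) for c, s, e in occupied if c == chrom)
        moved = True
        while moved:
            moved = False
            for s, e in taken:
                if start < e and s < start + width:
                    start = e + 100
                    moved = True
        link_rows.append((chrom, start, start + width, f"leukpeak_link_{gene}", 0.0))
        occupied.append((chrom, start, start + width))
    if link_rows:
        spec_df = pd.concat(
            [spec_df, pd.DataFrame(link_rows, columns=spec_df.columns)], ignore_index=True
        )
    specific = PeakSet(spec_df)

    spec_mean = pd.DataFrame(
        0.0, index=specific.names.to_numpy(), columns=patients
    )
    for name in spec_mean.index:
        level = rng.uniform(*config.specific_mean_range)
        if name.startswith("leukpeak_link_"):
            gene = name[len("leukpeak_link_"):]
            linked = dict(config.gene_links_up)[gene]
            unknown = set(linked) - set(patients)
            if unknown:
                raise KeyError(f"unknown patients {sorted(unknown)}")
            spec_mean.loc[name, list(linked)] = level
        else:
            spec_mean.loc[name] = level
    mean_all = pd.concat([shared_mean, spec_mean])

    columns, meta_rows = {}, []
    for i, patient in enumerate(patients):
        n_reps = 2 if i < config.n_replicate_patients else 1
        for r in range(1, n_reps + 1):
            sid = f"{patient}_r{r}"
            columns[sid] = _nb_draw(rng, mean_all[patient].to_numpy(), config.dispersion)
            meta_rows.append((sid, "T-ALL", patient, "T-ALL"))
    counts = pd.DataFrame(columns, index=mean_all.index)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "stage", "donor", "cohort"]
    ).set_index("sample_id")
    metadata["patient"] = metadata["donor"]
    return (
        CountMatrix(counts, metadata),
        MixtureTruth(weights=weights_df, leukemia_specific_peaks=specific),
    )


def combined_count_matrix(healthy: CountMatrix, leukemia: CountMatrix) -> CountMatrix:
    """Align two cohorts on the union feature set (absent features count 0)."""
    features = healthy.features.union(leukemia.features, sort=False)
    counts = pd.concat(
        [
            healthy.counts.reindex(features, fill_value=0),
            leukemia.counts.reindex(features, fill_value=0),
        ],
        axis=1,
    )
    meta = pd.concat([healthy.metadata, leukemia.metadata])
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------------------
# motifs and footprints


@dataclass
class MotifSimConfig:
    n_motifs: int = 40
    groups: tuple[str, ...] = MERGED_GROUPS
    base_count: float = 300.0
    base_log_sd: float = 0.3
    # motif -> {group: odds multiplier}
    enriched: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_low_variance: int = 3
    low_variance_base: float = 5.0
    redundant_pair: tuple[str, str] | None = ("M_red_a", "M_red_b")
    redundant_share: float = 0.95
    outside_fraction: float = 0.3
    motif_length: int = 10
    footprint_pad: int = 5


@dataclass
class MotifTruth:
    """Designated log-odds, occurrence intervals, scored footprints."""

    log_odds: pd.DataFrame  # motifs x groups, natural log
    occurrences: pd.DataFrame  # chrom,start,end,motif,group
    footprints: pd.DataFrame  # chrom,start,end,score

    def __post_init__(self) -> None:
        if (self.footprints["score"] < 0).any():
            raise ValueError("footprint scores must be >= 0")


def generate_motif_data(
    truth: StageTruth, config: MotifSimConfig, seed: int
) -> MotifTruth:
    """Motif occurrences in peaks with designated per-group enrichment."""
    rng = np.random.default_rng(seed)
    motifs = [f"M{i:03d}" for i in range(1, config.n_motifs + 1)]
    if config.redundant_pair:
        motifs += list(config.redundant_pair)
    groups = list(config.groups)
    unknown = set(config.enriched) - set(motifs)
    if unknown:
        raise ValueError(f"enriched motifs not in the simulated set: {sorted(unknown)}")

    base = np.exp(rng.normal(np.log(config.base_count), config.base_log_sd, len(motifs)))
    base[: config.n_low_variance] = config.low_variance_base
    odds = pd.DataFrame(1.0, index=motifs, columns=groups)
    for motif, per_group in config.enriched.items():
        for group, mult in per_group.items():
            odds.loc[motif, group] = mult

    cat = truth.peak_catalog.df
    peak_idx = np.arange(len(cat))
    widths = (cat["end"] - cat["start"]).to_numpy()

    occ_rows, fp_rows = [], []

    def _emit(motif: str, group: str, n_total: int):
        if n_total == 0:
            return []
        chosen = rng.choice(peak_idx, size=n_total)
        offs = rng.integers(0, np.maximum(widths[chosen] - config.motif_length, 1))
        covered = rng.random(n_total) < (1.0 - config.outside_fraction)
        local = []
        for j in range(n_total):
            row = cat.iloc[chosen[j]]
            s = int(row["start"] + offs[j])
            e = s + config.motif_length
            local.append((row["chrom"], s, e, motif, group))
            if covered[j]:
                fp_rows.append(
                    (
                        row["chrom"],
                        s - config.footprint_pad,
                        e + config.footprint_pad,
                        float(rng.uniform(26.0, 80.0)),
                    )
                )
            elif rng.random() < 0.5:  # weak footprint, below the score cutoff
                fp_rows.append(
                    (
                        row["chrom"],
                        s - config.footprint_pad,
                        e + config.footprint_pad,
                        float(rng.uniform(5.0, 25.0)),
                    )
                )
        occ_rows.extend(local)
        return local

    red_a_rows: list = []
    for i, motif in enumerate(motifs):
        if config.redundant_pair and motif == config.redundant_pair[1]:
            # second member: copy a share of the first member's locations
            n_copy = int(round(config.redundant_share * len(red_a_rows)))
            copied = [
                (c, s, e, motif, g) for (c, s, e, _, g) in red_a_rows[:n_copy]
            ]
            occ_rows.extend(copied)
            # a few extra private locations keep the pair below full identity
            # while leaving the copy the smaller of the two
            _emit(motif, groups[0], max(1, (len(red_a_rows) - n_copy) // 2))
            continue
        for group in groups:
            rate = base[i] * odds.loc[motif, group] / (1.0 - config.outside_fraction)
            emitted = _emit(motif, group, int(rng.poisson(rate)))
            if config.redundant_pair and motif == config.redundant_pair[0]:
                red_a_rows.extend(emitted)

    occurrences = pd.DataFrame(
        occ_rows, columns=["chrom", "start", "end", "motif", "group"]
    )
    footprints = pd.DataFrame(fp_rows, columns=["chrom", "start", "end", "score"])
    footprints["start"] = footprints["start"].clip(lower=0)
    return MotifTruth(
        log_odds=np.log(odds), occurrences=occurrences, footprints=footprints
    )


# ---------------------------------------------------------------------------
# RNA counts coupled to accessibility


@dataclass
class DysregulatedGene:
    gene: str
    patients: tuple[str, ...]
    quadrant: str  # Q1..Q4; Q1/Q2 raise RNA, Q3/Q4 lower it
    fold: float = 16.0


@dataclass
class RnaConfig:
    n_reference: int = 3
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion: float = 0.05
    dysregulation: tuple[DysregulatedGene, ...] = ()
    concordance: float = 1.0  # fraction of designated pairs with ATAC coupling


def generate_rna_counts(
    truth: StageTruth,
    mixture: MixtureTruth,
    config: RnaConfig,
    seed: int,
    genome: GenomeModel,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Bulk-reference and per-patient RNA counts with a dysregulation truth table."""
    rng = np.random.default_rng(seed)
    genes = list(genome.tss_catalog["gene_id"])
    known = set(genes)
    for spec in config.dysregulation:
        if spec.gene not in known:
            raise KeyError(f"gene {spec.gene!r} not in genome model")
        if spec.quadrant not in {"Q1", "Q2", "Q3", "Q4"}:
            raise ValueError(f"bad quadrant {spec.quadrant!r}")
    patients = list(mixture.weights.index)
    base = rng.uniform(*config.base_mean_range, size=len(genes))
    base_s = pd.Series(base, index=genes)

    mean = pd.DataFrame(
        np.tile(base, (len(patients), 1)).T, index=genes, columns=patients
    )
    truth_rows = []
    for spec in config.dysregulation:
        unknown = set(spec.patients) - set(patients)
        if unknown:
            raise KeyError(f"unknown patients {sorted(unknown)}")
        for patient in spec.patients:
            if spec.quadrant in ("Q1", "Q2"):
                mean.loc[spec.gene, patient] = base_s[spec.gene] * spec.fold
            else:
                mean.loc[spec.gene, patient] = base_s[spec.gene] / spec.fold
            coupled = rng.random() < config.concordance
            truth_rows.append(
                {
                    "gene": spec.gene,
                    "patient": patient,
                    "quadrant": spec.quadrant,
                    "atac_coupled": coupled,
                }
            )
    columns, meta_rows = {}, []
    for r in range(1, config.n_reference + 1):
        sid = f"thymus_bulk_{r}"
        columns[sid] = _nb_draw(rng, base, config.dispersion)
        meta_rows.append((sid, "bulk", f"B{r}", "thymus_bulk"))
    for patient in patients:
        columns[patient] = _nb_draw(rng, mean[patient].to_numpy(), config.dispersion)
        meta_rows.append((patient, "T-ALL", patient, "T-ALL"))
    counts = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "stage", "donor", "cohort"]
    ).set_index("sample_id")
    metadata["patient"] = metadata["donor"]
    truth_table = pd.DataFrame(
        truth_rows, columns=["gene", "patient", "quadrant", "atac_coupled"]
    )
    return CountMatrix(counts, metadata), truth_table


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CohortConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    stages: StageProfileConfig = field(default_factory=StageProfileConfig)
    leukemia: LeukemiaConfig = field(default_factory=LeukemiaConfig)
    motifs: MotifSimConfig = field(default_factory=MotifSimConfig)
    rna: RnaConfig = field(default_factory=RnaConfig)


def default_cohort_config() -> CohortConfig:
    """Study-shaped defaults: 7 stages x 5 donors, 19 patients, one gene
    up-dysregulated in 15/19 patients (DAB1-style) and one silenced in 17
    (CDKN2A-style), plus early-group-enriched motifs."""
    p = patient_ids(19)
    dab1_like, cdkn2a_like = "gene_chr1_010", "gene_chr2_010"
    up_patients = tuple(p[:15])
    silenced_patients = tuple(p[:17])
    enriched = {
        "M010": {"DN2": 4.0},
        "M011": {"DN2": 3.0},
        "M012": {"DN3.ISP": 3.0},
        "M013": {"DP": 0.4},
        "M014": {"SPCD4": 2.5},
        "M015": {"SPCD8": 2.5},
    }
    return CohortConfig(
        stages=StageProfileConfig(gene_anchored_peaks=(cdkn2a_like,)),
        leukemia=LeukemiaConfig(
            gene_links_up=((dab1_like, up_patients),),
            silence_links=((cdkn2a_like, silenced_patients),),
        ),
        motifs=MotifSimConfig(enriched=enriched),
        rna=RnaConfig(
            dysregulation=(
                DysregulatedGene(dab1_like, up_patients, "Q1", fold=16.0),
                DysregulatedGene(cdkn2a_like, silenced_patients, "Q3", fold=50.0),
            )
        ),
    )


@dataclass
class SimulatedCohort:
    genome: GenomeModel
    stage_truth: StageTruth
    thymus_counts: CountMatrix
    leukemia_counts: CountMatrix
    mixture_truth: MixtureTruth
    motif_truth: MotifTruth
    rna_counts: CountMatrix
    rna_truth: pd.DataFrame


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Run the whole generator; per-step seeds derive from ``seed``."""
    config = config or default_cohort_config()
    sub = np.random.SeedSequence(seed).generate_state(5) % (2**31)
    genome = generate_genome_model(
        GenomeConfig(**{**asdict(config.genome), "seed": int(sub[0])})
    )
    stage_truth, thymus = generate_stage_profiles(genome, config.stages, int(sub[1]))
    leukemia, mixture = generate_leukemia_samples(
        stage_truth, config.leukemia, int(sub[2]), genome=genome
    )
    motifs = generate_motif_data(stage_truth, config.motifs, int(sub[3]))
    rna, rna_truth = generate_rna_counts(
        stage_truth, mixture, config.rna, int(sub[4]), genome=genome
    )
    return SimulatedCohort(
        genome=genome,
        stage_truth=stage_truth,
        thymus_counts=thymus,
        leukemia_counts=leukemia,
        mixture_truth=mixture,
        motif_truth=motifs,
        rna_counts=rna,
        rna_truth=rna_truth,
    )


def save_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort to plain-text files (BED6, TSV, JSON)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(cohort.stage_truth.peak_catalog, out / "peaks.bed")
    cohort.motif_truth.footprints.assign(name="fp", strand=".").to_csv(
        out / "footprints.bed",
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    cohort.motif_truth.occurrences.assign(score=0, strand=".").to_csv(
        out / "motif_occurrences.bed",
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "motif", "score", "strand"],
    )
    cohort.thymus_counts.to_tsv(out / "thymus_counts.tsv", out / "thymus_metadata.tsv")
    cohort.leukemia_counts.to_tsv(
        out / "leukemia_counts.tsv", out / "leukemia_metadata.tsv"
    )
    cohort.rna_counts.to_tsv(out / "rna_counts.tsv", out / "rna_metadata.tsv")
    cohort.mixture_truth.weights.to_csv(out / "mixture_weights.tsv", sep="\t")
    cohort.stage_truth.pattern_labels.to_csv(out / "pattern_truth.tsv", sep="\t")
    cohort.rna_truth.to_csv(out / "rna_dysregulation_truth.tsv", sep="\t", index=False)
    with open(out / "genome.json", "w") as fh:
        json.dump(
            {
                "chromosomes": cohort.genome.chromosomes,
                "n_genes": int(len(cohort.genome.tss_catalog)),
            },
            fh,
            indent=2,
        )
    cohort.genome.tss_catalog.to_csv(out / "tss_catalog.tsv", sep="\t", index=False)
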