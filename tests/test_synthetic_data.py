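import numpy as np
import pandas as pd
import pytest

from thymoatlas import counts_norm as cn
from thymoatlas import motif_enrichment as me
from thymoatlas import synthetic_data as syn


class TestGenomeModel:
    def test_seed_determinism(self):
        a = syn.generate_genome_model(syn.GenomeConfig(seed=1))
        b = syn.generate_genome_model(syn.GenomeConfig(seed=1))
        assert a.tss_catalog.equals(b.tss_catalog)

    def test_gene_count(self):
        g = syn.generate_genome_model(
            syn.GenomeConfig(chromosomes=(("c1", 10**6), ("c2", 10**6)), genes_per_chromosome=100)
        )
        assert len(g.tss_catalog) == 200

    def test_spacing_respected(self):
        cfg = syn.GenomeConfig(chromosomes=(("c1", 10**6),), genes_per_chromosome=100, min_tss_spacing=5_000)
        g = syn.generate_genome_model(cfg)
        pos = np.sort(g.tss_catalog["pos"].to_numpy())
        assert np.diff(pos).min() >= cfg.min_tss_spacing

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            syn.generate_genome_model(
                syn.GenomeConfig(chromosomes=(("c1", 10_000),), genes_per_chromosome=100)
            )

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            syn.generate_genome_model(syn.GenomeConfig(chromosomes=(("c1", 0),)))


class TestStageProfiles:
    def test_matrix_dimensions(self, small_genome):
        cfg = syn.StageProfileConfig(n_peaks=1_000, donors_per_stage=5)
        _, counts = syn.generate_stage_profiles(small_genome, cfg, seed=2)
        assert counts.counts.shape == (1_000, 35)

    def test_bad_pattern_fractions_rejected(self, small_genome):
        cfg = syn.StageProfileConfig(
            pattern_fractions={"steady": 0.5, "decreasing": 0.2, "fluctuating": 0.2, "increasing": 0.2}
        )
        with pytest.raises(ValueError, match="sum to 1"):
            syn.generate_stage_profiles(small_genome, cfg, seed=0)

    def test_zero_dispersion_counts_are_poisson(self, small_genome):
        # variance ~ mean on a large replicate set
        cfg = syn.StageProfileConfig(n_peaks=300, donors_per_stage=60, dispersion=0.0)
        truth, counts = syn.generate_stage_profiles(small_genome, cfg, seed=3)
        stage = truth.stage_order[0]
        cols = [s for s in counts.samples if s.startswith(stage + "_")]
        sub = counts.counts[cols]
        mean, var = sub.mean(axis=1), sub.var(axis=1, ddof=1)
        ratio = (var / mean.clip(lower=0.5)).median()
        assert 0.8 <= ratio <= 1.25

    def test_pattern_truth_matches_rule_categorizer(self, small_stage_data):
        truth, _ = small_stage_data
        labels = cn.categorize_patterns(truth.stage_mean_matrix)
        assert (labels == truth.pattern_labels).all()

    def test_condensation_is_monotone(self, small_stage_data):
        truth, _ = small_stage_data
        accessible = (truth.stage_mean_matrix >= syn.ACCESSIBILITY_FLOOR).sum(axis=0)
        assert (np.diff(accessible.to_numpy()) <= 0).all()

    def test_accessible_medians_decline_in_counts(self, cohort):
        from thymoatlas import peak_atlas as pa

        medians = []
        for stage in cohort.stage_truth.stage_order:
            ids = [s for s in cohort.thymus_counts.samples if s.startswith(stage + "_")]
            medians.append(
                np.median([pa.count_accessible(cohort.thymus_counts, s) for s in ids])
            )
        assert (np.diff(medians) <= 0).all()

    def test_realized_pattern_mix_near_target(self):
        genome = syn.generate_genome_model(syn.GenomeConfig(seed=5))
        cfg = syn.StageProfileConfig(n_peaks=10_000, donors_per_stage=2)
        truth, _ = syn.generate_stage_profiles(genome, cfg, seed=5)
        mix = truth.pattern_labels.value_counts(normalize=True)
        targets = {"steady": 0.59, "decreasing": 0.29, "fluctuating": 0.117, "increasing": 0.003}
        for label, target in targets.items():
            assert abs(mix.get(label, 0.0) - target) <= 0.02


class TestLeukemiaSamples:
    def test_one_hot_zero_noise_matches_stage_profile(self, small_stage_data):
        truth, _ = small_stage_data
        onehot = tuple(tuple(1.0 if s == "ISP" else 0.0 for s in truth.stage_order) for _ in range(2))
        cfg = syn.LeukemiaConfig(
            n_patients=2, n_specific_peaks=0, dispersion=0.0, n_replicate_patients=0,
            fixed_weights=onehot,
        )
        counts, mixture = syn.generate_leukemia_samples(truth, cfg, seed=6)
        # Poisson draws around exactly the ISP mean profile
        mu = truth.stage_mean_matrix["ISP"]
        obs = counts.counts.mean(axis=1)
        resid = (obs - mu) / np.sqrt(mu.clip(lower=1) / counts.counts.shape[1])
        assert abs(resid.mean()) < 0.5

    def test_weights_rows_on_simplex(self, small_stage_data):
        truth, _ = small_stage_data
        cfg = syn.LeukemiaConfig(n_patients=19, n_specific_peaks=50)
        _, mixture = syn.generate_leukemia_samples(truth, cfg, seed=7)
        assert mixture.weights.shape[0] == 19
        assert np.allclose(mixture.weights.sum(axis=1), 1.0, atol=1e-9)
        assert (mixture.weights.to_numpy() >= 0).all()

    def test_specific_peaks_grow_union_exactly(self, small_stage_data):
        truth, _ = small_stage_data
        cfg = syn.LeukemiaConfig(n_patients=3, n_specific_peaks=800)
        counts, mixture = syn.generate_leukemia_samples(truth, cfg, seed=8)
        assert len(mixture.leukemia_specific_peaks) == 800
        assert len(counts.features) == len(truth.peak_catalog) + 800
        # disjoint from the stage catalog
        stage_ids = set(truth.peak_catalog.names)
        assert not (set(mixture.leukemia_specific_peaks.names) & stage_ids)

    def test_negative_noise_rejected(self, small_stage_data):
        truth, _ = small_stage_data
        with pytest.raises(ValueError, match="noise"):
            syn.generate_leukemia_samples(truth, syn.LeukemiaConfig(dispersion=-1), seed=0)


class TestMotifData:
    def test_null_config_gives_unit_odds_ratios(self, small_stage_data):
        truth, _ = small_stage_data
        cfg = syn.MotifSimConfig(n_motifs=25, enriched={}, redundant_pair=None, n_low_variance=0)
        motifs = syn.generate_motif_data(truth, cfg, seed=9)
        occ = me.intersect_footprints(motifs.occurrences, motifs.footprints)
        res = me.fisher_enrichment(me.build_motif_count_matrix(occ))
        med = res.groupby("motif")["odds_ratio"].apply(lambda s: s.sub(1).abs().max())
        assert 0.8 <= res["odds_ratio"].median() <= 1.25

    def test_designated_enrichment_recovered(self, cohort):
        occ = me.intersect_footprints(cohort.motif_truth.occurrences, cohort.motif_truth.footprints)
        res = me.fisher_enrichment(me.build_motif_count_matrix(occ))
        row = res[(res.motif == "M010") & (res.group == "DN2")].iloc[0]
        assert 2.5 <= row.odds_ratio <= 6.0
        assert row.p_bonferroni < 0.05

    def test_redundant_pair_flagged(self, cohort):
        occ = me.intersect_footprints(cohort.motif_truth.occurrences, cohort.motif_truth.footprints)
        locs = {m: set(zip(sub.chrom, sub.start)) for m, sub in occ.groupby("motif")}
        retained, dropped = me.redundancy_filter(locs)
        assert dropped.get("M_red_b") == "M_red_a"

    def test_occurrences_lie_within_peaks(self, cohort):
        occ = cohort.motif_truth.occurrences
        cat = cohort.stage_truth.peak_catalog.df
        for chrom, sub in occ.groupby("chrom"):
            peaks = cat[cat.chrom == chrom].sort_values("start")
            starts = peaks["start"].to_numpy()
            ends = peaks["end"].to_numpy()
            # catalog peaks are disjoint: the covering peak is the last one
            # starting at or before the occurrence
            j = np.searchsorted(starts, sub["start"].to_numpy(), side="right") - 1
            assert (j >= 0).all()
            assert (sub["end"].to_numpy() <= ends[j]).all()


class TestRnaCounts:
    def test_reference_sample_count(self, cohort):
        refs = cohort.rna_counts.metadata.query("cohort == 'thymus_bulk'")
        assert len(refs) == 3

    def test_truth_table_records_designated_recurrence(self, cohort):
        truth = cohort.rna_truth
        q1 = truth[truth.quadrant == "Q1"]
        assert q1.groupby("gene")["patient"].nunique().max() == 15

    def test_unknown_gene_rejected(self, small_stage_data, small_genome):
        truth, _ = small_stage_data
        cfg = syn.LeukemiaConfig(n_patients=2, n_specific_peaks=10)
        _, mixture = syn.generate_leukemia_samples(truth, cfg, seed=1)
        rna_cfg = syn.RnaConfig(
            dysregulation=(syn.DysregulatedGene("not_a_gene", ("P01",), "Q1"),)
        )
        with pytest.raises(KeyError, match="not_a_gene"):
            syn.generate_rna_counts(truth, mixture, rna_cfg, 1, genome=small_genome)


class TestSeedDeterminism:
    def test_identical_seeds_give_identical_cohorts(self):
        cfg = syn.CohortConfig(
            stages=syn.StageProfileConfig(n_peaks=300, donors_per_stage=2),
            leukemia=syn.LeukemiaConfig(n_patients=3, n_specific_peaks=20),
            motifs=syn.MotifSimConfig(n_motifs=5),
        )
        a = syn.simulate_cohort(cfg, seed=42)
        b = syn.simulate_cohort(cfg, seed=42)
        assert a.thymus_counts.counts.equals(b.thymus_counts.counts)
        assert a.leukemia_counts.counts.equals(b.leukemia_counts.counts)
        assert a.rna_counts.counts.equals(b.rna_counts.counts)
        assert a.motif_truth.occurrences.equals(b.motif_truth.occurrences)

    def test_different_seeds_differ(self):
        cfg = syn.CohortConfig(
            stages=syn.StageProfileConfig(n_peaks=300, donors_per_stage=2),
            leukemia=syn.LeukemiaConfig(n_patients=3, n_specific_peaks=20),
            motifs=syn.MotifSimConfig(n_motifs=5),
        )
        a = syn.simulate_cohort(cfg, seed=1)
        b = syn.simulate_cohort(cfg, seed=2)
        assert not a.thymus_counts.counts.equals(b.thymus_counts.counts)
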